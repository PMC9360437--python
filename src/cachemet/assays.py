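"""Treadmill exercise-capacity metrics and qPCR relative quantitation.

The maximal exercise test starts with 3 min of acclimation at zero speed,
then runs at 8 m/min with 2.5 m/min increments every 3 min until fatigue.
Distance is the time-integral of that speed schedule up to exhaustion, and
work against gravity is m * g * distance * sin(incline). The treadmill
incline is deliberately a required parameter: at 0 degrees the
against-gravity work is identically zero, which is rarely what is meant.

qPCR quantitation implements the standard 2^-dCt (target vs reference gene,
scaled so the reference group's mean is 1) and ddCt (e.g. mitochondrial vs
nuclear target, re-centred on the reference group's mean dCt) methods, with
no amplification-efficiency correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GRAVITY_M_S2 = 9.81


class AssayError(ValueError):
    pass


@dataclass
class TreadmillProtocol:
    """Incremental treadmill schedule (speeds in m/min, durations in min)."""

    acclimation_min: float = 3.0
    start_speed: float = 8.0
    increment: float = 2.5
    step_min: float = 3.0
    incline_deg: float | None = None   # required for work; no default

    def __post_init__(self) -> None:
        if min(self.acclimation_min, self.start_speed, self.step_min) < 0 \
                or self.increment < 0:
            raise AssayError("protocol parameters must be nonnegative")

    def speed_at(self, t_min: float) -> float:
        """Belt speed (m/min) at a time since test start."""
        if t_min < self.acclimation_min:
            return 0.0
        step = int((t_min - self.acclimation_min) // self.step_min)
        return self.start_speed + step * self.increment


def treadmill_distance(time_to_exhaustion: float,
                       protocol: TreadmillProtocol | None = None) -> float:
    """Distance run (m): integral of the piecewise-constant speed schedule
    from test start to exhaustion (zero speed during acclimation)."""
    protocol = protocol or TreadmillProtocol()
    t = float(time_to_exhaustion)
    if t < 0:
        raise AssayError("time must be nonnegative")
    run = max(0.0, t - protocol.acclimation_min)
    n_full = int(run // protocol.step_min)
    rem = run - n_full * protocol.step_min
    speeds = protocol.start_speed + protocol.increment * np.arange(n_full)
    dist = float(protocol.step_min * speeds.sum())
    dist += rem * (protocol.start_speed + protocol.increment * n_full)
    return dist


def treadmill_metrics(time_to_exhaustion: float, body_mass_g: float,
                      protocol: TreadmillProtocol | None = None
                      ) -> dict[str, float]:
    """Total duration (min), distance (m), and against-gravity work (J) of
    one exhaustion test. Raises unless the protocol specifies the incline."""
    protocol = protocol or TreadmillProtocol()
    if protocol.incline_deg is None:
        raise AssayError("treadmill incline must be specified to compute work")
    if body_mass_g <= 0:
        raise AssayError("body mass must be positive")
    dist = treadmill_distance(time_to_exhaustion, protocol)
    work = (body_mass_g / 1000.0) * GRAVITY_M_S2 * dist * np.sin(
        np.deg2rad(protocol.incline_deg))
    return {"duration_min": float(time_to_exhaustion),
            "distance_m": dist, "work_j": float(work)}


# ---------------------------------------------------------------------------
# qPCR

def _check_ct(table: pd.DataFrame) -> None:
    for col in ("sample_id", "group", "target_ct", "reference_ct"):
        if col not in table:
            raise AssayError(f"Ct table missing column {col!r}")
    ct = table[["target_ct", "reference_ct"]].to_numpy(dtype=float)
    if np.any(ct <= 0) or np.any(ct >= 45):
        raise AssayError("Ct values must lie in (0, 45)")


def relative_expression_2dct(table: pd.DataFrame,
                             reference_group: str = "-CACS") -> pd.DataFrame:
    """2^-dCt relative expression, normalized to the reference group's mean.

    dCt = target Ct - reference-gene Ct per sample; expression = 2^-dCt,
    then divided by the reference group's mean expression so that group
    averages 1 exactly.
    """
    _check_ct(table)
    ref = table["group"] == reference_group
    if not ref.any():
        raise AssayError(f"reference group {reference_group!r} is empty")
    dct = table["target_ct"].astype(float) - table["reference_ct"].astype(float)
    expr = np.power(2.0, -dct)
    out = table[["sample_id", "group"]].copy()
    out["dct"] = dct
    out["rel_expression"] = expr / expr[ref].mean()
    return out


def mtdna_content_ddct(table: pd.DataFrame,
                       reference_group: str = "-CACS") -> pd.DataFrame:
    """ddCt relative content (e.g. mitochondrial target vs nuclear target).

    dCt = Ct(mt) - Ct(nuclear); ddCt = dCt - mean dCt of the reference
    group; content = 2^-ddCt, so a sample at the reference group's mean dCt
    has content 1 and each cycle of earlier mt amplification doubles it.
    """
    _check_ct(table)
    ref = table["group"] == reference_group
    if not ref.any():
        raise AssayError(f"reference group {reference_group!r} is empty")
    dct = table["target_ct"].astype(float) - table["reference_ct"].astype(float)
    ddct = dct - dct[ref].mean()
    out = table[["sample_id", "group"]].copy()
    out["dct"] = dct
    out["ddct"] = ddct
    out["rel_content"] = np.power(2.0, -ddct)
    return out
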