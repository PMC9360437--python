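"""Indirect-calorimetry primitives: energy-expenditure rate, RER, daily TEE,
cumulative intake and activity from metabolic-cage traces.

A metabolic cage records, on a uniform time grid, the volume of oxygen
consumed (VO2) and carbon dioxide produced (VCO2), the distance travelled,
and the food mass removed from the hopper. Gas exchange is converted to an
energy-expenditure rate with the abbreviated Weir equation

    EE [kcal/h] = 60 * (3.941 * VO2 + 1.106 * VCO2),   gases in L/min,

which is the convention of commercial cage systems. The coefficients are
exposed so alternative calorific equivalents (e.g. Lusk) can be swapped in.

Recordings have two phases: the first 24 h is acclimation (animals behave
atypically in a new cage) and is excluded from analysis summaries by
default; everything after is the fed phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: kcal per litre O2 and CO2 in the abbreviated Weir equation.
WEIR_O2 = 3.941
WEIR_CO2 = 1.106

#: Energy density of standard rodent chow (PicoLab Rodent 20 5053), kcal/g.
CHOW_KCAL_PER_G = 3.43

ACCLIMATION_HOURS = 24.0


class CalorimetryError(ValueError):
    """Invalid cage-trace data or configuration."""


@dataclass
class CageTrace:
    """Uniformly sampled gas-exchange / activity / feeding series for one animal.

    Parameters
    ----------
    animal_id : str
        Subject identifier.
    t : ndarray
        Minutes since recording start; strictly increasing, uniform spacing.
    vo2, vco2 : ndarray
        Oxygen consumption and CO2 production in L/min.
    activity : ndarray
        Distance travelled per bin, metres.
    food : ndarray
        Food mass consumed per bin, grams.
    temperature_label : str
        Housing temperature, "22C" or "30C".
    """

    animal_id: str
    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    activity: np.ndarray
    food: np.ndarray
    temperature_label: str = "22C"

    def __post_init__(self) -> None:
        for name in ("t", "vo2", "vco2", "activity", "food"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if n < 2:
            raise CalorimetryError("trace needs at least two samples")
        for name in ("vo2", "vco2", "activity", "food"):
            arr = getattr(self, name)
            if arr.size != n:
                raise CalorimetryError(f"{name} length {arr.size} != t length {n}")
            if np.any(arr < 0):
                raise CalorimetryError(f"negative values in {name}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise CalorimetryError("t must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise CalorimetryError("t must be uniformly spaced; regularize upstream")

    @property
    def bin_minutes(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration_hours(self) -> float:
        """Total recorded span including the final bin."""
        return (self.t[-1] - self.t[0] + self.bin_minutes) / 60.0

    def activity_rate(self) -> np.ndarray:
        """Per-bin activity rate in m/h (distance / bin duration)."""
        return self.activity / (self.bin_minutes / 60.0)


@dataclass
class DailySummary:
    """One 24-h analysis window."""

    day: int
    tee: float            # kcal/day
    mean_rer: float       # dimensionless
    intake_kcal: float    # kcal/day
    distance: float       # m/day
    phase: str            # "acclimation" | "fed"

    def __post_init__(self) -> None:
        if self.tee < 0 or self.intake_kcal < 0:
            raise CalorimetryError("daily TEE and intake must be nonnegative")


def ee_rate(trace: CageTrace, o2_coef: float = WEIR_O2,
            co2_coef: float = WEIR_CO2) -> np.ndarray:
    """Energy-expenditure rate series in kcal/h via the abbreviated Weir equation."""
    return 60.0 * (o2_coef * trace.vo2 + co2_coef * trace.vco2)


def ee_rate_to_gases(ee: np.ndarray, rer: np.ndarray,
                     o2_coef: float = WEIR_O2,
                     co2_coef: float = WEIR_CO2) -> tuple[np.ndarray, np.ndarray]:
    """Invert the Weir equation: gas volumes (L/min) realizing a target energy
    rate (kcal/h) at a target RER.  ``ee_rate`` applied to the result recovers
    ``ee`` to machine precision; used by the synthetic generator."""
    ee = np.asarray(ee, dtype=float)
    rer = np.broadcast_to(np.asarray(rer, dtype=float), ee.shape)
    if np.any(rer <= 0):
        raise CalorimetryError("target RER must be positive")
    vo2 = ee / (60.0 * (o2_coef + co2_coef * rer))
    return vo2, rer * vo2


def rer_series(trace: CageTrace) -> np.ndarray:
    """Respiratory exchange ratio VCO2/VO2 per bin; NaN where VO2 is zero."""
    out = np.full(trace.vo2.shape, np.nan)
    ok = trace.vo2 > 0
    if not ok.any():
        warnings.warn("all-zero VO2: RER undefined everywhere", stacklevel=2)
        return out
    out[ok] = trace.vco2[ok] / trace.vo2[ok]
    return out


def intake_kcal(food_g: np.ndarray,
                chow_density: float = CHOW_KCAL_PER_G) -> np.ndarray:
    """Cumulative energy intake (kcal) from per-bin food mass (g)."""
    food_g = np.asarray(food_g, dtype=float)
    if chow_density <= 0:
        raise CalorimetryError("chow_density must be positive")
    if np.any(food_g < 0):
        raise CalorimetryError("negative food mass")
    return np.cumsum(food_g) * chow_density


def activity_distance(trace: CageTrace) -> np.ndarray:
    """Cumulative distance travelled (m)."""
    return np.cumsum(trace.activity)


def daily_tee(trace: CageTrace, exclude_acclimation: bool = True,
              chow_density: float = CHOW_KCAL_PER_G) -> list[DailySummary]:
    """Summarize a trace into consecutive 24-h windows aligned to recording start.

    Each window integrates the energy rate into a daily TEE (kcal/day), and
    carries mean RER, energy intake, and distance for that day. Windows that
    overlap the first 24 h are labelled ``acclimation`` and dropped when
    ``exclude_acclimation`` is set (the default, matching the two-phase
    recording protocol). Only complete 24-h windows are summarized.
    """
    bins_per_day = int(round(1440.0 / trace.bin_minutes))
    n_days = trace.t.size // bins_per_day
    if exclude_acclimation and trace.duration_hours < 2 * ACCLIMATION_HOURS - 1e-9:
        raise CalorimetryError(
            "trace shorter than one analysis day after acclimation exclusion")
    if n_days == 0:
        raise CalorimetryError("trace shorter than 24 h")
    ee = ee_rate(trace)
    rer = rer_series(trace)
    bin_h = trace.bin_minutes / 60.0
    out: list[DailySummary] = []
    for d in range(n_days):
        sl = slice(d * bins_per_day, (d + 1) * bins_per_day)
        phase = "acclimation" if d == 0 else "fed"
        if exclude_acclimation and phase == "acclimation":
            continue
        day_rer = rer[sl]
        out.append(DailySummary(
            day=d,
            tee=float(np.sum(ee[sl]) * bin_h),
            mean_rer=float(np.nanmean(day_rer)) if np.isfinite(day_rer).any() else float("nan"),
            intake_kcal=float(np.sum(trace.food[sl]) * chow_density),
            distance=float(np.sum(trace.activity[sl])),
            phase=phase,
        ))
    return out


def daily_summary_frame(summaries: list[DailySummary]) -> pd.DataFrame:
    """Tabulate daily summaries (column names are part of the file contract)."""
    return pd.DataFrame(
        [(s.day, s.phase, s.tee, s.mean_rer, s.intake_kcal, s.distance)
         for s in summaries],
        columns=["day", "phase", "tee_kcal_day", "mean_rer",
                 "intake_kcal_day", "distance_m_day"],
    )


def post_acclimation(trace: CageTrace) -> np.ndarray:
    """Boolean mask of bins after the 24-h acclimation phase."""
    return trace.t >= ACCLIMATION_HOURS * 60.0
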