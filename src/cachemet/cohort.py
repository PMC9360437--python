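"""Weight-trajectory processing: peak normalization, cachexia (CACS)
classification, disease staging, and humane-endpoint checks.

An animal is +CACS if it lost strictly more than 15 % of body weight from
its peak weight at any point over the observed course; otherwise -CACS.
"Pre-CACS" describes an animal that is at or below the threshold at a given
measurement time but crosses it later. The humane endpoint is >= 30 % loss
from peak or a body-composition score below 2, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Percent loss from peak defining cachexia (strict inequality).
CACS_THRESHOLD_PCT = 15.0
#: Percent loss from peak triggering euthanasia (inclusive).
ENDPOINT_LOSS_PCT = 30.0
#: Body-composition scores below this trigger euthanasia.
ENDPOINT_BCS = 2

EARLY_MAX_WEEKS = 4.0
MID_MAX_WEEKS = 8.0


class CohortError(ValueError):
    pass


@dataclass
class WeightSeries:
    """Serial body weights (and optional composition) for one animal."""

    animal_id: str
    day: np.ndarray       # days since induction, strictly increasing
    weight: np.ndarray    # grams
    lean: np.ndarray | None = None
    fat: np.ndarray | None = None
    bcs: np.ndarray | None = None   # ordinal body-composition score

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.day.size == 0:
            raise CohortError("empty weight series")
        if self.day.size != self.weight.size:
            raise CohortError("day/weight length mismatch")
        if np.any(np.diff(self.day) <= 0):
            raise CohortError("days must be strictly increasing")
        if np.any(self.weight <= 0):
            raise CohortError("weights must be positive")
        for name in ("lean", "fat", "bcs"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))


@dataclass
class CachexiaStatus:
    label: str                  # "+CACS" | "-CACS" | "Pre-CACS"
    onset_day: float | None     # first observed day loss exceeds threshold
    max_loss_pct: float


def loss_from_peak_pct(series: WeightSeries) -> np.ndarray:
    """Percent loss from the global peak weight at each observation."""
    peak = float(series.weight.max())
    return 100.0 * (1.0 - series.weight / peak)


def normalize_to_peak(series: WeightSeries) -> np.ndarray:
    """Weights as a fraction of the global peak; max of the output is 1."""
    return series.weight / float(series.weight.max())


def classify_cacs(series: WeightSeries,
                  threshold_pct: float = CACS_THRESHOLD_PCT,
                  at_time: float | None = None) -> CachexiaStatus:
    """Classify an animal's weight course.

    +CACS iff loss from the global peak strictly exceeds ``threshold_pct``
    at any observed day (so exactly 15.000 % loss is -CACS). When
    ``at_time`` is given and the animal is at/below threshold at that day
    but crosses later, the label is "Pre-CACS".
    """
    if not (0.0 < threshold_pct < 100.0):
        raise CohortError("threshold must be in (0, 100)")
    loss = loss_from_peak_pct(series)
    # strict inequality, with float-rounding guard so an exact-threshold
    # loss computed through division never flips the call
    exceeded = loss > threshold_pct + 1e-9
    max_loss = float(loss.max())
    onset = float(series.day[np.argmax(exceeded)]) if exceeded.any() else None
    if not exceeded.any():
        return CachexiaStatus("-CACS", None, max_loss)
    if at_time is not None:
        seen = series.day <= at_time
        if seen.any() and not exceeded[seen].any():
            return CachexiaStatus("Pre-CACS", onset, max_loss)
    return CachexiaStatus("+CACS", onset, max_loss)


def stage_label(day_since_induction: float,
                euthanasia_day: float | None = None,
                is_final_measurement: bool = False) -> str:
    """Disease stage of a measurement: Early (<= 4 weeks), Mid (4-8 weeks],
    or Late for the final pre-euthanasia measurement regardless of week
    (Late takes precedence)."""
    if day_since_induction < 0:
        raise CohortError("day must be nonnegative")
    if is_final_measurement and euthanasia_day is not None:
        return "Late"
    weeks = day_since_induction / 7.0
    if weeks <= EARLY_MAX_WEEKS:
        return "Early"
    if weeks <= MID_MAX_WEEKS:
        return "Mid"
    return "Late"


def endpoint_check(series: WeightSeries) -> tuple[bool, str | None, float | None]:
    """First humane-endpoint trigger: >= 30 % loss from peak, or BCS < 2.

    Returns ``(triggered, reason, day)`` with reason "weight" or "bcs"
    (the earlier trigger wins; at a tie, weight is reported)."""
    loss = loss_from_peak_pct(series)
    weight_day = None
    hit = loss >= ENDPOINT_LOSS_PCT - 1e-9
    if hit.any():
        weight_day = float(series.day[np.argmax(hit)])
    bcs_day = None
    if series.bcs is not None:
        low = series.bcs < ENDPOINT_BCS
        if low.any():
            bcs_day = float(series.day[np.argmax(low)])
    if weight_day is None and bcs_day is None:
        return False, None, None
    if bcs_day is None or (weight_day is not None and weight_day <= bcs_day):
        return True, "weight", weight_day
    return True, "bcs", bcs_day


def classify_cohort(weights: pd.DataFrame,
                    threshold_pct: float = CACS_THRESHOLD_PCT,
                    at_time: float | None = None) -> pd.DataFrame:
    """Classify every animal in a long-format cohort table
    (animal_id, day, weight_g[, bcs...]); one status row per animal."""
    rows = []
    for aid, grp in weights.groupby("animal_id", sort=True):
        grp = grp.sort_values("day")
        s = WeightSeries(animal_id=str(aid), day=grp["day"].to_numpy(),
                         weight=grp["weight_g"].to_numpy(),
                         bcs=grp["bcs"].to_numpy() if "bcs" in grp else None)
        st = classify_cacs(s, threshold_pct=threshold_pct, at_time=at_time)
        trig, reason, tday = endpoint_check(s)
        rows.append({"animal_id": str(aid), "label": st.label,
                     "onset_day": st.onset_day,
                     "max_loss_pct": st.max_loss_pct,
                     "endpoint_triggered": trig,
                     "endpoint_reason": reason, "endpoint_day": tday})
    return pd.DataFrame(rows)
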