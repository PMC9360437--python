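"""Prospective randomized-trial machinery for preclinical cachexia studies:
enrollment on weight-loss criteria, sex-stratified permuted-block
randomization, the primary weight-loss outcome with humane-endpoint
imputation, t-based sample-size estimation, and Kaplan-Meier / log-rank
survival analysis.

Design conventions mirror the source study: animals enter when they first
lose 10-15 % of peak weight, are randomized in blocks of 6 stratified by
sex, and the primary outcome is percent weight change 14 days after the
start of treatment; an animal euthanized before the End assessment carries
-30 % as its End value. Survival is measured from the induction date.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import StatsError, t_test

END_IMPUTATION_PCT = -30.0
DEFAULT_ENROLL_WINDOW = (10.0, 15.0)
DEFAULT_HORIZON_DAYS = 14.0


class TrialError(ValueError):
    pass


# ---------------------------------------------------------------------------
# enrollment and randomization

def enroll(weights: pd.DataFrame,
           window: tuple[float, float] = DEFAULT_ENROLL_WINDOW) -> pd.DataFrame:
    """Find each animal's enrollment day on serial monitoring.

    An animal is enrolled at the first observation where its loss from the
    peak-to-date falls inside ``window`` (percent). If weekly monitoring
    jumps over the window (e.g. 8 % -> 18 %), the animal is enrolled at the
    first observation past it and flagged ``window_skipped``. Animals never
    reaching the lower bound are not enrolled.
    """
    lo, hi = window
    if not (0 < lo < hi < 100):
        raise TrialError("invalid enrollment window")
    rows = []
    for aid, grp in weights.groupby("animal_id", sort=True):
        grp = grp.sort_values("day")
        w = grp["weight_g"].to_numpy(dtype=float)
        peak = np.maximum.accumulate(w)
        loss = 100.0 * (1.0 - w / peak)
        in_win = (loss >= lo) & (loss <= hi)
        past = loss > hi
        if in_win.any():
            k, skipped = int(np.argmax(in_win)), False
        elif past.any():
            k, skipped = int(np.argmax(past)), True
        else:
            continue
        row = {"animal_id": aid,
               "enroll_day": float(grp["day"].iloc[k]),
               "start_weight": float(w[k]),
               "loss_at_enroll_pct": float(loss[k]),
               "window_skipped": skipped}
        if "sex" in grp:
            row["sex"] = grp["sex"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def block_randomize(subjects: pd.DataFrame, arms: list[str],
                    block_size: int = 6, seed: int = 0) -> pd.DataFrame:
    """Permuted-block randomization stratified by sex.

    Within each sex stratum, subjects (in their given order) are assigned
    from consecutive blocks; every complete block contains each arm exactly
    ``block_size / len(arms)`` times in seed-permuted order. An incomplete
    final block is the truncation of one more permuted full block, so its
    arm counts differ by at most 1.
    """
    arms = list(arms)
    if block_size % len(arms) != 0:
        raise TrialError(
            f"block size {block_size} not divisible by {len(arms)} arms")
    if "animal_id" not in subjects or "sex" not in subjects:
        raise TrialError("subjects need animal_id and sex columns")
    per = block_size // len(arms)
    rng = np.random.default_rng(seed)
    out = []
    for sex in sorted(pd.unique(subjects["sex"]).tolist()):
        ids = subjects.loc[subjects["sex"] == sex, "animal_id"].tolist()
        assigned = []
        while len(assigned) < len(ids):
            block = np.repeat(np.arange(len(arms)), per)
            rng.shuffle(block)
            assigned.extend(block.tolist())
        for aid, a in zip(ids, assigned):
            out.append({"animal_id": aid, "sex": sex, "arm": arms[a]})
    return pd.DataFrame(out)[["animal_id", "arm"]] if out else pd.DataFrame(
        columns=["animal_id", "arm"])


# ---------------------------------------------------------------------------
# primary outcome

@dataclass
class TrialRecord:
    """One enrolled animal's trial course."""

    animal_id: str
    sex: str
    arm: str
    enroll_day: float
    start_weight: float               # g at randomization
    end_weight: float | None          # g at the End assessment, if reached
    endpoint_day: float | None        # day humane endpoint met, if before End
    death_day: float | None = None    # from induction
    censor_day: float | None = None


def primary_outcome_table(records: list[TrialRecord],
                          horizon: float = DEFAULT_HORIZON_DAYS) -> pd.DataFrame:
    """Percent weight change from Start to End per animal.

    Animals meeting the humane endpoint before ``horizon`` days of treatment
    receive exactly -30 % (imputed). Animals with neither an End weight nor
    an endpoint are recorded missing and excluded from summaries.
    """
    rows = []
    for r in records:
        met_endpoint = (r.endpoint_day is not None
                        and r.endpoint_day < r.enroll_day + horizon)
        if met_endpoint:
            pct, imputed, missing = END_IMPUTATION_PCT, True, False
        elif r.end_weight is not None:
            pct = 100.0 * (r.end_weight - r.start_weight) / r.start_weight
            imputed, missing = False, False
        else:
            pct, imputed, missing = np.nan, False, True
        rows.append({"animal_id": r.animal_id, "arm": r.arm,
                     "start_weight": r.start_weight,
                     "end_pct_change": pct, "imputed": imputed,
                     "missing": missing})
    return pd.DataFrame(rows)


def arm_summary(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-arm summary of the primary outcome with a paired Start-vs-End
    test (equivalently a one-sample t of percent change against 0)."""
    rows = []
    for arm, grp in outcomes.groupby("arm", sort=True):
        vals = grp.loc[~grp["missing"], "end_pct_change"].to_numpy(dtype=float)
        n_missing = int(grp["missing"].sum())
        if vals.size >= 2 and np.std(vals) >= 0:
            t, df, p = t_test(vals, popmean=0.0)
        else:
            t = df = p = np.nan
        rows.append({"arm": arm, "n": int(vals.size),
                     "n_missing": n_missing,
                     "n_imputed": int(grp["imputed"].sum()),
                     "mean_pct_change": float(np.mean(vals)) if vals.size else np.nan,
                     "sd_pct_change": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                     "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sample size

def sample_size_two_means(relative_change: float, sd: float, mean: float,
                          alpha: float = 0.05, power: float = 0.90,
                          n_max: int = 100000) -> int:
    """Smallest per-group n for a two-sided two-sample t-test to detect a
    ``relative_change`` x ``mean`` difference with the stated power.

    Power is evaluated exactly with the noncentral t distribution
    (ncp = effect / (sd * sqrt(2/n)), df = 2n - 2).
    """
    if sd <= 0:
        raise TrialError("sd must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise TrialError("alpha and power must be in (0,1)")
    effect = abs(relative_change * mean)
    if effect == 0:
        raise TrialError("zero effect: required n is unbounded")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        ncp = effect / (sd * np.sqrt(2.0 / n))
        achieved = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
        if achieved >= power:
            return n
    raise TrialError("required n exceeds n_max; effect too small")


# ---------------------------------------------------------------------------
# survival

@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate."""

    times: np.ndarray      # distinct event times (days)
    survival: np.ndarray   # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_day": self.times,
                             "survival": self.survival,
                             "at_risk": self.at_risk,
                             "events": self.events})


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimator; at tied times deaths are processed
    before censorings (standard convention)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size != events.size or times.size == 0:
        raise TrialError("times/events mismatch or empty")
    if np.any(times < 0):
        raise TrialError("negative survival time")
    event_times = np.unique(times[events])
    s = 1.0
    surv, risk, dth = [], [], []
    for t in event_times:
        n_risk = int(np.sum(times >= t))   # censored at t still at risk
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        risk.append(n_risk)
        dth.append(d)
    return KMCurve(times=event_times, survival=np.array(surv),
                   at_risk=np.array(risk, dtype=int),
                   events=np.array(dth, dtype=int))


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]
                 ) -> tuple[float, int, float]:
    """Mantel-Cox log-rank test across >= 2 groups.

    Returns ``(chi2, df, p)`` with df = groups - 1. The statistic compares
    observed versus expected events in each group over the pooled risk sets,
    using the hypergeometric variance (covariance for > 2 groups).
    """
    k = len(groups)
    if k < 2:
        raise TrialError("need >= 2 groups")
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=bool) for _, e in groups]
    all_times = np.concatenate(times)
    all_events = np.concatenate(events)
    if not all_events.any():
        raise TrialError("no events: log-rank test undefined")
    labels = np.concatenate([np.full(t.size, g) for g, t in enumerate(times)])
    tau = np.unique(all_times[all_events])

    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in tau:
        at_risk = all_times >= t
        n = at_risk.sum()
        d = int((all_events & (all_times == t)).sum())
        if n == 0 or d == 0:
            continue
        n_g = np.array([(at_risk & (labels == g)).sum() for g in range(k)],
                       dtype=float)
        d_g = np.array([((all_events) & (all_times == t) & (labels == g)).sum()
                        for g in range(k)], dtype=float)
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        if n > 1:
            frac = n_g / n
            c = d * (n - d) / (n - 1)
            cov += c * (np.diag(frac) - np.outer(frac, frac))
    # drop the last group (singular covariance); generalized form
    v = cov[:-1, :-1]
    u = o_minus_e[:-1]
    try:
        chi2 = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(v) @ u)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return chi2, df, float(sps.chi2.sf(chi2, df))


def survival_from_records(records: pd.DataFrame,
                          origin: str = "induction") -> pd.DataFrame:
    """Extract (time, event) per arm from a trial table. ``origin`` is
    "induction" (default, times already measured from induction day 0) or
    "enrollment" (times re-anchored to each animal's enroll_day)."""
    if origin not in ("induction", "enrollment"):
        raise TrialError("origin must be 'induction' or 'enrollment'")
    t = records["time_day"].to_numpy(dtype=float)
    if origin == "enrollment":
        t = t - records["enroll_day"].to_numpy(dtype=float)
    return pd.DataFrame({"arm": records["arm"], "time_day": t,
                         "event": records["event"].astype(bool)})
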