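"""Synthetic metabolic-cage and cohort generator with a known truth ledger.

Emulates the data streams of a murine lung-cancer cachexia study so that
every downstream stage — calorimetry, energy partitioning, cachexia
classification, trial analysis — can be exercised against known ground
truth:

* circadian resting energy expenditure (sinusoid peaking mid-dark-phase);
* bursty spontaneous activity as a marked Poisson process, dark-phase rate
  >= light-phase rate (cumulative-distance traces are step-like);
* a strictly activity-proportional energy cost, so the true total energy
  rate is TEE(t) = REE(t) + CCA * activity_rate(t) by construction;
* gas traces obtained by inverting the Weir equation at the simulated
  energy rate and a target RER, so calorimetry round-trips exactly;
* weight trajectories with logistic rise to a peak and, in animals drawn
  cachectic, an exponential fractional decline after a random onset day;
* survival tied to the 30 %-loss humane endpoint;
* arm-specific treatment effects for randomized-trial simulations.

All randomness flows through :func:`numpy.random.default_rng` seeded from
the config, so identical (config, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calorimetry import CHOW_KCAL_PER_G, CageTrace, ee_rate_to_gases


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-level simulation settings.

    Defaults describe a 12 h light/dark colony at 22 degC: ~70 % of
    tumor-bearing animals become cachectic, cages record 3 consecutive days
    at 5-min bins, and chow is 3.43 kcal/g.
    """

    n_animals: int = 20
    sex_ratio: float = 0.5            # fraction female
    cacs_penetrance: float = 0.7      # probability an animal becomes cachectic
    bin_minutes: int = 5
    days: int = 3
    ree_base: float = 0.4             # kcal/h resting rate (midline)
    circadian_amp: float = 0.15       # fraction of ree_base
    cca_true: float = 0.02            # kcal per metre travelled
    activity_rate_dark: float = 12.0  # bursts/h
    activity_rate_light: float = 4.0  # bursts/h
    burst_distance: float = 3.0       # mean metres per burst
    rer_fed: float = 0.95
    rer_fasted: float = 0.72
    noise_sd: float = 0.05            # kcal/h additive energy-rate noise
    chow_density: float = CHOW_KCAL_PER_G
    daily_food_g: float = 4.0         # ad-libitum intake, grams/day
    cr_ration_g: float | None = None  # calorie-restricted evening ration (g/day)
    seed: int = 0

    # weight / survival model
    peak_weight_mean: float = 30.0    # g (females ~3 g lighter)
    peak_weight_sd: float = 1.5
    sex_weight_gap: float = 3.0       # male minus female peak weight, g
    onset_day_mean: float = 42.0      # day decline begins (post-induction)
    onset_day_sd: float = 7.0
    decline_rate_mean: float = 0.02   # fractional loss per day after onset
    decline_rate_sd: float = 0.004
    weigh_interval_days: int = 7
    follow_up_days: int = 120
    weight_noise_sd: float = 0.2      # g, scale measurement noise

    def __post_init__(self) -> None:
        if self.bin_minutes <= 0 or self.days <= 0:
            raise SimConfigError("bin_minutes and days must be positive")
        if 1440 % self.bin_minutes != 0:
            raise SimConfigError("bin_minutes must divide 1440")
        if not (0.0 <= self.cacs_penetrance <= 1.0):
            raise SimConfigError("cacs_penetrance must be in [0,1]")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise SimConfigError("sex_ratio must be in [0,1]")
        for name in ("ree_base", "circadian_amp", "activity_rate_dark",
                     "activity_rate_light", "burst_distance", "noise_sd",
                     "chow_density", "daily_food_g", "weight_noise_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be nonnegative")
        for name in ("rer_fed", "rer_fasted"):
            if not (0.65 <= getattr(self, name) <= 1.05):
                raise SimConfigError(f"{name} must be in [0.65, 1.05]")
        if self.activity_rate_dark < self.activity_rate_light:
            raise SimConfigError("dark-phase activity rate must be >= light-phase")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CageTruth:
    """Per-trace truth ledger: noise-free series on the trace's time grid."""

    cca: float                 # kcal/m
    ree: np.ndarray            # kcal/h, true resting series
    ee: np.ndarray             # kcal/h, true total series (pre-noise)
    activity_rate: np.ndarray  # m/h


def _phase_dark(t_min: np.ndarray) -> np.ndarray:
    """True where a bin falls in the dark phase; recording starts at lights-on."""
    return (t_min % 1440.0) >= 720.0


def simulate_cage_trace(config: SimConfig, seed: int,
                        animal_id: str = "M1") -> tuple[CageTrace, CageTruth]:
    """Generate one animal's cage trace plus its truth ledger.

    The true total energy rate is ``REE(t) + cca_true * activity_rate(t)``
    exactly; truncated-Gaussian noise is added on the energy-rate scale and
    the noisy rate is inverted to (VO2, VCO2) at the bin's target RER
    (``rer_fed`` in the dark phase, ``rer_fasted`` in the light phase).
    """
    rng = np.random.default_rng(seed)
    n = config.days * (1440 // config.bin_minutes)
    t = np.arange(n, dtype=float) * config.bin_minutes
    bin_h = config.bin_minutes / 60.0
    dark = _phase_dark(t)

    # circadian REE peaking mid-dark (t = 1080 min on day 0)
    ree = config.ree_base * (
        1.0 + config.circadian_amp * np.cos(2 * np.pi * (t - 1080.0) / 1440.0))

    # marked Poisson activity bursts, exponential distances
    rate = np.where(dark, config.activity_rate_dark, config.activity_rate_light)
    n_bursts = rng.poisson(rate * bin_h)
    distance = np.zeros(n)
    moving = n_bursts > 0
    # Gamma(k bursts, mean burst distance) == sum of k exponential marks
    distance[moving] = rng.gamma(n_bursts[moving], config.burst_distance)
    activity_rate = distance / bin_h

    ee_true = ree + config.cca_true * activity_rate
    ee_obs = ee_true
    if config.noise_sd > 0:
        ee_obs = np.maximum(ee_true + rng.normal(0.0, config.noise_sd, n), 0.0)

    rer = np.where(dark, config.rer_fed, config.rer_fasted)
    vo2, vco2 = ee_rate_to_gases(ee_obs, rer)

    food = _food_schedule(config, t, dark, rng)

    trace = CageTrace(animal_id=animal_id, t=t, vo2=vo2, vco2=vco2,
                      activity=distance, food=food)
    truth = CageTruth(cca=config.cca_true, ree=ree, ee=ee_true,
                      activity_rate=activity_rate)
    return trace, truth


def _food_schedule(config: SimConfig, t: np.ndarray, dark: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Ad-libitum feeding spread over dark bins; or, for calorie restriction,
    a single fixed evening ration delivered at dark onset (18:00)."""
    food = np.zeros(t.size)
    if config.cr_ration_g is not None:
        evening = np.isclose(t % 1440.0, 720.0)
        food[evening] = config.cr_ration_g
        return food
    if config.daily_food_g <= 0:
        return food
    dark_idx = np.flatnonzero(dark)
    if dark_idx.size == 0:
        return food
    # split each day's intake over that day's dark bins with Dirichlet weights
    day = (t[dark_idx] // 1440).astype(int)
    for d in np.unique(day):
        idx = dark_idx[day == d]
        w = rng.dirichlet(np.full(idx.size, 0.3))
        food[idx] = config.daily_food_g * w
    return food


def simulate_cohort_traces(config: SimConfig) -> tuple[list[CageTrace], list[CageTruth]]:
    """Cage traces for ``n_animals``, with per-animal seeds spawned from the
    config seed."""
    traces, truths = [], []
    base = np.random.default_rng(config.seed)
    seeds = base.integers(0, 2**31 - 1, size=config.n_animals)
    for i, s in enumerate(seeds):
        tr, gt = simulate_cage_trace(config, int(s), animal_id=f"M{i + 1:03d}")
        traces.append(tr)
        truths.append(gt)
    return traces, truths


# ---------------------------------------------------------------------------
# weight trajectories and survival


@dataclass
class AnimalTruth:
    """Ground truth for one animal's disease course."""

    animal_id: str
    sex: str                       # "F" | "M"
    is_cacs: bool
    peak_weight: float             # g
    decline_start_day: float | None
    cacs_onset_day: float | None   # first day true loss from peak exceeds 15 %
    decline_rate: float | None     # fractional loss per day
    death_day: float | None        # day true loss reaches 30 %
    censor_day: float


CACS_LOSS_FRAC = 0.15
ENDPOINT_LOSS_FRAC = 0.30


def _true_weight(day: np.ndarray, peak: float, decline_start: float | None,
                 rate: float | None) -> np.ndarray:
    """Noise-free weight model: logistic rise to the peak, then exponential
    fractional decline at `rate` per day once decline starts."""
    day = np.asarray(day, dtype=float)
    w = peak * (1.0 - 0.08 * np.exp(-day / 10.0))   # rises from 92 % of peak
    if decline_start is not None:
        post = day > decline_start
        w_at = peak * (1.0 - 0.08 * np.exp(-decline_start / 10.0))
        w = np.where(post, w_at * np.exp(-rate * (day - decline_start)), w)
    return w


def simulate_weight_trajectories(
        config: SimConfig, seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serial weights plus the truth ledger for a tumor-bearing cohort.

    Returns ``(weights, truth)``: a long-format frame (animal_id, sex, day,
    weight_g, lean_g, fat_g, bcs) observed every ``weigh_interval_days`` with
    a terminal observation on the euthanasia day, and one truth row per
    animal. Each cachectic animal declines toward the 30 %-loss humane
    endpoint, which sets its death day; non-cachectic animals stay well above
    15 % loss for the whole series and are censored at follow-up end.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, truth_rows = [], []
    for i in range(config.n_animals):
        aid = f"A{i + 1:03d}"
        sex = "F" if rng.random() < config.sex_ratio else "M"
        peak = rng.normal(config.peak_weight_mean, config.peak_weight_sd)
        if sex == "F":
            peak -= config.sex_weight_gap / 2.0
        else:
            peak += config.sex_weight_gap / 2.0
        drawn_cacs = bool(rng.random() < config.cacs_penetrance)
        decline_start = onset15 = rate = death = None
        if drawn_cacs:
            decline_start = float(max(21.0, rng.normal(
                config.onset_day_mean, config.onset_day_sd)))
            rate = float(max(1e-3, rng.normal(
                config.decline_rate_mean, config.decline_rate_sd)))
            # loss is referenced to the peak weight actually observed on the
            # weigh schedule (the last rising observation), as an analyst
            # measuring "loss from peak" would see it
            last_rise = (decline_start // config.weigh_interval_days
                         ) * config.weigh_interval_days
            peak_obs = float(_true_weight(np.array([last_rise]), peak,
                                          None, None)[0])
            w_start = float(_true_weight(np.array([decline_start]), peak,
                                         None, None)[0])
            onset15 = decline_start + np.log(
                w_start / ((1.0 - CACS_LOSS_FRAC) * peak_obs)) / rate
            death = decline_start + np.log(
                w_start / ((1.0 - ENDPOINT_LOSS_FRAC) * peak_obs)) / rate
            if onset15 > config.follow_up_days:
                # censored before ever crossing the cachexia threshold: over
                # the observed course this animal is not cachectic
                drawn_cacs = False
                decline_start = onset15 = rate = death = None
            elif death > config.follow_up_days:
                death = None
        is_cacs = drawn_cacs

        end = death if death is not None else float(config.follow_up_days)
        days = np.arange(0.0, end + 1e-9, config.weigh_interval_days)
        if days[-1] < end - 1e-9:
            days = np.append(days, end)    # terminal (euthanasia) observation
        w = _true_weight(days, peak, decline_start, rate)
        if config.weight_noise_sd > 0:
            w = w + rng.normal(0.0, config.weight_noise_sd, days.size)
        w = np.maximum(w, 1.0)
        # simple allometric body composition: lean ~77 % of weight, rest fat;
        # cachectic decline erodes both compartments
        lean = 0.77 * w
        fat = w - lean - 1.0   # ~1 g other (bone, organs offset)
        fat = np.maximum(fat, 0.2)
        for d, wt, ln, ft in zip(days, w, lean, fat):
            rows.append((aid, sex, float(d), float(wt), float(ln),
                         float(ft), 3))
        truth_rows.append(AnimalTruth(
            animal_id=aid, sex=sex, is_cacs=is_cacs, peak_weight=float(peak),
            decline_start_day=decline_start, cacs_onset_day=onset15,
            decline_rate=rate, death_day=death,
            censor_day=float(config.follow_up_days)))

    weights = pd.DataFrame(
        rows, columns=["animal_id", "sex", "day", "weight_g",
                       "lean_g", "fat_g", "bcs"])
    truth = pd.DataFrame([dataclasses.asdict(t) for t in truth_rows])
    return weights, truth


# ---------------------------------------------------------------------------
# randomized-trial cohorts


@dataclass
class ArmEffect:
    """Additive treatment effects applied from enrollment onward.

    ``decline_rate_delta`` shifts the post-enrollment fractional weight-loss
    rate (negative slows loss; large negative reverses it), which in turn
    moves the 30 %-loss death day — the survival effect. The remaining fields
    perturb secondary outcomes.
    """

    decline_rate_delta: float = 0.0    # per day
    intake_kcal_delta: float = 0.0     # kcal/day
    fat_pct_delta: float = 0.0         # percent change at End
    lean_pct_delta: float = 0.0
    activity_m_delta: float = 0.0      # m/day


def simulate_trial_cohort(
        config: SimConfig,
        arm_effects: dict[str, ArmEffect],
        seed: int | None = None,
        enroll_window: tuple[float, float] = (10.0, 15.0),
        horizon_days: float = 14.0,
        block_size: int = 6,
) -> pd.DataFrame:
    """Simulate a prospective randomized trial on a cachectic cohort.

    Animals are monitored on the weigh schedule; when loss from peak first
    enters ``enroll_window`` (percent) they are enrolled and randomized to an
    arm (permuted blocks, stratified by sex). From enrollment the decline
    rate becomes ``rate + decline_rate_delta`` for the assigned arm. The End
    weight is read from the perturbed trajectory at ``horizon_days`` after
    enrollment; animals whose trajectory hits the 30 % humane endpoint first
    die on that day and are flagged for -30 % imputation downstream. With all
    effects zero the cohort reduces to :func:`simulate_weight_trajectories`
    courses.

    Returns one row per enrolled animal with Start/End weights, endpoint and
    survival fields (survival measured from induction, day 0).
    """
    from .trial import block_randomize  # local import to avoid a cycle

    if not arm_effects:
        raise SimConfigError("arm_effects must name at least one arm")
    rng_seed = config.seed if seed is None else seed
    weights, truth = simulate_weight_trajectories(config, seed=rng_seed)
    rng = np.random.default_rng(rng_seed + 1)

    lo, hi = enroll_window
    enrolled = []
    for aid, grp in weights.groupby("animal_id", sort=True):
        grp = grp.sort_values("day")
        peak_so_far = np.maximum.accumulate(grp["weight_g"].to_numpy())
        loss_pct = 100.0 * (1.0 - grp["weight_g"].to_numpy() / peak_so_far)
        in_win = (loss_pct >= lo) & (loss_pct <= hi)
        past = loss_pct > hi
        if in_win.any():
            k = int(np.argmax(in_win))
            skipped = False
        elif past.any():
            k = int(np.argmax(past))
            skipped = True
        else:
            continue
        enrolled.append({
            "animal_id": aid,
            "sex": grp["sex"].iloc[0],
            "enroll_day": float(grp["day"].iloc[k]),
            "start_weight": float(grp["weight_g"].iloc[k]),
            "window_skipped": skipped,
        })
    if not enrolled:
        return pd.DataFrame(columns=[
            "animal_id", "sex", "arm", "enroll_day", "start_weight",
            "end_weight", "end_pct_change", "endpoint_day", "imputed",
            "time_day", "event", "window_skipped",
            "intake_kcal_day", "fat_pct_change", "lean_pct_change",
            "activity_m_day"])

    enrolled_df = pd.DataFrame(enrolled)
    arms = sorted(arm_effects)
    assignment = block_randomize(
        enrolled_df[["animal_id", "sex"]], arms=arms,
        block_size=block_size, seed=int(rng.integers(0, 2**31 - 1)))
    enrolled_df = enrolled_df.merge(assignment, on="animal_id")

    tmap = truth.set_index("animal_id")
    rows = []
    for rec in enrolled_df.itertuples(index=False):
        tr = tmap.loc[rec.animal_id]
        eff = arm_effects[rec.arm]
        base_rate = 0.0 if pd.isna(tr.decline_rate) else float(tr.decline_rate)
        new_rate = base_rate + eff.decline_rate_delta
        w0 = rec.start_weight
        peak = tr.peak_weight

        def w_post(d: float) -> float:
            return w0 * np.exp(-new_rate * d)   # from enrollment onward

        # day (post-enrollment) the 30 %-loss endpoint is reached, if ever
        endpoint_rel = None
        target = (1.0 - ENDPOINT_LOSS_FRAC) * peak
        if new_rate > 0 and w0 > target:
            endpoint_rel = float(np.log(w0 / target) / new_rate)
        elif w0 <= target:
            endpoint_rel = 0.0

        imputed = endpoint_rel is not None and endpoint_rel < horizon_days
        if imputed:
            end_weight = float(w_post(endpoint_rel))
            endpoint_day = rec.enroll_day + endpoint_rel
        else:
            end_weight = float(w_post(horizon_days))
            endpoint_day = None

        if endpoint_rel is not None and (
                rec.enroll_day + endpoint_rel <= config.follow_up_days):
            time_day, event = rec.enroll_day + endpoint_rel, True
        else:
            time_day, event = float(config.follow_up_days), False

        noise = rng.normal(0.0, config.weight_noise_sd) if config.weight_noise_sd else 0.0
        end_obs = -30.0 if imputed else 100.0 * ((end_weight + noise) - w0) / w0
        rows.append({
            "animal_id": rec.animal_id, "sex": rec.sex, "arm": rec.arm,
            "enroll_day": rec.enroll_day, "start_weight": w0,
            "end_weight": end_weight,
            "end_pct_change": float(end_obs),
            "endpoint_day": endpoint_day, "imputed": bool(imputed),
            "time_day": float(time_day), "event": bool(event),
            "window_skipped": rec.window_skipped,
            "intake_kcal_day": float(
                config.daily_food_g * config.chow_density
                + eff.intake_kcal_delta + rng.normal(0, 0.8)),
            "fat_pct_change": float(eff.fat_pct_delta + rng.normal(0, 3.0)),
            "lean_pct_change": float(eff.lean_pct_delta + rng.normal(0, 2.0)),
            "activity_m_day": float(max(0.0, 400.0 + eff.activity_m_delta
                                        + rng.normal(0, 60.0))),
        })
    return pd.DataFrame(rows)
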