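# Methods

This note documents the models implemented in `cachemet`, the defaults and
why they were chosen, the numerical decisions, and what validation on
synthetic data does and does not establish.

## Indirect calorimetry

Energy-expenditure rate is computed with the abbreviated Weir equation,
`EE [kcal/h] = 60·(3.941·VO₂ + 1.106·VCO₂)` with gases in L/min — the
convention of commercial metabolic-cage systems. The calorific coefficients
are exposed (`ee_rate(trace, o2_coef, co2_coef)`) so alternative equivalents
(e.g. Lusk) can be substituted. Traces must be strictly uniform in time;
gaps are rejected rather than imputed, because silent imputation of gas
traces corrupts the downstream regression in ways that are hard to audit.

Recordings follow a two-phase protocol: the first 24 h in a fresh cage is
acclimation and is excluded from all analysis summaries by default (a flag
restores it). Daily windows are aligned to recording start rather than clock
midnight; recording-start alignment is exactly reproducible from the trace
itself, whereas midnight alignment would depend on external clock metadata
the trace format does not carry. A 3-day recording therefore yields 2
analysis days. Chow energy density defaults to 3.43 kcal/g (standard rodent
chow), making the 2.33 g/day restricted ration ≈ 8 kcal/day.

## Energy partition and the caloric cost of activity

The decomposition has exactly two components. Per animal:

1. the caloric cost of activity (CCA, kcal/m) is the coefficient of the
   activity rate (m/h) in a regression of total energy rate (kcal/h);
2. `AEE(t) = CCA · activity_rate(t)`; `REE(t) = TEE(t) − AEE(t)`.

The identity `AEE + REE = TEE` holds bin-wise by construction; smoothing is
applied afterwards and never alters the unsmoothed accounting. Daily
aggregates are computed from unsmoothed series.

**Two CCA estimators.** `fit_cca` is the plain fixed-intercept OLS of energy
rate on activity rate. `fit_cca_spline` — the default used by
`partition_trace` — fits `EE(t) = f(t) + CCA·activity_rate(t)` where `f` is
a penalized B-spline of time, penalizing only the spline coefficients. The
joint fit exists because resting expenditure is circadian and mice are more
active in the dark phase: with a fixed intercept, part of the nocturnal rise
in REE is attributed to activity, biasing the slope upward by an amount that
does not shrink with the noise level (at the package defaults the OLS bias
is ≈ +0.8 %, several naive standard errors). Accounting for a time-varying
resting baseline while estimating the activity cost is precisely the reason
a spline enters this analysis at all; the plain OLS remains available for
comparison and for traces without circadian structure.

Degenerate designs (constant activity) raise an error naming the animal.
Negative fitted CCA, possible under noise, is reported as-is with a warning;
`clamp_nonnegative` clamps to zero for pipeline use. Bins with negative
computed REE are retained but counted; more than 5 % triggers a data-quality
warning. OLS standard errors are naive (no autocorrelation correction); the
spline estimator's SE is a penalized-regression sandwich estimate.

**P-spline smoother.** Degree-2 B-spline basis on equally spaced knots
(default spacing 60 min), order-2 difference penalty, solving
`(B'B + λD'D)β = B'y`. λ is either fixed or chosen by generalized
cross-validation, `GCV(λ) = n·RSS/(n − tr(H))²`, minimized over a 25-point
log grid from 1e-4 to 1e8. The order-2 penalty leaves linear trends
unpenalized, so λ→∞ reproduces straight-line data; λ=0 interpolates any
function exactly representable in the basis (e.g. a quadratic). Solves use
Cholesky factorization with a tiny ridge fallback only if the unpenalized
normal matrix is rank-deficient (an empty knot span). At λ ≳ 1e12 the solve
is dominated by the penalty block and loses a few digits; GCV never selects
that regime.

## ANCOVA and the statistics toolkit

Lean-mass normalization of TEE uses a common-slope ANCOVA: cell-means group
indicators plus a single shared covariate slope, solved from the normal
equations. Adjusted means are the fitted values at the grand-mean covariate;
`residual df = n − k − 1`. The no-interaction (common-slope) form follows
standard mouse-phenotyping practice; a slope-homogeneity F-test
(`ancova_interaction_test`) is provided for checking, but the default
pipeline does not condition on it.

Pairwise contrasts use Tukey's studentized range with Tukey–Kramer standard
errors (`q = √2·|diff|/SE_diff`). The studentized-range CDF is evaluated by
direct Gauss–Legendre quadrature of its classical double integral (outer
over the scaled-chi scale variable on (0, 5] with 120 nodes, inner over the
range anchor on [−8, 8] with 80 nodes), accurate to ~1e-6 and validated in
the tests against both Monte-Carlo simulation and an independent library
implementation. Fisher's LSD is provided (`lsd_pairwise`) without
multiplicity protection, for comparison only; Tukey is the default.

Two-sample t-tests default to pooled variance (classical Student), with
Welch behind a flag. Two-way ANOVA for cumulative intake/activity curves is
a factorial fixed-effects decomposition on per-animal daily totals (Type-II
sums of squares via model comparison) — bin-level series are autocorrelated
and are not a valid unit of analysis.

## Cohort classification

"Peak" is the global maximum of the observed weight series. +CACS requires
loss from peak strictly greater than 15 % (an exact 15.000 % loss is −CACS);
a 1e-9 percentage-point guard prevents float rounding from flipping
boundary cases. Pre-CACS at time *t* means at-or-below threshold at *t* and
+CACS eventually; no additional weight-stability criterion is imposed. The
humane endpoint is ≥ 30 % loss or body-composition score < 2, whichever
observation comes first (weight reported on ties). Stage labels: Early
(≤ 4 weeks), Mid (4–8 weeks], and Late for the final pre-euthanasia
measurement, which takes precedence regardless of week.

## Trial machinery

Enrollment scans serial weights for the first observation with loss from
peak-to-date inside 10–15 %; a trajectory that jumps the window between
weekly weighings is enrolled at the first observation past it, flagged
`window_skipped`. Randomization is permuted-block (default block 6)
stratified by sex; an incomplete final block is a truncated permuted full
block, so within-stratum arm counts never differ by more than 1. The
primary outcome is percent weight change at 14 days from the randomization
day; animals meeting the humane endpoint first carry exactly −30 %
(`imputed` flag set). Missing End weights without an endpoint are excluded
with a count, never imputed.

Sample size for two means iterates the exact noncentral-t power of the
two-sided pooled t-test (ncp = effect/(sd·√(2/n)), df = 2n−2) to the
smallest n achieving the target power; the textbook reference point
(d = 1.0 SD, α = 0.05, power 0.90 → n = 23/group) is asserted in the tests.
The power argument is named `power` (0.90), as a type-II-error rate of 0.90
would be uninterpretable.

Survival uses the Kaplan–Meier product-limit estimator (deaths before
censorings at ties) and the Mantel–Cox log-rank test with the
hypergeometric covariance, df = groups − 1. Both are validated against an
independent survival library on random small datasets to 1e-8. Survival is
timed from induction (day 0) by default; `origin="enrollment"` re-anchors.
Note the chi-square approximation of the log-rank test is mildly
anticonservative in small samples: at n = 20/arm with no censoring the
null rejection rate at α = 0.05 is ≈ 0.059 (the independent library gives
the same number on identical data).

## Exercise and qPCR assays

Treadmill distance integrates the incremental schedule — 3 min acclimation
at zero speed, 8 m/min start, +2.5 m/min every 3 min — to the exhaustion
time; work against gravity is `m·g·d·sin(incline)`. The incline is a
required parameter with no default: the protocol source does not state one,
and silently computing zero work at 0° would be misleading. Fatigue
detection is experimental metadata, not computed.

qPCR: `2^-ΔCt` relative expression (target minus reference-gene Ct,
normalized so the reference group's mean is exactly 1) and the ΔΔCt method
for relative content (e.g. mitochondrial vs nuclear target, re-centred on
the reference group's mean ΔCt). No amplification-efficiency correction is
applied. Ct values must lie in (0, 45).

## The synthetic generator

`cachemet.synthetic` emulates the study's data streams with an explicit
truth ledger:

* **REE**: sinusoid `ree_base·(1 + circadian_amp·cos(…))` peaking mid-dark;
  defaults 0.4 kcal/h and 15 % amplitude, typical of a ~30 g mouse.
* **Activity**: marked Poisson bursts (dark 12/h ≥ light 4/h, mean 3 m per
  exponential burst — step-like cumulative distance, ~0.5–0.7 km/day).
* **Energy**: `TEE(t) = REE(t) + cca_true·activity_rate(t)` exactly;
  `cca_true` defaults to 0.02 kcal/m, the value used throughout the
  validation suite. Gaussian noise (default 0.05 kcal/h, truncated at 0) is
  added on the energy-rate scale *before* inversion to gases — recovery
  properties are much easier to reason about than with per-gas noise.
* **Gases**: Weir-equation inversion at the bin's target RER (fed/dark vs
  fasted/light), so calorimetry round-trips to machine precision on
  noise-free traces.
* **Feeding**: ad-libitum intake Dirichlet-spread over dark bins
  (4 g/day ≈ 13.7 kcal); the calorie-restriction mode delivers a fixed
  2.33 g ration at the 18:00 dark onset.
* **Weights**: logistic rise to a peak (♂ ≈ 31.5 g, ♀ ≈ 28.5 g), then for
  animals drawn cachectic (penetrance 0.7, the model's typical rate) an
  exponential fractional decline (2 %/day ± 0.4) starting around day 42 ± 7.
  With these rates an animal crosses 15 % loss ~8 days after decline onset
  and reaches the 30 % endpoint ~10 days later, matching the observed 7–14
  day window between cachexia onset and endpoint. Onset and death days are
  referenced to the peak weight achievable on the weigh schedule, so the
  terminal observation realizes exactly 30 % observed loss. Animals whose
  crossing would fall beyond follow-up (120 days) are censored and counted
  non-cachectic over the observed course.
* **Trials**: arm effects perturb the post-enrollment decline rate (which
  moves both the End weight and the endpoint/death day), intake, body
  composition and activity; all-zero effects reduce to the base cohort.

Everything flows through a single seeded `numpy` generator; identical
(config, seed) inputs give bit-identical outputs.

**What the generator does not emulate**: tumor growth and lung mass, the
thermic effect of food (the decomposition has exactly two components by
design), temperature-dependent thermogenesis differences between 22 °C and
30 °C housing, weight-loss-dependent changes in CCA, drift or sensor
artifacts in gas traces, and behavioral correlations between feeding bouts
and activity bursts. Passing recovery tests therefore demonstrates the
estimators are correct under the stated generative assumptions — unbiased
slope recovery under circadian confounding, exact accounting identities,
calibrated test sizes — not that the assumptions hold in any particular
real cage system. At the defaults the simulated AEE share of TEE (~50 %) is
higher than in typical real mice; the validation constant 0.02 kcal/m is
kept because the recovery guarantees are scale-free.

## Problem sizes

The test suite and the acceptance script use 20–60 simulated animals, 3-day
traces at 5-min bins (864 bins/animal), 50-design ANCOVA sweeps, 1000-run
null calibrations, and 100-seed randomization checks; the full suite runs
in well under a minute on one CPU.

## Known limitations

* CCA standard errors ignore residual autocorrelation; they are labelled
  naive and should not be used for formal inference across animals.
* The GCV grid is fixed (1e-4…1e8); pathological series whose optimal λ
  lies outside it get the nearest endpoint.
* The studentized-range quadrature targets ~1e-6 absolute accuracy, ample
  for p-value reporting but not for extreme tail ratios.
* `sample_size_two_means` addresses the two-arm pooled-t design only; no
  multiplicity adjustment for three-arm trials is attempted.
* Block randomization balances within strata only; it does not constrain
  imbalance across strata for odd stratum sizes.
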