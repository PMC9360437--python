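# cachemet

Energy accounting and trial statistics for murine cancer anorexia-cachexia
(CACS) studies built on indirect-calorimetry metabolic cages.

In lung-cancer mouse models a large fraction of tumor-bearing animals become
cachectic — they lose more than 15 % of body weight from their peak — and the
loss is driven by falling food intake *and* falling energy expenditure.
Disentangling the two requires splitting total energy expenditure (TEE) into
its resting (REE) and activity (AEE) components, normalizing TEE to lean mass
across groups, classifying cachexia from serial weights, and, for
intervention studies, running a properly randomized trial with survival
analysis. `cachemet` implements that full quantitative workflow as a tested
library plus CLI, together with a synthetic-data generator that emulates cage
recordings with known ground truth so every stage can be validated.

## The core computations

**Energy expenditure.** Gas exchange is converted with the abbreviated Weir
equation, `EE [kcal/h] = 60·(3.941·VO₂ + 1.106·VCO₂)` (gases in L/min), and
the respiratory exchange ratio is `RER = VCO₂/VO₂`. Recordings have an
initial 24 h acclimation phase that is excluded from analysis by default.

**Energy partition.** For each animal the caloric cost of activity
(CCA, kcal per metre travelled) is the slope of total energy rate on
activity rate. The components are then

```
AEE(t) = CCA · activity_rate(t)        REE(t) = TEE(t) − AEE(t)
```

so `AEE + REE = TEE` holds bin-wise exactly. Component series are smoothed
with a degree-2 penalized B-spline (order-2 difference penalty, GCV-chosen
λ). Because resting expenditure is circadian and mice are more active in the
dark phase, the default CCA estimator fits the activity slope jointly with a
P-spline time-varying resting baseline, which removes the dark-phase
confounding; the plain fixed-intercept regression is also available.

**Group comparison.** TEE is normalized to lean mass by common-slope ANCOVA
(group indicators + one shared lean-mass slope); adjusted means are evaluated
at the grand-mean lean mass and compared pairwise with Tukey's studentized
range test. Student t-tests, one/two-way ANOVA, and Pearson correlation are
included.

**Cohort and trials.** Animals are +CACS if loss from peak exceeds 15 %
(strict); the humane endpoint is ≥ 30 % loss or body-composition score < 2.
Trials enroll animals when loss first enters 10–15 %, randomize in permuted
blocks of 6 stratified by sex, take percent weight change at 14 days as the
primary outcome (−30 % imputed for animals euthanized earlier), and analyze
survival from induction with Kaplan–Meier curves and the log-rank
(Mantel–Cox) test.

## Worked example

```python
import numpy as np
from cachemet import (SimConfig, simulate_cage_trace, daily_tee,
                      partition_trace, fit_ancova, tukey_pairwise)

cfg = SimConfig(cca_true=0.02, noise_sd=0.05)       # 3 days, 5-min bins
trace, truth = simulate_cage_trace(cfg, seed=1)
for d in daily_tee(trace):                          # acclimation excluded
    print(f"day {d.day}: TEE {d.tee:.2f} kcal, RER {d.mean_rer:.3f}, "
          f"intake {d.intake_kcal:.1f} kcal, {d.distance:.0f} m")
p = partition_trace(trace)
print(f"CCA {p.cca:.5f} kcal/m (true {truth.cca})")
print(f"REE {p.daily_ree_kcal():.2f} kcal/day  AEE {p.daily_aee_kcal():.2f} kcal/day")
```

prints

```
day 1: TEE 22.72 kcal, RER 0.835, intake 13.7 kcal, 655 m
day 2: TEE 19.76 kcal, RER 0.835, intake 13.7 kcal, 508 m
CCA 0.01998 kcal/m (true 0.02)
REE 9.62 kcal/day  AEE 11.45 kcal/day
```

The estimated caloric cost of activity recovers the generator's true value
(0.02 kcal/m) to 0.1 %, and the daily REE matches the simulated circadian
resting rate (0.4 kcal/h ≈ 9.6 kcal/day). A lean-mass ANCOVA on a simulated
three-group cohort:

```python
rng = np.random.default_rng(0)
group = np.repeat(["WT", "-CACS", "+CACS"], 10)
lean = rng.normal(22, 2, 30)
tee = 2.0 + 0.35*lean + (group == "+CACS")*-1.5 + rng.normal(0, 0.5, 30)
fit = fit_ancova(tee, lean, group)
print(tukey_pairwise(fit))
```

recovers the planted −1.5 kcal/day deficit of the cachectic group
(+CACS − −CACS adjusted difference −1.98 ± 0.20, Tukey p < 1e-4) while the
−CACS vs WT contrast is null (p = 0.28).

The same stages are scriptable from the shell:

```bash
cachemet simulate --seed 3 --out-dir sim/
cachemet calorimetry sim/trace_M001.tsv
cachemet partition sim/trace_M001.tsv
cachemet classify sim/weights.tsv
cachemet trial randomize sim/weights.tsv --arms ctrl,mab,combo --seed 1
cachemet treadmill --time 15 --mass 30 --incline 10
```

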