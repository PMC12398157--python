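# ppcvd — 10-year cardiovascular risk prediction in postpartum women

`ppcvd` is a desk-scale pipeline for developing, updating and validating
10-year cardiovascular disease (CVD) risk prediction models in women of
reproductive age who have been pregnant.  Real primary-care extracts for
this population are access-controlled, so the package ships a synthetic
cohort generator that reproduces the statistical structure such a cohort
exhibits — the predictor marginals, ~1% 10-year event fraction and
~3.7-year median follow-up of a UK primary-care population of women aged
15–49 followed from six months postpartum — and builds everything else on
top of it:

- **`ppcvd.cohort`** — synthetic cohorts from a proportional-hazards truth
  (exponential baseline, administrative + dropout censoring), MCAR
  missingness injection, and study-entry eligibility filters with a
  flow-diagram log.
- **`ppcvd.riskeq`** — QRISK-style risk equations: fractional-polynomial
  transforms, linear predictors `η = Σβx`, and absolute risk
  `π = 1 − S₀(t)^exp(η − c)` from a baseline survival value; equations load
  from YAML (no proprietary coefficients are bundled).
- **`ppcvd.impute`** — the single-imputation policy (age-band means for
  clinical measurements, non-smoker / white / median-deprivation defaults,
  absent-means-no for condition flags) and the ≥40%-missing exclusion rule.
- **`ppcvd.develop`** — Cox fitting (Efron ties, offsets), Breslow baseline
  survival, closed-test fractional-polynomial selection, LASSO-Cox variable
  selection with forced-in predictors (selection-only: the reported model is
  always an unpenalised refit), and offset-based baseline recalibration.
- **`ppcvd.validate`** — Harrell's C, Uno's time-dependent C, Royston's D
  and R²_D, O/E, jackknife pseudo-values, cloglog pseudo-value calibration
  intercept/slope, percentile calibration curves, subgroup metrics, and
  decision-curve net benefit.
- **`ppcvd.internal`** — bootstrap optimism correction that replays the
  entire modelling recipe (selection included) per resample, and
  `run_study`, which executes the whole study graph.

## The statistics at the core

For a Cox model with linear predictor η and Breslow baseline survival
S₀(t), the predicted 10-year risk is `π_i = 1 − S₀(10)^exp(η_i − c)`.
Observed 10-year risk under censoring is carried per subject by jackknife
pseudo-values `PV_i = n·F̂(10) − (n−1)·F̂₋ᵢ(10)` of the Kaplan–Meier
cumulative incidence.  Calibration regresses PV on cloglog(π) with a
cloglog link: the offset form gives the calibration intercept (0 is ideal;
negative means predictions too high) and the free-coefficient form the
calibration slope (1 is ideal; <1 indicates overfitting).  Mean calibration
is the O/E ratio; discrimination is summarised by Harrell's C and Royston's
D, with `R²_D = (D²/κ²)/(π²/6 + D²/κ²)`, `κ² = 8/π`.  Clinical utility is
decision-curve net benefit `NB(p_t) = TP − FP·p_t/(1−p_t)` with
Kaplan–Meier event probabilities among test-positives.

## Worked example

```python
from ppcvd.cohort import generate_cohort
from ppcvd.defaults import default_spec, benchmark_equation
from ppcvd.develop import recalibrate_baseline
from ppcvd.riskeq import linear_predictor, predicted_risk
from ppcvd.validate import performance_report

cohort = generate_cohort(default_spec(n=100_000, seed=2024, missingness=False))
bench = benchmark_equation()            # deliberately under-predicting benchmark
lp = linear_predictor(cohort, bench)
risk = predicted_risk(lp, bench)
rep = performance_report(cohort, lp, risk, horizon=10.0)
print(f"C {rep.harrell_c.value:.3f}  D {rep.royston_d.value:.3f}  "
      f"O/E {rep.oe.value:.3f}  slope {rep.slope.value:.3f}")

recal = recalibrate_baseline(lp, cohort, bench, horizon=10.0)
risk2 = predicted_risk(lp, recal)
print(f"recalibrated O/E {performance_report(cohort, lp, risk2, 10.0).oe.value:.3f}")
```

prints (seed 2024):

```
C 0.695  D 1.163  O/E 1.370  slope 0.981
recalibrated O/E 1.001
```

The benchmark discriminates (C ≈ 0.70) but under-predicts by ~27% on
average (O/E 1.37); re-estimating only the baseline survival by offset Cox
regression restores mean calibration (O/E 1.00) without touching the
predictor effects.

## The analysis

Numbered drivers under `analysis/` walk the full study and write their
tables under `results/`:

1. `01_simulate_cohort.py` — simulate the population, apply eligibility
   filters, report the exclusion log and baseline characteristics.
2. `02_external_validation.py` — validate the benchmark equation
   (discrimination, pseudo-value calibration, decision curves), then
   recalibrate its baseline and re-validate.
3. `03_develop_models.py` — develop Model 1 (benchmark linear predictor as
   two cubic FP terms + pregnancy/reproductive candidates), Model 2a
   (established predictors refit) and Model 2b (established + candidates),
   with LASSO selection and forced-in predictors.
4. `04_internal_validation.py` — bootstrap optimism correction replaying
   the whole Model 2b recipe per resample.
5. `05_recovery_experiments.py` — generator-fidelity experiments
   (hazard-ratio recovery, in-sample calibration slope, recalibration O/E,
   null optimism).

A `ppcvd` CLI (`simulate`, `score`, `develop`, `validate`, `run`) wraps the
same library for shell use.

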