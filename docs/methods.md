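# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limits of what the package's tests demonstrate.

## The problem

Risk equations such as QRISK predict an individual's 10-year risk of a
first cardiovascular event from established risk factors.  In women of
reproductive age who have been pregnant, pregnancy complications
(pre-eclampsia, gestational hypertension and diabetes, stillbirth,
miscarriage) and reproductive factors (PCOS, endometriosis, gravidity) are
known to carry additional hazard.  The pipeline implemented here (a) scores
and externally validates a benchmark risk equation in a postpartum cohort,
(b) updates it — first by recalibrating only its baseline survival, then by
refitting and extending it with pregnancy/reproductive predictors — and
(c) validates the updated models internally with bootstrap optimism
correction.

## Synthetic cohort generator

Because the motivating data (a UK primary-care cohort of 567,667 women aged
15–49 followed from six months postpartum) cannot be redistributed, the
generator emulates its published statistical structure:

- **Marginals.** Binary predictor prevalences, continuous means/SDs, the
  gravidity distribution (with the "5 or more" tail drawn uniformly on
  5–10) and smoking/ethnicity category frequencies are the cohort's
  baseline characteristics.  Continuous predictors are truncated normals;
  the parent parameters are solved numerically so the *truncated*
  distribution attains the target mean and SD (naive truncation would
  shrink the age SD by ~4%).  Skewed laboratory-style variables
  (cholesterol ratio, SBP variability) are log-normal with the reported
  medians and IQR-derived log-SDs.  Predictors are independent by default;
  the published tables report only marginals, so any correlation structure
  would be invented.
- **Event times.** Proportional hazards with an exponential baseline:
  `T* ~ Exp(λ₀ · exp(η − c))`, where η uses the full-model hazard ratios
  (established + pregnancy/reproductive factors) as the generating truth.
  The four predictors the source selection dropped (preterm birth, SGA,
  irregular menses, placental abruption) are generated but carry zero true
  effect, so selection tests have honest null candidates.  `c = 4.6936` is
  the population mean linear predictor and `λ₀ = 7.81e-4`/year was
  calibrated once (2,000,000-draw evaluation) so the marginal 10-year
  cumulative incidence is 1% — between the two event fractions the source
  reports (0.38% within 10 years, 0.98% during follow-up) and configurable.
- **Censoring.** Administrative time to end-of-study uniform on
  [0.5, 21] years, capped at the 10-year horizon — leaving ~13% of
  subjects censored exactly at 10 years, as a long recruitment window
  produces — plus exponential dropout at 0.1437/year, jointly tuned to the
  reported 3.66-year median follow-up.  A uniform-to-horizon design with no
  mass at 10 years was rejected: it sends the censoring survival G(10⁻) to
  zero and makes every horizon-anchored estimate (pseudo-values, O/E)
  needlessly unstable, which real cohorts of this kind do not exhibit.
- **Missingness.** MCAR at the reported per-predictor rates (e.g. 91% for
  the cholesterol ratio, 40% for SBP variability).  The source data are
  likely missing-not-at-random; MCAR is the weakest assumption that
  reproduces the reported proportions.
- **Determinism.** All draws flow from one root seed through named
  substreams; identical specs give byte-identical CSVs.

What passing tests on this generator do **not** show: performance on real
data with correlated predictors, informative missingness, practice-level
clustering, or coding artefacts.  Absolute metric values (C ≈ 0.70 under
the defaults) depend on the generator's effect sizes and are not external
validity claims.

## Risk equations

A `CoefficientSet` is a named list of design terms (linear, dummy contrast,
or fractional-polynomial column), log-hazard coefficients, a centering
constant, the horizon, and `S₀(t)`.  Fractional polynomials follow the
Royston–Sauerbrei conventions: powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3},
power 0 meaning ln, a repeated power contributing an `x^p ln x` column;
variables may be shifted and scaled first (e.g. age/10, (SBP/100)²,
(LP + 4)³).  Inputs that violate the transform's domain raise rather than
clamp — the benchmark's cubic LP terms presume LP > −4, and silently
clamping would hide a transport problem.  Predicted risk is
`π = 1 − S₀(t)^exp(η − c)`, giving the exact identity
`cloglog(π) = ln(−ln S₀) + (η − c)` on which the calibration machinery
rests (risks are clamped to [1e−10, 1−1e−10] before cloglog).

## Missing-data policy

Single imputation: 5-year age-band means for SBP, BMI and cholesterol
ratio (the source imputes "based on age and sex"; all subjects are women,
and the band width is configurable), non-smoker for missing smoking, white
for missing ethnicity, cohort median for deprivation, and absence for
missing condition flags.  Candidate predictors with ≥ 40% missingness are
excluded from development.  The strict reading of "more than 40%" would be
a > rule; the ≥ convention is used because the 40%-missing SBP-variability
predictor is in fact excluded in the motivating analysis, and the
convention is configurable.  Complete-case analysis is available as a
pipeline flag.

## Model development

- **Cox fitting** delegates partial-likelihood maximisation to statsmodels
  `PHReg` (Newton, Efron ties, offset support) on internally standardised
  columns for conditioning; coefficients and covariances are mapped back.
  If Newton overshoots (near-separation, collinear FP pairs), BFGS walks in
  and Newton restarts from there.  Binary predictors with zero events in
  one arm have infinite MLEs; they are detected up front, fixed at a capped
  coefficient (|β| = 15) with a warning, and the rest refit conditionally.
  Convergence demands a score norm below 1e−3·(event count).
- **Breslow baseline.** `Ĥ₀(t) = Σ_{t_j ≤ t} d_j / Σ_{at risk} exp(η − c)`
  with centering at the fit-time mean LP, so S₀ is invariant to covariate
  location shifts.  Recalibration fits the cohort with a fixed external LP
  as offset and no free terms, and substitutes the resulting S₀(10) (and
  centering) into the template equation.
- **FP selection** is the standard closed test at α = 0.05: best FP2 by
  partial likelihood vs omission (4 df), vs linear (3 df), vs best FP1
  (2 df).  The pipeline fixes the FP forms before variable selection and
  does not re-select them inside bootstrap resamples (a flag exists).
- **LASSO selection** uses scikit-survival's coxnet with penalty factor 0
  on forced terms and 1 on candidates, an automatic 50-point path, and
  10-fold cross-validated partial likelihood (Verweij–van Houwelingen form)
  at its maximum; fold assignment is seeded.  The LASSO is selection-only:
  the reported model is an unpenalised refit on forced ∪ selected.  Folds
  whose training half cannot be fitted (separation of an unpenalised
  column) are skipped under a bounded iteration cap; when the full
  unpenalised block itself cannot enter coxnet, the forced terms are
  condensed into a single unpenalised probe-LP column for the selection
  stage only — the final refit always carries every forced term.

## Validation measures

- **Harrell's C** from scikit-survival's pair counts (predictor ties count
  ½); the CI uses a Hanley–McNeil-type SE with events as cases — a fast
  approximation chosen because the exact Noether variance needs
  triple-order pair counts.
- **Time-dependent C** is Uno's IPCW concordance truncated at the horizon
  (the estimator behind "time-dependent C statistic" is not unique; Uno's
  is the standard horizon-anchored choice and is stated here so external
  comparisons are like-for-like).
- **Royston's D**: ranks of the LP mapped to Blom normal scores, divided by
  κ = √(8/π), used as the single covariate of a Cox fit; D is its
  coefficient and `R²_D = (D²/κ²)/(π²/6 + D²/κ²)` exactly.
- **Pseudo-values** use a closed-form leave-one-out Kaplan–Meier update
  (prefix/suffix products over event-time blocks) rather than n refits;
  brute-force jackknife oracles verify it to 1e−10, ties included.  Their
  mean equals the KM cumulative incidence exactly whenever the KM estimate
  stays positive through the horizon; if the risk set is exhausted by an
  event (KM hits zero — impossible in this application's ~1%-risk regime)
  the identity degrades, which the tests document.
- **Calibration intercept/slope** come from a quasi-likelihood GLM with
  cloglog link fitted by damped Newton with sandwich SEs (pseudo-values lie
  outside [0,1], so standard binomial GLM implementations refuse them; the
  quasi-score needs only the mean-variance relation).  The offset form
  yields the intercept, the free form the slope.
- **O/E** is KM cumulative incidence over mean predicted risk, CI by the
  delta method on log O with Greenwood variance.
- **Net benefit** uses the survival construction with KM estimates among
  test-positives, thresholds on an 0.01-step grid; treat-none is
  identically zero, treat-all tends to the KM incidence as the threshold
  goes to zero.
- **Subgroups** recompute every metric within group; groups with fewer than
  10 events are flagged low-information, zero-event groups report
  undefined.

## Internal validation

Bootstrap optimism: each replicate resamples subjects with replacement,
replays the entire recipe — LASSO selection included — and the optimism is
the in-resample minus on-original difference, averaged over replicates;
adjusted = apparent − mean optimism, reported for C, D and the calibration
slope.  Replicates that fail (zero events, degenerate resample) are logged
and skipped.  The production default is B = 500; the analysis drivers and
tests use B = 20–50 at smaller n, which leaves the optimism estimate
unbiased but noisier.

## Problem sizes

The test suite and acceptance script run at desk scale: marginal checks at
n = 100,000, parameter recovery at n = 300,000 (horizon-only censoring, the
cleanest design for recovery), calibration and recalibration properties at
n = 200,000, optimism at n = 50,000 with B = 50, and the end-to-end study
smoke test at n = 2,500 with B = 2.  The analysis drivers use n = 100,000
with flow-diagram ineligibility for the study narrative and n = 15,000 at a
3% event fraction for the bootstrap stage.

## Known limitations

Independent predictors (optional correlation is not exercised by default);
MCAR missingness only; no multiple imputation or Rubin pooling; no
competing risks, time-varying effects, PH diagnostics or practice-level
random effects; the benchmark equation is synthetic (constructed from the
generating truth with a deflated baseline), not a published coefficient
set.
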