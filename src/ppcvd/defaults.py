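"""Default study conditions for the synthetic postpartum cohort.

The marginal predictor distributions, missingness proportions, median
follow-up target and event fraction emulate the baseline characteristics
table of a UK primary-care cohort of 567,667 women aged 15-49 followed from
six months postpartum; the data-generating log-hazards are the logs of the
adjusted hazard ratios of the full (established + pregnancy/reproductive
factor) Cox model reported for that cohort.  Everything here is a default:
callers can override any element of the returned spec.
"""

from __future__ import annotations

import numpy as np

from .config import Censoring, ContinuousSpec, SimulationSpec
from .riskeq import CoefficientSet, Term

__all__ = [
    "default_spec",
    "truth_terms",
    "TRUE_HAZARD_RATIOS",
    "BINARY_PREVALENCES",
    "MISSINGNESS_RATES",
    "FIG1_INELIGIBILITY",
    "ESTABLISHED_TERMS",
    "PREGNANCY_CANDIDATE_TERMS",
    "LP_CENTER",
    "BASELINE_RATE",
    "benchmark_equation",
]

# Binary predictor prevalences (fraction of cohort with the condition).
BINARY_PREVALENCES: dict[str, float] = {
    "famhist_cvd": 0.0323,
    "af": 0.0006,
    "migraine": 0.0903,
    "ra": 0.0024,
    "ckd": 0.0007,
    "smi": 0.0094,
    "sle": 0.0012,
    "diabetes1": 0.0026,
    "diabetes2": 0.0042,
    "antipsychotics": 0.0028,
    "corticosteroids": 0.0027,
    "antihypertensives": 0.0031,
    "preeclampsia": 0.0329,
    "gest_htn": 0.0299,
    "sga": 0.0615,
    "postnatal_depression": 0.0541,
    "gdm": 0.0286,
    "stillbirth": 0.0093,
    "miscarriage": 0.2238,
    "preterm_birth": 0.0414,
    "placental_abruption": 0.0052,
    "endometriosis": 0.0220,
    "irregular_menses": 0.1191,
    "pcos": 0.0375,
}

CONTINUOUS: dict[str, ContinuousSpec] = {
    "age": ContinuousSpec(32.01, 6.63, lower=15.0, upper=49.0),
    "sbp": ContinuousSpec(115.16, 12.72, lower=70.0, upper=210.0),
    "bmi": ContinuousSpec(25.68, 5.71, lower=13.0, upper=60.0),
    # right-skewed lab-style variables: log-normal, parameters on log scale
    # (medians 8.37 and 3.23; sigma from the IQR width)
    "sbp_sd": ContinuousSpec(float(np.log(8.37)), 0.511, log_scale=True),
    "tchdl": ContinuousSpec(float(np.log(3.23)), 0.292, log_scale=True),
}

ORDINAL: dict[str, dict] = {
    "gravidity": {1: 0.452, 2: 0.272, 3: 0.143, 4: 0.072, "5+": 0.061},
    "townsend": {1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2},
}

CATEGORICAL: dict[str, dict[str, float]] = {
    "ethnicity": {"white": 0.798, "black": 0.075, "asian": 0.062, "mixed": 0.014, "other": 0.051},
    "smoking": {"non": 0.660, "ex": 0.151, "current": 0.189},
}

# Hazard ratios of the data-generating model (full model: established CVD
# risk factors plus pregnancy and reproductive factors).  Predictors that
# the source selection dropped (preterm birth, SGA, irregular menses,
# placental abruption) are generated but carry no true effect.
TRUE_HAZARD_RATIOS: dict[str, float] = {
    "age_10": 2.04,
    "bmi_10": 1.29,
    "sbp_100_sq": 1.83,
    "townsend": 1.18,
    "famhist_cvd": 1.48,
    "eth_black": 1.54,
    "eth_mixed": 1.24,
    "eth_asian": 1.19,
    "eth_other": 0.90,
    "smoke_ex": 0.89,
    "smoke_current": 1.73,
    "af": 2.79,
    "migraine": 1.58,
    "ra": 1.02,
    "ckd": 3.82,
    "smi": 1.89,
    "sle": 3.50,
    "diabetes1": 5.30,
    "diabetes2": 3.94,
    "antipsychotics": 0.98,
    "corticosteroids": 1.67,
    "antihypertensives": 1.32,
    "preeclampsia": 1.52,
    "postnatal_depression": 1.33,
    "gdm": 1.18,
    "gest_htn": 1.34,
    "miscarriage": 1.16,
    "stillbirth": 1.37,
    "gravidity": 1.07,
    "endometriosis": 1.56,
    "pcos": 1.41,
}

MISSINGNESS_RATES: dict[str, float] = {
    "sbp": 0.16,
    "sbp_sd": 0.40,
    "bmi": 0.24,
    "tchdl": 0.91,
    "smoking": 0.18,
    "townsend": 0.0011,
}

# Eligibility-violation rates shaped like the study's flow diagram
# (fractions of the pre-filter population).
FIG1_INELIGIBILITY: dict[str, float] = {
    "age_outside_range": 0.0012,
    "statins": 0.0031,
    "died_before_index": 0.0005,
    "left_practice": 0.1700,
    "last_collection_before_index": 0.0703,
    "prior_cvd": 0.0013,
}


def _established_terms() -> list[Term]:
    return [
        Term("age_10", "fp", "age", power=1.0, divisor=10.0),
        Term("bmi_10", "fp", "bmi", power=1.0, divisor=10.0),
        Term("sbp_100_sq", "fp", "sbp", power=2.0, divisor=100.0),
        Term("townsend", "linear", "townsend"),
        Term("famhist_cvd", "linear", "famhist_cvd"),
        Term("eth_black", "indicator", "ethnicity", equals="black"),
        Term("eth_mixed", "indicator", "ethnicity", equals="mixed"),
        Term("eth_asian", "indicator", "ethnicity", equals="asian"),
        Term("eth_other", "indicator", "ethnicity", equals="other"),
        Term("smoke_ex", "indicator", "smoking", equals="ex"),
        Term("smoke_current", "indicator", "smoking", equals="current"),
        Term("af", "linear", "af"),
        Term("migraine", "linear", "migraine"),
        Term("ra", "linear", "ra"),
        Term("ckd", "linear", "ckd"),
        Term("smi", "linear", "smi"),
        Term("sle", "linear", "sle"),
        Term("diabetes1", "linear", "diabetes1"),
        Term("diabetes2", "linear", "diabetes2"),
        Term("antipsychotics", "linear", "antipsychotics"),
        Term("corticosteroids", "linear", "corticosteroids"),
        Term("antihypertensives", "linear", "antihypertensives"),
    ]


def _pregnancy_terms(selected_only: bool = True) -> list[Term]:
    names = [
        "preeclampsia",
        "postnatal_depression",
        "gdm",
        "gest_htn",
        "miscarriage",
        "stillbirth",
        "gravidity",
        "endometriosis",
        "pcos",
    ]
    if not selected_only:
        names += ["preterm_birth", "sga", "irregular_menses", "placental_abruption"]
    return [Term(n, "linear", n) for n in names]


ESTABLISHED_TERMS: list[Term] = _established_terms()
PREGNANCY_CANDIDATE_TERMS: list[Term] = _pregnancy_terms(selected_only=False)


def truth_terms() -> list[Term]:
    """Design terms of the data-generating model (true-effect terms only)."""
    return _established_terms() + _pregnancy_terms(selected_only=True)


# Calibration constants of the default data-generating process, frozen from
# a one-off large-sample evaluation of the default marginals (see
# docs/methods.md): LP_CENTER is the population mean linear predictor and
# BASELINE_RATE the exponential event rate (per person-year, at the LP
# center) that gives a marginal 10-year cumulative incidence of 1%.
LP_CENTER: float = 4.693622
BASELINE_RATE: float = 7.8146e-04


def default_spec(
    n: int,
    seed: int = 0,
    *,
    missingness: bool = True,
    censoring: Censoring | None = Censoring(),
    ineligibility: dict[str, float] | None = None,
    incidence_10yr: float | None = None,
) -> SimulationSpec:
    """Build the default study-condition simulation spec.

    Parameters
    ----------
    missingness : include the table-style missingness rates (MCAR).
    censoring : censoring config; ``None`` disables everything but the
        horizon (parameter-recovery experiments).
    ineligibility : flow-diagram violation rates, e.g. ``FIG1_INELIGIBILITY``.
    incidence_10yr : override the marginal 10-year cumulative incidence
        (baseline rate is scaled proportionally, accurate for rare events).
    """
    rate = BASELINE_RATE
    if incidence_10yr is not None:
        rate = BASELINE_RATE * incidence_10yr / 0.01
    return SimulationSpec(
        n=n,
        binary_predictors=dict(BINARY_PREVALENCES),
        continuous_predictors=dict(CONTINUOUS),
        ordinal_predictors={k: dict(v) for k, v in ORDINAL.items()},
        categorical_predictors={k: dict(v) for k, v in CATEGORICAL.items()},
        truth_terms=truth_terms(),
        true_log_hazards={k: float(np.log(v)) for k, v in TRUE_HAZARD_RATIOS.items()},
        baseline_rate=rate,
        lp_center=LP_CENTER,
        horizon=10.0,
        censoring=censoring if censoring is not None else Censoring(np.inf, np.inf, 0.0),
        missingness_rates=dict(MISSINGNESS_RATES) if missingness else {},
        ineligibility_rates=dict(ineligibility or {}),
        seed=seed,
    )


def benchmark_equation(miscalibration: float = 0.75) -> CoefficientSet:
    """Synthetic external benchmark equation (stand-in for a published
    general-population risk score; no published coefficients are bundled).

    Uses the true log-hazards with a baseline cumulative hazard scaled by
    ``miscalibration`` (< 1 under-predicts, motivating recalibration).
    """
    h10 = BASELINE_RATE * 10.0  # 10-year cumulative hazard at the LP center
    return CoefficientSet(
        name="benchmark",
        terms=truth_terms(),
        coefficients={k: float(np.log(v)) for k, v in TRUE_HAZARD_RATIOS.items()},
        baseline_survival=float(np.exp(-miscalibration * h10)),
        centering=LP_CENTER,
        horizon=10.0,
    )
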