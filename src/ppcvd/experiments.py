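"""Canned simulation experiments shared by the analysis drivers, the test
suite, and the acceptance script.

Each experiment regenerates its inputs from the default study conditions
and a caller-supplied seed, runs the relevant part of the pipeline, and
returns plain numbers, so results are reproducible from (experiment, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import generate_cohort, substream
from .defaults import TRUE_HAZARD_RATIOS, benchmark_equation, default_spec, truth_terms
from .develop import fit_cox, recalibrate_baseline
from .internal import ModelRecipe, bootstrap_optimism
from .riskeq import linear_predictor, predicted_risk
from .validate import calibration_intercept_slope, oe_ratio, pseudo_values

__all__ = [
    "hazard_recovery",
    "insample_calibration_slope",
    "recalibration_oe",
    "null_optimism",
]


def hazard_recovery(n: int = 300_000, seed: int = 0) -> pd.DataFrame:
    """Simulate a cohort from the default truth and refit the full model.

    No dropout or administrative censoring is applied (only the 10-year
    horizon), the cleanest design for parameter recovery.  Returns the
    hazard-ratio table with the true values and z-scores attached.
    """
    spec = default_spec(n=n, seed=seed, missingness=False, censoring=None)
    df = generate_cohort(spec)
    model = fit_cox(df, truth_terms())
    out = model.hazard_ratios()
    out["hr_true"] = [TRUE_HAZARD_RATIOS[k] for k in out.index]
    out["z"] = (out["coef"] - np.log(out["hr_true"])) / out["se"]
    return out


def insample_calibration_slope(n: int = 200_000, seed: int = 0) -> dict[str, float]:
    """Fit the full model and calibrate it against its own development data.

    Predicted 10-year risks come from the fitted model's Breslow baseline;
    observed risks are jackknife pseudo-values; the slope is the free
    coefficient of the cloglog-transformed predictions in the pseudo-value
    GLM.  A well-specified in-sample fit gives slope ~ 1 and intercept ~ 0.
    """
    spec = default_spec(n=n, seed=seed, missingness=False)
    df = generate_cohort(spec)
    model = fit_cox(df, truth_terms(), estimate_baseline=True, horizon=10.0)
    cs = model.to_coefficient_set("refit", 10.0)
    lp = model.predict_lp(df).to_numpy()
    risk = predicted_risk(lp, cs).to_numpy()
    pv = pseudo_values(df["time"].to_numpy(), df["event"].to_numpy(), 10.0)
    intercept, slope = calibration_intercept_slope(pv, risk)
    return {
        "slope": slope.value,
        "slope_se": slope.se,
        "intercept": intercept.value,
        "n_events": int(df["event"].sum()),
    }


def recalibration_oe(
    n: int = 200_000, seed: int = 0, miscalibration: float = 0.75
) -> dict[str, float]:
    """Score with a miscalibrated benchmark, recalibrate its baseline by
    offset Cox regression, and measure O/E before and after."""
    spec = default_spec(n=n, seed=seed, missingness=False)
    df = generate_cohort(spec)
    bench = benchmark_equation(miscalibration)
    lp = linear_predictor(df, bench).to_numpy()
    time, event = df["time"].to_numpy(), df["event"].to_numpy()
    oe_before = oe_ratio(predicted_risk(lp, bench).to_numpy(), time, event, 10.0)
    recal = recalibrate_baseline(lp, df, bench, horizon=10.0)
    oe_after = oe_ratio(predicted_risk(lp, recal).to_numpy(), time, event, 10.0)
    return {"oe_before": oe_before.value, "oe_after": oe_after.value,
            "n_events": int(event.sum())}


def null_optimism(
    n: int = 50_000, B: int = 50, seed: int = 0
) -> dict[str, float]:
    """Bootstrap optimism of a small fixed model at a large events-per-
    parameter ratio: with no selection and n >> parameters, the mean
    optimism in C should be negligible."""
    from .riskeq import Term

    terms = [
        Term("age_10", "fp", "age", power=1.0, divisor=10.0),
        Term("smoke_current", "indicator", "smoking", equals="current"),
        Term("preeclampsia", "linear", "preeclampsia"),
    ]
    spec = default_spec(n=n, seed=seed, missingness=False, censoring=None)
    df = generate_cohort(spec)
    recipe = ModelRecipe("null-optimism", forced=terms, candidates=[], use_lasso=False)
    rep = bootstrap_optimism(df, recipe, B=B, seed=seed)
    return {
        "apparent_c": rep.apparent["harrell_c"],
        "optimism_c": rep.optimism["harrell_c"],
        "adjusted_c": rep.adjusted["harrell_c"],
        "completed": rep.completed,
    }
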