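"""Missing-data policy: single imputation and high-missingness exclusion.

The policy mirrors common practice for risk-equation implementation in
primary-care data: continuous clinical measurements are imputed within age
bands (all subjects here are women, so age alone defines the band), missing
smoking status is taken as non-smoker, missing ethnicity as white, missing
deprivation as the cohort median, and an absent condition record means the
condition is absent.  Candidate predictors whose missing proportion reaches
a threshold (default 40%) are excluded from model development altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import EVENT_COL, TIME_COL

__all__ = ["ImputationPolicy", "default_policy", "single_impute",
           "drop_high_missingness", "complete_case", "missing_report"]

_NON_PREDICTORS = {
    "subject_id", TIME_COL, EVENT_COL,
    "statins", "died_before_index", "left_practice",
    "last_collection_before_index", "prior_cvd",
}


@dataclass
class ImputationPolicy:
    """Per-predictor imputation rules.

    Rules: ``age_band_mean`` (mean of non-missing values in the subject's
    age band), ``median`` (cohort median), ``constant:<value>`` (fixed
    fill, e.g. ``constant:non`` for smoking), ``zero`` (condition flags).
    """

    rules: dict[str, str] = field(default_factory=dict)
    age_band_width: float = 5.0
    age_column: str = "age"
    drop_threshold: float = 0.40
    drop_inclusive: bool = True  # >= threshold drops (see methods note)
    exempt_from_drop: tuple[str, ...] = ()

    def validate(self) -> None:
        if not 0 < self.drop_threshold <= 1:
            raise ValueError("drop threshold must be in (0, 1]")
        if self.age_band_width <= 0:
            raise ValueError("age band width must be > 0")


def default_policy() -> ImputationPolicy:
    return ImputationPolicy(
        rules={
            "sbp": "age_band_mean",
            "bmi": "age_band_mean",
            "tchdl": "age_band_mean",
            "sbp_sd": "age_band_mean",
            "smoking": "constant:non",
            "ethnicity": "constant:white",
            "townsend": "median",
        },
        age_band_width=5.0,
    )


def _fill(df: pd.DataFrame, col: str, rule: str, policy: ImputationPolicy) -> pd.Series:
    s = df[col]
    if rule == "age_band_mean":
        if policy.age_column not in df.columns:
            raise KeyError(f"age-band imputation of {col!r} needs column {policy.age_column!r}")
        bands = np.floor(df[policy.age_column] / policy.age_band_width)
        band_means = s.groupby(bands).transform("mean")
        out = s.fillna(band_means)
        return out.fillna(s.mean())  # bands with no observed values
    if rule == "median":
        return s.fillna(s.median())
    if rule == "zero":
        return s.fillna(0)
    if rule.startswith("constant:"):
        raw = rule.split(":", 1)[1]
        try:
            value: object = float(raw)
        except ValueError:
            value = raw
        return s.fillna(value)
    raise ValueError(f"unknown imputation rule {rule!r} for {col!r}")


def single_impute(cohort: pd.DataFrame, policy: ImputationPolicy | None = None) -> pd.DataFrame:
    """Fill every missing predictor value once, per the policy.

    Predictors with missing entries but no rule raise; condition-style
    integer flags default to rule ``zero`` (no record means absent).
    Imputation is idempotent and never alters an observed value.
    """
    policy = policy or default_policy()
    policy.validate()
    out = cohort.copy()
    for col in out.columns:
        if col in _NON_PREDICTORS or not out[col].isna().any():
            continue
        rule = policy.rules.get(col)
        if rule is None:
            # a condition flag with no record indicates absence
            if out[col].dropna().isin([0, 1, 0.0, 1.0]).all():
                rule = "zero"
            else:
                raise ValueError(f"predictor {col!r} has missing values but no imputation rule")
        out[col] = _fill(out, col, rule, policy)
    return out


def missing_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Proportion missing per predictor column (descending)."""
    cols = [c for c in cohort.columns if c not in _NON_PREDICTORS]
    prop = cohort[cols].isna().mean().sort_values(ascending=False)
    out = prop.rename("proportion_missing").reset_index()
    return out.rename(columns={"index": "predictor"})


def drop_high_missingness(
    cohort: pd.DataFrame,
    threshold: float = 0.40,
    *,
    inclusive: bool = True,
    exempt: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, list[str]]:
    """Remove candidate predictors with too much missing data.

    A predictor is dropped when its missing proportion is >= the threshold
    (or > with ``inclusive=False``).  Returns the reduced table and the
    names dropped; an empty drop list is a valid outcome.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    rep = missing_report(cohort).set_index("predictor")["proportion_missing"]
    if inclusive:
        dropped = [c for c, p in rep.items() if p >= threshold and c not in exempt]
    else:
        dropped = [c for c, p in rep.items() if p > threshold and c not in exempt]
    return cohort.drop(columns=dropped), dropped


def complete_case(cohort: pd.DataFrame, predictors: list[str] | None = None) -> pd.DataFrame:
    """Keep only rows with no missing value in the modelled predictors."""
    cols = predictors or [c for c in cohort.columns if c not in _NON_PREDICTORS]
    return cohort.dropna(subset=[c for c in cols if c in cohort.columns]).reset_index(drop=True)
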