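"""Synthetic postpartum cohort generation.

Cohorts mimic a primary-care population of women aged 15-49 followed from
six months postpartum for a first cardiovascular event.  Predictors are
drawn independently from configured marginals (binary prevalences,
truncated-normal continuous variables, ordinal and categorical
distributions), event times come from an exponential-baseline proportional
hazards model, and censoring combines a uniform administrative window, an
exponential dropout process, and the follow-up horizon.

All randomness flows from the spec's root seed through named substreams, so
every operation is a pure function of (inputs, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import Censoring, ConfigError, SimulationSpec
from .riskeq import build_design

__all__ = [
    "substream",
    "generate_cohort",
    "simulate_survival",
    "inject_missingness",
    "apply_eligibility_filters",
    "EligibilityRule",
    "ExclusionLog",
    "DEFAULT_ELIGIBILITY",
    "write_cohort",
    "read_cohort",
]

TIME_COL = "time"
EVENT_COL = "event"

ELIGIBILITY_FLAGS = (
    "statins",
    "died_before_index",
    "left_practice",
    "last_collection_before_index",
    "prior_cvd",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for a named operation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@lru_cache(maxsize=64)
def _truncnorm_parent(mean: float, sd: float, lower: float, upper: float):
    """Parent (mu, sigma) whose [lower, upper]-truncated normal has the
    requested mean and SD.  Plain truncation would deflate the SD, so the
    configured Table-style marginals would not be recovered."""
    if not np.isfinite(lower) and not np.isfinite(upper):
        return mean, sd

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - pathological bounds
        raise ConfigError(
            f"could not match truncated-normal moments for mean={mean}, sd={sd}, "
            f"bounds=({lower}, {upper})"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_continuous(rng, n, spec) -> np.ndarray:
    if spec.log_scale:
        return np.exp(rng.normal(spec.mean, spec.sd, size=n))
    mu, sigma = _truncnorm_parent(spec.mean, spec.sd, spec.lower, spec.upper)
    if not np.isfinite(spec.lower) and not np.isfinite(spec.upper):
        return rng.normal(mu, sigma, size=n)
    a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma
    # inverse-CDF sampling keeps the draw count fixed (determinism)
    return stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=mu, scale=sigma)


def _draw_ordinal(rng, n, levels: dict) -> np.ndarray:
    """Ordinal draw; a key like '5+' is an open top category sampled
    uniformly from {5, ..., 10} (grand multiparity tail)."""
    keys = list(levels.keys())
    probs = np.array([levels[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=n, p=probs / probs.sum())
    out = np.empty(n, dtype=float)
    for j, key in enumerate(keys):
        mask = idx == j
        if isinstance(key, str) and key.endswith("+"):
            k = int(key[:-1])
            out[mask] = rng.integers(k, k + 6, size=mask.sum())
        else:
            out[mask] = float(key)
    return out


def simulate_survival(
    lp: np.ndarray,
    baseline_rate: float,
    censoring: Censoring | None,
    horizon: float,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) from an exponential-baseline PH model.

    Latent event times are Exponential(rate = baseline_rate * exp(lp));
    observed time is the minimum of the latent time, the administrative
    censoring draw, the dropout draw, and the horizon.  ``event`` is 1 iff
    the latent event time attains that minimum.
    """
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    if baseline_rate <= 0:
        raise ValueError(f"baseline_rate must be > 0, got {baseline_rate}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = lp.shape[0]
    t_event = rng.exponential(1.0 / (baseline_rate * np.exp(lp)))
    censor = np.full(n, float(horizon))
    if censoring is not None:
        if np.isfinite(censoring.admin_hi):
            admin = rng.uniform(censoring.admin_lo, censoring.admin_hi, size=n)
            censor = np.minimum(censor, admin)
        if censoring.dropout_rate > 0:
            censor = np.minimum(censor, rng.exponential(1.0 / censoring.dropout_rate, size=n))
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return time, event


def generate_cohort(spec: SimulationSpec) -> pd.DataFrame:
    """Generate a full synthetic cohort table from a :class:`SimulationSpec`.

    Returns one row per subject with predictor columns, eligibility flag
    columns, follow-up ``time`` in years and the ``event`` indicator.
    Identical specs (including seed) give identical tables.
    """
    spec.validate()
    n = spec.n
    data: dict[str, np.ndarray] = {"subject_id": np.arange(1, n + 1)}

    rng_b = substream(spec.seed, "binary")
    for name in spec.binary_predictors:
        data[name] = (rng_b.uniform(size=n) < spec.binary_predictors[name]).astype(int)

    rng_c = substream(spec.seed, "continuous")
    for name, cspec in spec.continuous_predictors.items():
        data[name] = _draw_continuous(rng_c, n, cspec)

    rng_o = substream(spec.seed, "ordinal")
    for name, levels in spec.ordinal_predictors.items():
        data[name] = _draw_ordinal(rng_o, n, levels)

    rng_k = substream(spec.seed, "categorical")
    for name, levels in spec.categorical_predictors.items():
        keys = list(levels.keys())
        probs = np.array([levels[k] for k in keys], dtype=float)
        data[name] = rng_k.choice(keys, size=n, p=probs / probs.sum())

    df = pd.DataFrame(data)

    # eligibility-violation injection (all-zero flags when rates are empty)
    rng_e = substream(spec.seed, "ineligibility")
    for flag in ELIGIBILITY_FLAGS:
        rate = spec.ineligibility_rates.get(flag, 0.0)
        df[flag] = (rng_e.uniform(size=n) < rate).astype(int)
    age_rate = spec.ineligibility_rates.get("age_outside_range", 0.0)
    if age_rate > 0 and "age" in df.columns:
        mask = rng_e.uniform(size=n) < age_rate
        df.loc[mask, "age"] = rng_e.integers(50, 56, size=int(mask.sum())).astype(float)

    if spec.truth_terms:
        beta = np.array([spec.true_log_hazards[t.name] for t in spec.truth_terms])
        lp = build_design(df, spec.truth_terms).to_numpy() @ beta
    else:
        lp = np.zeros(n)
    time, event = simulate_survival(
        lp - spec.lp_center,
        spec.baseline_rate,
        spec.censoring,
        spec.horizon,
        substream(spec.seed, "survival"),
    )
    df[TIME_COL] = time
    df[EVENT_COL] = event

    if spec.missingness_rates:
        df = inject_missingness(df, spec.missingness_rates, substream(spec.seed, "missingness"))
    return df


def inject_missingness(
    cohort: pd.DataFrame,
    rates: dict[str, float],
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Set each named predictor missing completely at random at its rate.

    Follow-up time and the event indicator are never made missing.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    out = cohort.copy()
    for name, rate in rates.items():
        if name not in out.columns:
            raise KeyError(f"missingness rate names unknown predictor {name!r}")
        if name in (TIME_COL, EVENT_COL):
            raise ValueError(f"cannot inject missingness into {name!r}")
        if not 0 <= rate <= 1:
            raise ValueError(f"missingness rate for {name!r} must be in [0,1], got {rate}")
        if rate == 0:
            continue
        mask = rng.uniform(size=len(out)) < rate
        if out[name].dtype.kind in "iu":
            out[name] = out[name].astype(float)
        out.loc[mask, name] = np.nan
    return out


# ---------------------------------------------------------------------------
# Eligibility filtering


@dataclass(frozen=True)
class EligibilityRule:
    """A named keep-rule; ``requires`` lists the cohort columns it reads."""

    name: str
    requires: tuple[str, ...]
    keep: Callable[[pd.DataFrame], pd.Series]


DEFAULT_ELIGIBILITY: tuple[EligibilityRule, ...] = (
    EligibilityRule(
        "age outside 15-49", ("age",), lambda df: df["age"].between(15, 49, inclusive="both")
    ),
    EligibilityRule("statins before index", ("statins",), lambda df: df["statins"] == 0),
    EligibilityRule(
        "death before index", ("died_before_index",), lambda df: df["died_before_index"] == 0
    ),
    EligibilityRule(
        "left practice before index", ("left_practice",), lambda df: df["left_practice"] == 0
    ),
    EligibilityRule(
        "last data collection before index",
        ("last_collection_before_index",),
        lambda df: df["last_collection_before_index"] == 0,
    ),
    EligibilityRule("prior CVD", ("prior_cvd",), lambda df: df["prior_cvd"] == 0),
)


@dataclass
class ExclusionLog:
    """Flow-diagram record: subjects removed and remaining at each filter."""

    initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def final(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "removed", "remaining"])


def apply_eligibility_filters(
    cohort: pd.DataFrame,
    rules: Sequence[EligibilityRule] = DEFAULT_ELIGIBILITY,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply study-entry filters sequentially, recording a flow log.

    Filters run in the given order (default: age window, statins, death
    before index, left practice, last data collection before index, prior
    CVD) so each step's removal count refers to subjects surviving all
    previous steps.
    """
    log = ExclusionLog(initial=len(cohort))
    out = cohort
    for rule in rules:
        missing = [c for c in rule.requires if c not in out.columns]
        if missing:
            raise KeyError(f"eligibility rule {rule.name!r} requires missing column(s) {missing}")
        keep = rule.keep(out).fillna(False).astype(bool)
        removed = int((~keep).sum())
        out = out.loc[keep]
        log.steps.append((rule.name, removed, len(out)))
    return out.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Delimited-text IO (missing values as empty fields)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
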