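"""Simulation and pipeline configuration.

A :class:`SimulationSpec` fully describes a synthetic postpartum cohort:
marginal distributions of the predictors, the proportional-hazards truth
(design terms plus log-hazards), the exponential baseline event rate, the
censoring mechanism, and per-predictor missingness rates.  Specs round-trip
through YAML so a whole study is reproducible from one text file and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .riskeq import Term

__all__ = ["ContinuousSpec", "Censoring", "SimulationSpec", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a simulation spec violates its invariants."""


@dataclass(frozen=True)
class ContinuousSpec:
    """Target mean/SD of a truncated-normal predictor on [lower, upper].

    The generator solves for parent normal parameters such that the
    *truncated* distribution attains the requested mean and SD.
    """

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf
    log_scale: bool = False  # sample exp(N(mean, sd)) instead (skewed labs)


@dataclass(frozen=True)
class Censoring:
    """Administrative censoring plus exponential dropout.

    The administrative time (index date to the end of the study window) is
    uniform on [admin_lo, admin_hi] years; because the generator caps
    follow-up at the horizon, an admin_hi beyond the horizon leaves a point
    mass of subjects censored exactly at the horizon, as in a real cohort
    with a long recruitment window.  Dropout (practice transfer or death)
    is exponential.  Defaults are tuned to a ~3.66-year median follow-up.
    """

    admin_lo: float = 0.5
    admin_hi: float = 21.0
    dropout_rate: float = 0.1437

    def validate(self) -> None:
        if not 0 < self.admin_lo <= self.admin_hi:
            raise ConfigError("censoring: need 0 < admin_lo <= admin_hi")
        if self.dropout_rate < 0:
            raise ConfigError("censoring: dropout_rate must be >= 0")


NONE_CENSORING = Censoring(admin_lo=np.inf, admin_hi=np.inf, dropout_rate=0.0)
"""Only the follow-up horizon censors (parameter-recovery experiments)."""


@dataclass
class SimulationSpec:
    """Data-generating truth for a synthetic cohort of women of reproductive
    age followed from six months postpartum for incident CVD."""

    n: int
    binary_predictors: dict[str, float] = field(default_factory=dict)
    continuous_predictors: dict[str, ContinuousSpec] = field(default_factory=dict)
    ordinal_predictors: dict[str, dict] = field(default_factory=dict)
    categorical_predictors: dict[str, dict[str, float]] = field(default_factory=dict)
    truth_terms: list[Term] = field(default_factory=list)
    true_log_hazards: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 1e-3  # events per person-year at the LP center
    lp_center: float = 0.0
    horizon: float = 10.0
    censoring: Censoring = field(default_factory=Censoring)
    missingness_rates: dict[str, float] = field(default_factory=dict)
    ineligibility_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if self.baseline_rate <= 0:
            raise ConfigError(f"baseline_rate must be > 0, got {self.baseline_rate}")
        if self.horizon <= 0:
            raise ConfigError(f"horizon must be > 0, got {self.horizon}")
        for name, p in self.binary_predictors.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"prevalence of {name!r} must be in [0,1], got {p}")
        for name, spec in self.continuous_predictors.items():
            if spec.sd <= 0:
                raise ConfigError(f"sd of {name!r} must be > 0, got {spec.sd}")
            if spec.lower >= spec.upper:
                raise ConfigError(f"truncation bounds of {name!r} are empty")
        for group in (self.ordinal_predictors, self.categorical_predictors):
            for name, probs in group.items():
                vals = np.array(list(probs.values()), dtype=float)
                if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                    raise ConfigError(
                        f"category probabilities of {name!r} must be >= 0 and sum to 1"
                    )
        for name, r in self.missingness_rates.items():
            if not 0 <= r <= 1:
                raise ConfigError(f"missingness rate of {name!r} must be in [0,1], got {r}")
        for name in self.true_log_hazards:
            if name not in {t.name for t in self.truth_terms}:
                raise ConfigError(f"true log-hazard names unknown term {name!r}")
        for t in self.truth_terms:
            if t.name not in self.true_log_hazards:
                raise ConfigError(f"truth term {t.name!r} has no log-hazard")
        self.censoring.validate()

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["continuous_predictors"] = {
            k: asdict(v) for k, v in self.continuous_predictors.items()
        }
        d["censoring"] = asdict(self.censoring)
        d["truth_terms"] = [
            {k: v for k, v in asdict(t).items() if v not in (None, False) or k == "name"}
            for t in self.truth_terms
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        d["continuous_predictors"] = {
            k: ContinuousSpec(**v) for k, v in d.get("continuous_predictors", {}).items()
        }
        if "censoring" in d:
            d["censoring"] = Censoring(**d["censoring"])
        d["truth_terms"] = [Term(**t) for t in d.get("truth_terms", [])]
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
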