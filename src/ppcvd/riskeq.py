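"""QRISK-style risk equations: fractional-polynomial transforms, linear
predictors, and absolute 10-year risk from a baseline survival value.

A risk equation here is a :class:`CoefficientSet`: an ordered list of model
terms with log-hazard coefficients, a centering constant, and the baseline
survival ``S0(t)`` at the prediction horizon.  The predicted risk for a
subject with linear predictor ``eta`` is

    pi = 1 - S0(t) ** exp(eta - centering)

which is the standard construction for Cox-type risk scores (QRISK, SCORE2,
PREDICT).  Equations are loaded from structured text (YAML); no published
coefficient values are bundled.

Continuous predictors enter through fractional-polynomial (FP) terms: the
variable is divided by a scaling constant (optionally shifted first) and
raised to powers from the Royston-Sauerbrei grid, where power 0 denotes the
natural log and a repeated power ``p`` contributes a second ``x**p * ln(x)``
column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FPSpec",
    "Term",
    "CoefficientSet",
    "fp_transform",
    "fp_terms",
    "build_design",
    "linear_predictor",
    "predicted_risk",
    "cloglog",
]


@dataclass(frozen=True)
class FPSpec:
    """Fractional-polynomial specification for one continuous variable.

    Powers follow the usual convention: 0 means ``ln(x)``; a power repeated
    twice means the second column is multiplied by ``ln(x)``.  ``shift`` is
    added *before* division by ``divisor``.
    """

    variable: str
    divisor: float = 1.0
    powers: tuple[float, ...] = (1.0,)
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.divisor <= 0:
            raise ValueError(f"FPSpec({self.variable}): divisor must be > 0")
        if len(self.powers) == 0:
            raise ValueError(f"FPSpec({self.variable}): at least one power required")


@dataclass(frozen=True)
class Term:
    """One column of the model design matrix.

    kind:
        ``linear``    — the raw column.
        ``fp``        — ``((x + shift)/divisor) ** power`` with the power-0 /
                        log-multiplied conventions of :func:`fp_transform`.
        ``indicator`` — dummy contrast, 1 where ``column == equals``.
    """

    name: str
    kind: str
    column: str
    power: float | None = None
    with_log: bool = False
    divisor: float = 1.0
    shift: float = 0.0
    equals: object | None = None

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        if self.column not in df.columns:
            raise KeyError(f"term {self.name!r}: column {self.column!r} not in cohort")
        if self.kind == "linear":
            return np.asarray(df[self.column], dtype=float)
        if self.kind == "indicator":
            return (df[self.column] == self.equals).to_numpy(dtype=float)
        if self.kind == "fp":
            x = (np.asarray(df[self.column], dtype=float) + self.shift) / self.divisor
            return _fp_column(x, self.power, self.with_log, self.column)
        raise ValueError(f"unknown term kind {self.kind!r}")


def _fp_column(x: np.ndarray, power: float, with_log: bool, name: str) -> np.ndarray:
    needs_log = with_log or power == 0
    needs_positive = needs_log or power < 0 or power != int(power)
    if needs_positive and np.any(x <= 0):
        bad = float(np.min(x))
        raise ValueError(
            f"fractional polynomial for {name!r} requires positive values "
            f"after shift/scaling; smallest seen was {bad:.6g}"
        )
    if power == 0:
        out = np.log(x)
    else:
        out = x**power
    if with_log:
        out = out * np.log(x)
    return out


def fp_transform(values: Sequence[float] | np.ndarray, spec: FPSpec) -> np.ndarray:
    """Evaluate an FP spec, returning one column per power (n, k).

    Power 0 maps to ``ln(x)``; a repeated power ``p`` maps to
    ``x**p * ln(x)`` for its second occurrence.
    """
    x = (np.asarray(values, dtype=float) + spec.shift) / spec.divisor
    cols = []
    seen: dict[float, int] = {}
    for p in spec.powers:
        reps = seen.get(p, 0)
        if reps > 1:
            raise ValueError(f"FPSpec({spec.variable}): power {p} repeated more than twice")
        cols.append(_fp_column(x, p, with_log=reps == 1, name=spec.variable))
        seen[p] = reps + 1
    return np.column_stack(cols)


def fp_terms(spec: FPSpec, prefix: str | None = None) -> list[Term]:
    """Expand an FPSpec into individual design :class:`Term` objects."""
    prefix = prefix or spec.variable
    out: list[Term] = []
    seen: dict[float, int] = {}
    for p in spec.powers:
        reps = seen.get(p, 0)
        suffix = f"_{_fmt_power(p)}" + ("_ln" if reps == 1 else "")
        out.append(
            Term(
                name=f"{prefix}{suffix}",
                kind="fp",
                column=spec.variable,
                power=p,
                with_log=reps == 1,
                divisor=spec.divisor,
                shift=spec.shift,
            )
        )
        seen[p] = reps + 1
    return out


def _fmt_power(p: float) -> str:
    if p == int(p):
        return str(int(p)).replace("-", "m")
    return str(p).replace("-", "m").replace(".", "p")


@dataclass
class CoefficientSet:
    """A named risk equation: terms, log-hazard coefficients, centering
    constant, and baseline survival at the horizon."""

    name: str
    terms: list[Term]
    coefficients: dict[str, float]
    baseline_survival: float = 1.0
    centering: float = 0.0
    horizon: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_survival <= 1:
            raise ValueError(
                f"baseline survival must be in (0, 1], got {self.baseline_survival}"
            )
        missing = [t.name for t in self.terms if t.name not in self.coefficients]
        if missing:
            raise ValueError(f"coefficients missing for terms: {missing}")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[t.name] for t in self.terms])

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "horizon": self.horizon,
            "baseline_survival": float(self.baseline_survival),
            "centering": float(self.centering),
            "terms": [
                {
                    "name": t.name,
                    "kind": t.kind,
                    "column": t.column,
                    **({"power": t.power, "with_log": t.with_log,
                        "divisor": t.divisor, "shift": t.shift} if t.kind == "fp" else {}),
                    **({"equals": t.equals} if t.kind == "indicator" else {}),
                    "coefficient": float(self.coefficients[t.name]),
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        terms, coefs = [], {}
        for td in d["terms"]:
            term = Term(
                name=td["name"],
                kind=td["kind"],
                column=td["column"],
                power=td.get("power"),
                with_log=td.get("with_log", False),
                divisor=td.get("divisor", 1.0),
                shift=td.get("shift", 0.0),
                equals=td.get("equals"),
            )
            terms.append(term)
            coefs[term.name] = float(td["coefficient"])
        return cls(
            name=d["name"],
            terms=terms,
            coefficients=coefs,
            baseline_survival=float(d.get("baseline_survival", 1.0)),
            centering=float(d.get("centering", 0.0)),
            horizon=float(d.get("horizon", 10.0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_design(df: pd.DataFrame, terms: Sequence[Term]) -> pd.DataFrame:
    """Design matrix with one column per term, in term order."""
    missing = [t.column for t in terms if t.column not in df.columns]
    if missing:
        raise KeyError(f"cohort is missing columns required by terms: {sorted(set(missing))}")
    data = {t.name: t.evaluate(df) for t in terms}
    return pd.DataFrame(data, index=df.index)


def linear_predictor(df: pd.DataFrame, coeffs: CoefficientSet) -> pd.Series:
    """Per-subject linear predictor eta = sum_j beta_j * x_ij."""
    X = build_design(df, coeffs.terms)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(
            f"missing values in design columns {bad}; impute before scoring"
        )
    eta = X.to_numpy() @ coeffs.beta
    return pd.Series(eta, index=df.index, name="lp")


def predicted_risk(eta: pd.Series | np.ndarray, coeffs: CoefficientSet) -> pd.Series:
    """10-year (horizon) absolute risk pi = 1 - S0(t) ** exp(eta - centering)."""
    s0 = coeffs.baseline_survival
    if not 0 < s0 <= 1:
        raise ValueError(f"baseline survival must be in (0, 1], got {s0}")
    eta = np.asarray(eta, dtype=float)
    pi = 1.0 - s0 ** np.exp(eta - coeffs.centering)
    return pd.Series(pi, name="risk")


def cloglog(p: np.ndarray | pd.Series, clip: float = 1e-10) -> np.ndarray:
    """Complementary log-log transform log(-log(1 - p)) with clamping."""
    p = np.clip(np.asarray(p, dtype=float), clip, 1.0 - clip)
    return np.log(-np.log1p(-p))
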