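"""Performance measures for 10-year survival risk predictions.

Discrimination: Harrell's C (with a Noether-type SE), Uno's IPCW
time-dependent C truncated at the horizon, and Royston's D with its
explained-variation transform R2_D.  Calibration: observed/expected ratio
from the Kaplan-Meier estimate, jackknife pseudo-values of the cumulative
incidence at the horizon, a pseudo-value GLM with complementary log-log
link (offset form for the intercept, free-coefficient form for the slope),
and a percentile-binned calibration curve.  Clinical utility: decision-curve
net benefit with Kaplan-Meier estimates among test-positives.

Pseudo-values give each subject an individual "observed" 10-year risk that
remains unbiased under independent censoring: PV_i = n*F(t) - (n-1)*F_{-i}(t)
with F the Kaplan-Meier cumulative incidence.  They are computed here with a
closed-form leave-one-out update rather than n KM refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.metrics import concordance_index_censored, concordance_index_ipcw
from sksurv.util import Surv

from .cohort import EVENT_COL, TIME_COL
from .riskeq import cloglog

__all__ = [
    "Estimate",
    "PerformanceReport",
    "DecisionCurve",
    "km_incidence",
    "pseudo_values",
    "harrell_c",
    "time_dependent_c",
    "royston_d",
    "d_to_r2",
    "oe_ratio",
    "calibration_intercept_slope",
    "calibration_curve",
    "net_benefit",
    "subgroup_performance",
    "performance_report",
]

KAPPA2 = 8.0 / np.pi  # variance of the scaled normal scores in Royston's D
SIGMA2 = np.pi**2 / 6.0  # standard-logistic variance in the R2_D transform
_Z = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class Estimate:
    """Point estimate with standard error and 95% confidence interval."""

    value: float
    se: float = np.nan
    lo: float = np.nan
    hi: float = np.nan

    @classmethod
    def from_se(cls, value: float, se: float) -> "Estimate":
        return cls(value, se, value - _Z * se, value + _Z * se)


# ---------------------------------------------------------------------------
# Kaplan-Meier machinery


def _km_blocks(time: np.ndarray, event: np.ndarray):
    """Unique event times with event counts and risk-set sizes."""
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    n = len(t_s)
    at_risk = n - np.searchsorted(t_s, t_s, side="left")
    ev = e_s == 1
    uniq, inverse = np.unique(t_s[ev], return_inverse=True)
    d_j = np.bincount(inverse)
    n_j = np.zeros(len(uniq))
    n_j[inverse] = at_risk[ev]
    return uniq, d_j.astype(float), n_j


def km_incidence(
    time: np.ndarray, event: np.ndarray, horizon: float
) -> tuple[float, float]:
    """Kaplan-Meier cumulative incidence F(t) at the horizon and its
    Greenwood variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq, d_j, n_j = _km_blocks(time, event)
    mask = uniq <= horizon
    surv = float(np.prod(1.0 - d_j[mask] / n_j[mask]))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.sum(d_j[mask] / (n_j[mask] * (n_j[mask] - d_j[mask])))
    var = surv**2 * gw if np.isfinite(gw) else np.nan
    return 1.0 - surv, var


def pseudo_values(
    time: np.ndarray, event: np.ndarray, horizon: float
) -> np.ndarray:
    """Jackknife pseudo-values of the KM cumulative incidence at the horizon.

    PV_i = n*F(t) - (n-1)*F_{-i}(t).  Their mean equals F(t) exactly; with
    no censoring before the horizon they collapse to the event indicator.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    if n < 2:
        raise ValueError("pseudo-values require at least two subjects")
    if np.any(time <= 0):
        raise ValueError("all follow-up times must be > 0")

    uniq, d_j, n_j = _km_blocks(time, event)
    mask = uniq <= horizon
    uniq, d_j, n_j = uniq[mask], d_j[mask], n_j[mask]
    if len(uniq) == 0:
        return np.zeros(n)

    a = 1.0 - d_j / n_j                       # full-sample KM factors
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(n_j > 1, (n_j - 1.0 - d_j) / (n_j - 1.0), 1.0)
    S_full = float(np.prod(a))

    # leave-one-out survival via prefix/suffix products: while subject i is
    # in the risk set the factor is b_j instead of a_j; factors after i has
    # left the risk set are unchanged
    Q = np.concatenate([[1.0], np.cumprod(b)])            # Q[k] = prod_{j<k} b_j
    R = np.concatenate([np.cumprod(a[::-1])[::-1], [1.0]])  # R[k] = prod_{j>=k} a_j
    # k_i = number of event-time blocks <= min(T_i, horizon)
    k = np.searchsorted(uniq, np.minimum(time, horizon), side="right")
    # censored (or event after horizon): blocks < k use b, the rest use a
    S_loo = Q[k] * R[k]

    # events at T_i <= horizon: the own block loses one event
    ev_i = (event == 1) & (time <= horizon)
    j_i = np.searchsorted(uniq, time[ev_i])               # own block index
    nj, dj = n_j[j_i], d_j[j_i]
    with np.errstate(invalid="ignore"):
        own = np.where(nj > 1, (nj - dj) / (nj - 1.0), 1.0)
    S_loo[ev_i] = Q[j_i] * own * R[j_i + 1]

    F_full = 1.0 - S_full
    F_loo = 1.0 - S_loo
    return n * F_full - (n - 1) * F_loo


# ---------------------------------------------------------------------------
# Discrimination


def _concordance_se(c: float, n_cases: int, n_controls: int) -> float:
    """Hanley-McNeil-type standard error for a concordance statistic,
    treating events as cases; a fast approximation to the Noether variance."""
    c = min(max(c, 1e-12), 1 - 1e-12)
    q1 = c / (2.0 - c)
    q2 = 2.0 * c**2 / (1.0 + c)
    n_cases = max(n_cases, 1)
    n_controls = max(n_controls, 1)
    var = (
        c * (1 - c)
        + (n_cases - 1) * (q1 - c**2)
        + (n_controls - 1) * (q2 - c**2)
    ) / (n_cases * n_controls)
    return float(np.sqrt(max(var, 0.0)))


def harrell_c(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> Estimate:
    """Harrell's concordance over comparable pairs; ties in the predictor
    count one half.  CI from a Hanley-McNeil-type standard error."""
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    try:
        c, conc, disc, tied_r, _ = concordance_index_censored(event, time, lp)
    except ValueError as exc:
        raise ValueError(f"no comparable pairs; cannot compute Harrell's C ({exc})")
    if conc + disc + tied_r == 0:
        raise ValueError("no comparable pairs; cannot compute Harrell's C")
    n_ev = int(event.sum())
    se = _concordance_se(float(c), n_ev, len(time) - n_ev)
    return Estimate.from_se(float(c), se)


def time_dependent_c(
    lp: np.ndarray, time: np.ndarray, event: np.ndarray, horizon: float
) -> Estimate:
    """Uno's IPCW concordance truncated at the horizon (censoring weights
    from the KM estimate of the censoring distribution)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not np.any(event & (time <= horizon)):
        raise ValueError("no events before the horizon; time-dependent C undefined")
    y = Surv.from_arrays(event, time)
    tau = min(horizon, time[event].max())
    c, conc, disc, tied_r, _ = concordance_index_ipcw(y, y, np.asarray(lp, float), tau=tau)
    n_ev = int((event & (time <= tau)).sum())
    se = _concordance_se(float(c), n_ev, len(time) - n_ev)
    return Estimate.from_se(float(c), se)


def d_to_r2(d: float | np.ndarray) -> float | np.ndarray:
    """Royston-Sauerbrei explained variation: R2_D = (D^2/k^2)/(s^2 + D^2/k^2)
    with k^2 = 8/pi and s^2 = pi^2/6 (exact identity)."""
    q = np.asarray(d, dtype=float) ** 2 / KAPPA2
    out = q / (SIGMA2 + q)
    return float(out) if np.isscalar(d) else out


def royston_d(
    lp: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[Estimate, float]:
    """Royston's D: Cox coefficient on scaled normal scores of the LP rank.

    Ranks are mapped to expected standard-normal order statistics (Blom
    approximation) and divided by kappa = sqrt(8/pi); D is the log-hazard
    separation between prognostic halves.  Returns (D, R2_D).
    """
    from .develop import fit_cox  # local import to avoid a cycle
    from .riskeq import Term

    lp = np.asarray(lp, dtype=float)
    if np.unique(lp).size < 2:
        warnings.warn("constant linear predictor; D = 0", RuntimeWarning, stacklevel=2)
        return Estimate(0.0, np.nan, np.nan, np.nan), 0.0
    n = len(lp)
    ranks = stats.rankdata(lp, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25)) / np.sqrt(KAPPA2)
    df = pd.DataFrame({"z": z, TIME_COL: time, EVENT_COL: event})
    model = fit_cox(df, [Term("z", "linear", "z")])
    d = float(model.params["z"])
    se = float(model.bse["z"])
    return Estimate.from_se(d, se), d_to_r2(d)


# ---------------------------------------------------------------------------
# Calibration


def oe_ratio(
    pred_risk: np.ndarray, time: np.ndarray, event: np.ndarray, horizon: float
) -> Estimate:
    """Observed/expected ratio: KM cumulative incidence at the horizon over
    the mean predicted risk; CI by the delta method on log(O)."""
    pred_risk = np.asarray(pred_risk, dtype=float)
    e = float(np.mean(pred_risk))
    if e <= 0:
        raise ValueError("mean predicted risk is zero; O/E undefined")
    o, var_o = km_incidence(np.asarray(time, float), np.asarray(event, int), horizon)
    oe = o / e
    se_log = np.sqrt(var_o) / o if o > 0 else np.nan
    return Estimate(oe, oe * se_log, oe * np.exp(-_Z * se_log), oe * np.exp(_Z * se_log))


def _pv_glm_cloglog(
    y: np.ndarray, x: np.ndarray, slope_free: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-likelihood GLM of pseudo-values with cloglog link.

    Intercept model: eta = alpha + x (x as offset).  Slope model:
    eta = alpha + beta * x.  Returns (coef, sandwich SE); pseudo-values may
    lie outside [0, 1], which the quasi-score accommodates.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), x]) if slope_free else np.ones((n, 1))
    offset = np.zeros(n) if slope_free else x
    beta = np.array([0.0, 1.0]) if slope_free else np.array([0.0])

    def link_parts(b):
        eta = np.clip(X @ b + offset, -30.0, 5.0)  # mu ~ 1 - 3e-65 at eta = 5
        mu = -np.expm1(-np.exp(eta))
        dmu = np.exp(eta - np.exp(eta))
        V = np.clip(mu * (1.0 - mu), 1e-10, None)
        return mu, dmu, V

    def score_norm(b):
        mu, dmu, V = link_parts(b)
        return float(np.linalg.norm(X.T @ ((y - mu) * dmu / V)))

    for _ in range(100):
        mu, dmu, V = link_parts(beta)
        W = dmu * dmu / V
        A = X.T @ (X * W[:, None]) + 1e-10 * np.eye(X.shape[1])
        g = X.T @ ((y - mu) * dmu / V)
        step = np.linalg.solve(A, g)
        # damped Newton: halve until the quasi-score norm does not blow up
        g0 = np.linalg.norm(g)
        for _half in range(30):
            cand = beta + step
            if score_norm(cand) <= max(g0 * (1.0 - 1e-4), 1e-8) or g0 < 1e-8:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu, dmu, V = link_parts(beta)
    W = dmu * dmu / V
    u = (y - mu) * dmu / V
    A = X.T @ (X * W[:, None])
    B = X.T @ (X * (u**2)[:, None])
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    return beta, np.sqrt(np.diag(cov))


def calibration_intercept_slope(
    pv: np.ndarray, pred_risk: np.ndarray
) -> tuple[Estimate, Estimate]:
    """Calibration intercept and slope from the pseudo-value GLM.

    Intercept: cloglog-link GLM with cloglog(predicted risk) as an offset —
    negative means predictions are too high.  Slope: the same model with the
    cloglog-transformed predictions as a free covariate (its coefficient is
    the slope; 1 is ideal, < 1 indicates overfitting).  Robust (sandwich)
    standard errors throughout.
    """
    pv = np.asarray(pv, dtype=float)
    pred_risk = np.asarray(pred_risk, dtype=float)
    if np.any(np.clip(pred_risk, 0.0, 1.0) != pred_risk):
        raise ValueError("predicted risks must lie in [0, 1]")
    x = cloglog(pred_risk)
    if not np.all(np.isfinite(x)):
        raise ValueError("cloglog of predicted risk is non-finite after clamping")
    (a,), (se_a,) = _pv_glm_cloglog(pv, x, slope_free=False)
    (_, b), (_, se_b) = _pv_glm_cloglog(pv, x, slope_free=True)
    return Estimate.from_se(float(a), float(se_a)), Estimate.from_se(float(b), float(se_b))


def calibration_curve(
    pred_risk: np.ndarray, pv: np.ndarray, n_groups: int = 10
) -> pd.DataFrame:
    """Percentile-grouped calibration curve: per group, mean predicted risk
    versus mean pseudo-value with a normal-approximation 95% CI."""
    pred_risk = np.asarray(pred_risk, dtype=float)
    pv = np.asarray(pv, dtype=float)
    n = len(pred_risk)
    if not 1 <= n_groups <= n:
        raise ValueError("n_groups must be between 1 and the number of subjects")
    try:
        groups = pd.qcut(pred_risk, n_groups, labels=False, duplicates="raise")
    except ValueError:
        warnings.warn(
            "tied predicted risks; merging adjacent percentile groups",
            RuntimeWarning,
            stacklevel=2,
        )
        groups = pd.qcut(pred_risk, n_groups, labels=False, duplicates="drop")
    rows = []
    for g in np.unique(groups):
        m = groups == g
        obs = pv[m]
        se = obs.std(ddof=1) / np.sqrt(m.sum()) if m.sum() > 1 else np.nan
        rows.append(
            {
                "group": int(g),
                "n": int(m.sum()),
                "mean_predicted": float(pred_risk[m].mean()),
                "observed": float(obs.mean()),
                "obs_lo": float(obs.mean() - _Z * se),
                "obs_hi": float(obs.mean() + _Z * se),
            }
        )
    return pd.DataFrame(rows).sort_values("mean_predicted").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Decision curves


@dataclass
class DecisionCurve:
    """Net benefit of the model, treat-all and treat-none per threshold."""

    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.model,
                "nb_treat_all": self.treat_all,
                "nb_treat_none": self.treat_none,
            }
        )


def net_benefit(
    pred_risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
    thresholds: np.ndarray | None = None,
) -> DecisionCurve:
    """Decision-curve net benefit for a time-to-event outcome.

    At threshold p_t, subjects with predicted risk >= p_t are positive; the
    event probability among positives comes from the Kaplan-Meier estimate
    at the horizon, so NB = P(pos)*F_pos - P(pos)*(1-F_pos)*p_t/(1-p_t).
    Treat-all classifies everyone positive; treat-none is identically zero.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    pred_risk = np.asarray(pred_risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(pred_risk)
    f_all, _ = km_incidence(time, event, horizon)
    odds = thresholds / (1.0 - thresholds)
    nb_all = f_all - (1.0 - f_all) * odds
    nb_model = np.zeros_like(thresholds)
    for i, p_t in enumerate(thresholds):
        pos = pred_risk >= p_t
        if not np.any(pos):
            nb_model[i] = 0.0
            continue
        f_pos, _ = km_incidence(time[pos], event[pos], horizon)
        p_pos = pos.mean()
        nb_model[i] = p_pos * f_pos - p_pos * (1.0 - f_pos) * odds[i]
    return DecisionCurve(thresholds, nb_model, nb_all, np.zeros_like(thresholds))


# ---------------------------------------------------------------------------
# Report assembly


@dataclass
class PerformanceReport:
    """Discrimination and calibration summary for one model on one cohort."""

    n: int
    n_events: int
    harrell_c: Estimate
    time_dependent_c: Estimate | None
    royston_d: Estimate
    r2_d: float
    lp_mean: float
    lp_sd: float
    oe: Estimate
    intercept: Estimate
    slope: Estimate
    curve: pd.DataFrame | None = None
    low_information: bool = False

    def to_frame(self) -> pd.DataFrame:
        def unpack(prefix: str, e: Estimate | None) -> dict:
            if e is None:
                return {prefix: np.nan, f"{prefix}_lo": np.nan, f"{prefix}_hi": np.nan}
            return {prefix: e.value, f"{prefix}_lo": e.lo, f"{prefix}_hi": e.hi}

        row = {
            "n": self.n,
            "n_events": self.n_events,
            **unpack("harrell_c", self.harrell_c),
            **unpack("time_dependent_c", self.time_dependent_c),
            **unpack("royston_d", self.royston_d),
            "r2_d": self.r2_d,
            "lp_mean": self.lp_mean,
            "lp_sd": self.lp_sd,
            **unpack("oe", self.oe),
            **unpack("cal_intercept", self.intercept),
            **unpack("cal_slope", self.slope),
            "low_information": self.low_information,
        }
        return pd.DataFrame([row])


def performance_report(
    df: pd.DataFrame,
    lp: np.ndarray,
    pred_risk: np.ndarray,
    horizon: float = 10.0,
    *,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
    n_groups: int = 10,
    with_curve: bool = True,
) -> PerformanceReport:
    """Compute the full validation block for one model on one cohort."""
    time = np.asarray(df[time_col], dtype=float)
    event = np.asarray(df[event_col], dtype=int)
    lp = np.asarray(lp, dtype=float)
    pred_risk = np.asarray(pred_risk, dtype=float)
    n_events = int(event.sum())

    c = harrell_c(lp, time, event)
    try:
        ctd = time_dependent_c(lp, time, event, horizon)
    except ValueError:
        ctd = None
    d, r2 = royston_d(lp, time, event)
    oe = oe_ratio(pred_risk, time, event, horizon)
    pv = pseudo_values(time, event, horizon)
    intercept, slope = calibration_intercept_slope(pv, pred_risk)
    curve = calibration_curve(pred_risk, pv, n_groups) if with_curve else None
    return PerformanceReport(
        n=len(df),
        n_events=n_events,
        harrell_c=c,
        time_dependent_c=ctd,
        royston_d=d,
        r2_d=r2,
        lp_mean=float(lp.mean()),
        lp_sd=float(lp.std(ddof=1)),
        oe=oe,
        intercept=intercept,
        slope=slope,
        curve=curve,
        low_information=n_events < 10,
    )


def subgroup_performance(
    df: pd.DataFrame,
    lp: np.ndarray,
    pred_risk: np.ndarray,
    grouping: str,
    horizon: float = 10.0,
    **kwargs,
) -> dict[str, PerformanceReport | None]:
    """Recompute all metrics within each level of a grouping column.

    Groups with fewer than 10 events are flagged low-information; groups
    with zero events report ``None`` (metrics undefined, not an error).
    """
    if grouping not in df.columns:
        raise KeyError(f"grouping column {grouping!r} not in cohort")
    lp = np.asarray(lp, dtype=float)
    pred_risk = np.asarray(pred_risk, dtype=float)
    out: dict[str, PerformanceReport | None] = {}
    for g, sub in df.groupby(grouping, observed=True, sort=True):
        idx = df.index.get_indexer(sub.index)
        if int(sub[EVENT_COL].sum()) == 0:
            out[str(g)] = None
            continue
        try:
            out[str(g)] = performance_report(
                sub, lp[idx], pred_risk[idx], horizon, **kwargs
            )
        except ValueError:
            out[str(g)] = None
    return out
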