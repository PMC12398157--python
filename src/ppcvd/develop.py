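"""Cox model development: fitting, baseline hazard, fractional-polynomial
term selection, LASSO variable selection with forced covariates, and
offset-based baseline recalibration.

Partial-likelihood maximisation is delegated to statsmodels' ``PHReg``
(Newton iterations, Efron tie handling, offset support).  The Breslow
baseline cumulative hazard, the cross-validated partial likelihood used to
pick the LASSO penalty, and the closed-test fractional-polynomial search
are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.duration.hazard_regression import PHReg

from .cohort import EVENT_COL, TIME_COL
from .riskeq import CoefficientSet, FPSpec, Term, build_design, fp_terms

__all__ = [
    "CoxModel",
    "BaselineHazard",
    "SelectionResult",
    "fit_cox",
    "breslow_baseline",
    "recalibrate_baseline",
    "select_fp",
    "lasso_select",
    "partial_loglik",
    "FP_POWER_GRID",
]

FP_POWER_GRID: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_SEPARATION_CAP = 15.0


@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard step function (H0(0) = 0)."""

    times: np.ndarray
    cumhaz: np.ndarray

    def cumhaz_at(self, t: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        return np.exp(-self.cumhaz_at(t))


@dataclass
class CoxModel:
    """Fitted Cox proportional-hazards model."""

    terms: list[Term]
    params: pd.Series
    bse: pd.Series
    vcov: pd.DataFrame
    llf: float
    centering: float
    n: int
    n_events: int
    baseline: BaselineHazard | None = None
    # fit-time arrays retained for baseline estimation on the same cohort
    _lp_fit: np.ndarray | None = field(default=None, repr=False)
    _time: np.ndarray | None = field(default=None, repr=False)
    _event: np.ndarray | None = field(default=None, repr=False)

    def predict_lp(self, df: pd.DataFrame) -> pd.Series:
        if not self.terms:
            return pd.Series(np.zeros(len(df)), index=df.index, name="lp")
        X = build_design(df, self.terms)
        return pd.Series(
            X.to_numpy() @ self.params.to_numpy(), index=df.index, name="lp"
        )

    def hazard_ratios(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        b, se = self.params.to_numpy(), self.bse.to_numpy()
        return pd.DataFrame(
            {
                "coef": b,
                "se": se,
                "hr": np.exp(b),
                "hr_lo": np.exp(b - z * se),
                "hr_hi": np.exp(b + z * se),
            },
            index=self.params.index,
        )

    def to_coefficient_set(self, name: str, horizon: float = 10.0) -> CoefficientSet:
        if self.baseline is None:
            raise ValueError("estimate the Breslow baseline before exporting the equation")
        s0 = float(self.baseline.survival_at(horizon))
        return CoefficientSet(
            name=name,
            terms=list(self.terms),
            coefficients={k: float(v) for k, v in self.params.items()},
            baseline_survival=s0,
            centering=self.centering,
            horizon=horizon,
        )


def fit_cox(
    df: pd.DataFrame,
    terms: Sequence[Term],
    *,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
    offset: np.ndarray | pd.Series | None = None,
    estimate_baseline: bool = False,
    horizon: float = 10.0,
) -> CoxModel:
    """Fit a Cox PH model by partial-likelihood maximisation (Efron ties).

    With an offset and no free terms the null fit is returned with the
    offset absorbed into the linear predictor.  Raises on zero events and
    on non-convergence; a separated predictor yields a warning and a capped
    coefficient.
    """
    time = np.asarray(df[time_col], dtype=float)
    event = np.asarray(df[event_col], dtype=int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("cannot fit a Cox model to a cohort with zero events")
    if offset is not None:
        offset = np.asarray(offset, dtype=float)
        if not np.all(np.isfinite(offset)):
            raise ValueError("offset contains non-finite values")

    terms = list(terms)
    if not terms:
        lp = offset if offset is not None else np.zeros(len(df))
        llf = partial_loglik(lp, time, event)
        model = CoxModel(
            terms=[],
            params=pd.Series(dtype=float),
            bse=pd.Series(dtype=float),
            vcov=pd.DataFrame(),
            llf=float(llf),
            centering=float(np.mean(lp)),
            n=len(df),
            n_events=n_events,
            _lp_fit=np.asarray(lp, dtype=float),
            _time=time,
            _event=event,
        )
        if estimate_baseline:
            model.baseline = breslow_baseline(model, horizon=horizon)
        return model

    X = build_design(df, terms)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"design columns contain missing values: {bad}; impute first")
    Xv = X.to_numpy()

    # a binary predictor with zero events in one arm has an infinite MLE;
    # detect it up front, fix its coefficient at the cap, and optimise the rest
    fixed_beta = np.full(Xv.shape[1], np.nan)
    any_separated = False
    for j in range(Xv.shape[1]):
        col = Xv[:, j]
        uniq = np.unique(col)
        if len(uniq) == 1:
            fixed_beta[j] = 0.0  # constant column: unidentifiable, drop from fit
        elif len(uniq) == 2:
            hi = col == uniq.max()
            ev_hi = int(event[hi].sum())
            scale = max(uniq.max() - uniq.min(), 1.0)
            if ev_hi == 0:
                fixed_beta[j] = -_SEPARATION_CAP / scale
                any_separated = True
            elif ev_hi == n_events:
                fixed_beta[j] = _SEPARATION_CAP / scale
                any_separated = True
    fixed = np.isfinite(fixed_beta)
    if any_separated:
        warnings.warn(
            "coefficient(s) capped; a predictor appears perfectly separated",
            RuntimeWarning,
            stacklevel=2,
        )
    if fixed.any():
        sep_offset = Xv[:, fixed] @ fixed_beta[fixed]
        offset = sep_offset if offset is None else offset + sep_offset
        free_idx = np.flatnonzero(~fixed)
        sub = fit_cox(
            df,
            [terms[i] for i in free_idx],
            time_col=time_col,
            event_col=event_col,
            offset=offset,
            estimate_baseline=False,
        )
        names = [t.name for t in terms]
        params = np.full(len(terms), np.nan)
        bse = np.full(len(terms), np.inf)
        cov = pd.DataFrame(0.0, index=names, columns=names)
        params[fixed] = fixed_beta[fixed]
        for i, gi in enumerate(free_idx):
            params[gi] = sub.params.iloc[i]
            bse[gi] = sub.bse.iloc[i]
            for i2, gi2 in enumerate(free_idx):
                cov.iloc[gi, gi2] = sub.vcov.iloc[i, i2]
        lp_fit = Xv @ params + (0.0 if offset is sep_offset else offset - sep_offset)
        model = CoxModel(
            terms=terms,
            params=pd.Series(params, index=names),
            bse=pd.Series(bse, index=names),
            vcov=cov,
            llf=sub.llf,
            centering=float(np.mean(lp_fit)),
            n=len(df),
            n_events=n_events,
            _lp_fit=np.asarray(lp_fit, dtype=float),
            _time=time,
            _event=event,
        )
        if estimate_baseline:
            model.baseline = breslow_baseline(model, horizon=horizon)
        return model

    # fit on standardised columns for numerical conditioning; the partial
    # likelihood is invariant to the affine change, coefficients map back
    mu_x = Xv.mean(axis=0)
    sd_x = Xv.std(axis=0)
    sd_x[sd_x == 0] = 1.0
    Z = (Xv - mu_x) / sd_x

    ph = PHReg(time, Z, status=event, offset=offset, ties="efron")
    gtol = 1e-3 * max(1.0, n_events)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ph.fit(method="newton", maxiter=100, disp=False, tol=1e-10)
        params_z = np.asarray(res.params, dtype=float)
        bad = not np.all(np.isfinite(params_z)) or (
            np.linalg.norm(ph.score(params_z)) > gtol
        )
        if bad:
            # statsmodels' Newton takes undamped steps and can overshoot to
            # non-finite values; quasi-Newton walks in safely, then a Newton
            # restart from there polishes to full precision
            res = ph.fit(method="bfgs", maxiter=500, disp=False)
            start = np.asarray(res.params, dtype=float)
            if np.all(np.isfinite(start)):
                try:
                    res = ph.fit(
                        method="newton", maxiter=100, disp=False, tol=1e-10,
                        start_params=start,
                    )
                    if np.all(np.isfinite(np.asarray(res.params, dtype=float))):
                        params_z = np.asarray(res.params, dtype=float)
                    else:
                        params_z = start
                except Exception:  # keep the quasi-Newton solution
                    params_z = start
            else:
                params_z = start
    if not np.all(np.isfinite(params_z)):
        raise RuntimeError("Cox fit diverged (non-finite coefficients)")
    grad = np.linalg.norm(ph.score(params_z))
    separated = np.any(np.abs(params_z / sd_x) > _SEPARATION_CAP) or np.any(
        np.abs(params_z) > _SEPARATION_CAP
    )
    if grad > gtol and not separated:
        raise RuntimeError(
            f"Cox fit did not converge after 100 Newton iterations (|gradient| = {grad:.3g})"
        )
    params = params_z / sd_x
    if separated:
        warnings.warn(
            "coefficient(s) capped; a predictor appears perfectly separated",
            RuntimeWarning,
            stacklevel=2,
        )
        params = np.clip(params, -_SEPARATION_CAP, _SEPARATION_CAP)
        llf_at = np.clip(params_z, -_SEPARATION_CAP, _SEPARATION_CAP)
    else:
        llf_at = params_z

    names = [t.name for t in terms]
    cov = np.asarray(res.cov_params(), dtype=float) / np.outer(sd_x, sd_x)
    lp_fit = Xv @ params + (offset if offset is not None else 0.0)
    model = CoxModel(
        terms=terms,
        params=pd.Series(params, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        vcov=pd.DataFrame(cov, index=names, columns=names),
        llf=float(ph.loglike(llf_at)),
        centering=float(np.mean(lp_fit)),
        n=len(df),
        n_events=n_events,
        _lp_fit=np.asarray(lp_fit, dtype=float),
        _time=time,
        _event=event,
    )
    if estimate_baseline:
        model.baseline = breslow_baseline(model, horizon=horizon)
    return model


def partial_loglik(
    lp: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Cox partial log-likelihood at a fixed linear predictor.

    Breslow tie handling; used for cross-validated penalty selection and as
    a fast evaluator (Efron and Breslow coincide without ties).
    """
    lp = np.asarray(lp, dtype=float)
    order = np.argsort(-np.asarray(time, dtype=float), kind="stable")
    t_s, e_s, lp_s = np.asarray(time)[order], np.asarray(event)[order], lp[order]
    # risk-set denominator at each subject's time = cumulative sum over all
    # subjects with T >= t, sharing the value across tied times
    cum = np.cumsum(np.exp(lp_s))
    # tie blocks share the denominator taken at the last index of the block
    new_block = np.r_[True, t_s[1:] != t_s[:-1]]
    block_id = np.cumsum(new_block) - 1
    block_last = np.flatnonzero(np.r_[new_block[1:], True])
    denom = cum[block_last[block_id]]
    ev = e_s == 1
    return float(np.sum(lp_s[ev] - np.log(denom[ev])))


def breslow_baseline(
    model: CoxModel,
    df: pd.DataFrame | None = None,
    *,
    horizon: float = 10.0,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
) -> BaselineHazard:
    """Breslow baseline cumulative hazard, centred at the model's mean LP.

    ``H0(t) = sum_{event times t_j <= t} d_j / sum_{i at risk} exp(lp_i - c)``
    so that ``S0(t) = exp(-H0(t))`` is the survival of a subject whose linear
    predictor equals the centering constant ``c``.
    """
    if df is None:
        if model._lp_fit is None:
            raise ValueError("model holds no fit-time data; pass the cohort explicitly")
        lp, time, event = model._lp_fit, model._time, model._event
    else:
        lp = model.predict_lp(df).to_numpy()
        time = np.asarray(df[time_col], dtype=float)
        event = np.asarray(df[event_col], dtype=int)

    rel = np.exp(lp - model.centering)
    order = np.argsort(time, kind="stable")
    t_s, e_s, r_s = time[order], event[order], rel[order]
    # denominator at time t: sum of rel over T >= t  (reverse cumulative sum)
    rev_cum = np.cumsum(r_s[::-1])[::-1]
    first_idx = np.searchsorted(t_s, t_s, side="left")
    denom = rev_cum[first_idx]
    ev_mask = e_s == 1
    ev_times = t_s[ev_mask]
    ev_denom = denom[ev_mask]
    uniq, inverse = np.unique(ev_times, return_inverse=True)
    d_j = np.bincount(inverse)
    denom_j = np.zeros(len(uniq))
    denom_j[inverse] = ev_denom  # identical within a tie block
    cumhaz = np.cumsum(d_j / denom_j)
    bl = BaselineHazard(times=uniq, cumhaz=cumhaz)
    if len(uniq) and horizon > t_s.max():
        warnings.warn(
            f"horizon {horizon} beyond last observed time {t_s.max():.3f}; "
            "baseline held constant beyond it",
            RuntimeWarning,
            stacklevel=2,
        )
    model.baseline = bl
    return bl


def recalibrate_baseline(
    lp: np.ndarray | pd.Series,
    df: pd.DataFrame,
    template: CoefficientSet,
    *,
    horizon: float = 10.0,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
) -> CoefficientSet:
    """Re-estimate the baseline survival by offset Cox regression.

    Fits the survival data with the supplied linear predictor as an offset
    and no free coefficients, takes the Breslow baseline of that null fit,
    and returns the template equation with predictor effects unchanged and
    the new 10-year baseline survival (and centering) substituted.
    """
    lp = np.asarray(lp, dtype=float)
    model = fit_cox(
        df, [], time_col=time_col, event_col=event_col, offset=lp,
        estimate_baseline=True, horizon=horizon,
    )
    s0 = float(model.baseline.survival_at(horizon))
    return CoefficientSet(
        name=f"{template.name}_recalibrated",
        terms=list(template.terms),
        coefficients=dict(template.coefficients),
        baseline_survival=s0,
        centering=model.centering,
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# Fractional-polynomial selection (closed test, Royston-Sauerbrei grid)


def select_fp(
    df: pd.DataFrame,
    variable: str,
    *,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
    alpha: float = 0.05,
    powers: Sequence[float] = FP_POWER_GRID,
    divisor: float = 1.0,
    shift: float = 0.0,
    adjust: Sequence[Term] = (),
) -> FPSpec | None:
    """Pick the fractional-polynomial form of one continuous variable.

    Finds the best-fitting FP2 (pairs from the power grid, with repetition)
    by partial log-likelihood, then runs the closed test at level ``alpha``:
    FP2 vs omission (4 df), FP2 vs linear (3 df), FP2 vs best FP1 (2 df).
    Returns the selected :class:`FPSpec`, or ``None`` if the variable is
    omitted.  ``adjust`` terms are kept in every model.
    """
    x = (np.asarray(df[variable], dtype=float) + shift) / divisor
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{variable!r} contains non-finite values")
    if np.unique(x).size < 2:
        raise ValueError(f"{variable!r} is constant; cannot select an FP form")
    if np.any(x <= 0):
        raise ValueError(
            f"{variable!r} must be strictly positive after shift/scaling for FP modelling"
        )
    adjust = list(adjust)

    def ll(fp_powers: tuple[float, ...] | None) -> float:
        terms = list(adjust)
        if fp_powers is not None:
            terms += fp_terms(
                FPSpec(variable, divisor=divisor, powers=fp_powers, shift=shift)
            )
        m = fit_cox(df, terms, time_col=time_col, event_col=event_col)
        return m.llf

    ll_null = ll(None)
    ll_linear = ll((1.0,))
    fp1 = {(p,): ll((p,)) for p in powers}
    best1 = max(fp1, key=fp1.get)
    fp2 = {pp: ll(pp) for pp in combinations_with_replacement(powers, 2)}
    best2 = max(fp2, key=fp2.get)
    ll2 = fp2[best2]

    def sig(ll_small: float, df_diff: int) -> bool:
        lr = 2.0 * (ll2 - ll_small)
        return stats.chi2.sf(max(lr, 0.0), df_diff) < alpha

    if not sig(ll_null, 4):
        return None
    if not sig(ll_linear, 3):
        return FPSpec(variable, divisor=divisor, powers=(1.0,), shift=shift)
    if not sig(fp1[best1], 2):
        return FPSpec(variable, divisor=divisor, powers=best1, shift=shift)
    return FPSpec(variable, divisor=divisor, powers=best2, shift=shift)


# ---------------------------------------------------------------------------
# LASSO selection with forced covariates


@dataclass
class SelectionResult:
    """Outcome of penalised variable selection plus the unpenalised refit."""

    forced: list[str]
    candidates: list[str]
    selected: list[str]  # forced + selected candidates, in term order
    alphas: np.ndarray
    cv_loglik: np.ndarray | None
    chosen_alpha: float
    rule: str
    model: CoxModel


def lasso_select(
    df: pd.DataFrame,
    candidates: Sequence[Term],
    forced: Sequence[Term],
    *,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
    lambda_rule: str = "cv_min",
    n_folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    n_alphas: int = 50,
) -> SelectionResult:
    """LASSO-Cox selection with zero penalty on forced terms.

    The penalty weight is chosen by ``n_folds``-fold cross-validated partial
    likelihood (Verweij-van Houwelingen form) unless ``lambda_rule='fixed'``
    with an explicit ``alpha``.  The LASSO is selection-only: the returned
    model is an unpenalised Cox refit on forced plus selected candidates.
    """
    forced, candidates = list(forced), list(candidates)
    f_names = [t.name for t in forced]
    c_names = [t.name for t in candidates]
    if set(f_names) & set(c_names):
        raise ValueError("forced and candidate term sets overlap")
    if not candidates:
        model = fit_cox(df, forced, time_col=time_col, event_col=event_col)
        return SelectionResult(
            f_names, [], list(f_names), np.array([]), None, np.nan, "no-candidates", model
        )

    all_terms = forced + candidates
    X = build_design(df, all_terms).to_numpy()
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    time = np.asarray(df[time_col], dtype=float)
    event = np.asarray(df[event_col], dtype=bool)
    y = Surv.from_arrays(event, time)
    n_unpen = len(forced)
    penalty = np.array([0.0] * n_unpen + [1.0] * len(candidates))
    rule_suffix = ""

    def coxnet(alphas=None, max_iter=100_000):
        return CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            penalty_factor=penalty,
            alphas=alphas,
            n_alphas=n_alphas,
            alpha_min_ratio=0.01,
            tol=1e-7,
            max_iter=max_iter,
        )


    try:
        full = coxnet().fit(Z, y)
    except ArithmeticError:
        # the unpenalised forced block can be unfittable at small event
        # counts (separation / collinearity); for the selection stage only,
        # condense it into one unpenalised column holding the LP of an
        # unpenalised Cox probe fit on the forced terms
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe = fit_cox(df, forced, time_col=time_col, event_col=event_col)
        lp_probe = probe._lp_fit
        Zc = build_design(df, candidates).to_numpy()
        mu_c, sd_c = Zc.mean(axis=0), Zc.std(axis=0)
        sd_c[sd_c == 0] = 1.0
        Z = np.column_stack([
            (lp_probe - lp_probe.mean()) / max(lp_probe.std(), 1e-12),
            (Zc - mu_c) / sd_c,
        ])
        n_unpen = 1
        penalty = np.array([0.0] + [1.0] * len(candidates))
        rule_suffix = "+condensed-forced"
        full = coxnet().fit(Z, y)
    path = np.asarray(full.alphas_)

    cv_ll = None
    if lambda_rule == "fixed":
        if alpha is None:
            raise ValueError("lambda_rule='fixed' requires an explicit alpha")
        chosen = float(alpha)
        coefs = coxnet(alphas=[chosen]).fit(Z, y).coef_[:, 0]
    elif lambda_rule == "cv_min":
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed & 0x7FFFFFFF)
        cv_ll = np.zeros(len(path))
        cv_cover = np.zeros(len(path), dtype=int)
        used_folds = 0
        for tr, _ in kf.split(Z):
            try:
                # bounded iterations: a fold that separates an unpenalised
                # column would otherwise grind for a long time before its
                # numerical error
                fit = coxnet(alphas=path, max_iter=3_000).fit(Z[tr], y[tr])
            except ArithmeticError:
                continue  # fold unfittable (e.g. separation); skip
            B = np.asarray(fit.coef_)  # (p, n_alphas_converged)
            fold_alphas = np.asarray(fit.alphas_)
            used_folds += 1
            for j, a in enumerate(fold_alphas):
                # the fold path can be a truncated version of the full path
                k = int(np.argmin(np.abs(path - a)))
                lp_all = Z @ B[:, j]
                ll_all = partial_loglik(lp_all, time, event.astype(int))
                ll_tr = partial_loglik(lp_all[tr], time[tr], event[tr].astype(int))
                cv_ll[k] += ll_all - ll_tr
                cv_cover[k] += 1
        if used_folds == 0:
            raise RuntimeError("no cross-validation fold could be fitted")
        eligible = cv_cover == cv_cover.max()
        best = int(np.flatnonzero(eligible)[np.argmax(cv_ll[eligible])])
        chosen = float(path[best])
        coefs = np.asarray(full.coef_)[:, best]
    else:
        raise ValueError(f"unknown lambda rule {lambda_rule!r}")

    keep = [t for t, c in zip(candidates, coefs[n_unpen:]) if abs(c) > 1e-10]
    final_terms = forced + keep
    model = fit_cox(df, final_terms, time_col=time_col, event_col=event_col)
    return SelectionResult(
        forced=f_names,
        candidates=c_names,
        selected=[t.name for t in final_terms],
        alphas=path,
        cv_loglik=cv_ll,
        chosen_alpha=chosen,
        rule=lambda_rule + rule_suffix,
        model=model,
    )
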