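"""Internal validation and study orchestration.

``bootstrap_optimism`` replays the *entire* modelling recipe — including
LASSO variable selection — inside every bootstrap resample, compares each
replicate's performance on its own resample with its performance on the
original cohort, and subtracts the mean optimism from the apparent
statistics.  ``run_study`` executes the whole study graph: eligibility
filters, imputation, benchmark scoring and validation, baseline
recalibration, development of the three updated models, validation with
subgroups and decision curves, and bootstrap optimism correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .cohort import (
    EVENT_COL,
    TIME_COL,
    apply_eligibility_filters,
    generate_cohort,
    substream,
    write_cohort,
)
from .develop import CoxModel, fit_cox, lasso_select, recalibrate_baseline
from .impute import default_policy, drop_high_missingness, complete_case, missing_report, single_impute
from .riskeq import CoefficientSet, Term, linear_predictor, predicted_risk
from .validate import (
    PerformanceReport,
    calibration_intercept_slope,
    harrell_c,
    net_benefit,
    performance_report,
    pseudo_values,
    royston_d,
    subgroup_performance,
)

__all__ = ["ModelRecipe", "BootstrapReport", "bootstrap_optimism", "StudyConfig", "run_study"]


@dataclass
class ModelRecipe:
    """A reproducible modelling recipe: forced terms, candidates, and the
    selection rule.  Fractional-polynomial forms are fixed up front and are
    not re-selected inside resamples (re-selection is available via
    ``refit_fp`` for sensitivity use)."""

    name: str
    forced: list[Term]
    candidates: list[Term] = field(default_factory=list)
    use_lasso: bool = True
    lambda_rule: str = "cv_min"
    n_folds: int = 10
    horizon: float = 10.0
    refit_fp: bool = False

    def fit(self, df: pd.DataFrame, seed: int = 0):
        """Run the full recipe on a cohort; returns (CoxModel, selected names)."""
        if self.candidates and self.use_lasso:
            sel = lasso_select(
                df,
                self.candidates,
                self.forced,
                lambda_rule=self.lambda_rule,
                n_folds=self.n_folds,
                seed=seed,
            )
            model = sel.model
            selected = sel.selected
        else:
            terms = self.forced + list(self.candidates)
            model = fit_cox(df, terms)
            selected = [t.name for t in terms]
        from .develop import breslow_baseline

        breslow_baseline(model, horizon=self.horizon)
        return model, selected


@dataclass
class BootstrapReport:
    """Optimism-corrected performance (C, D, calibration slope)."""

    apparent: dict[str, float]
    optimism: dict[str, float]
    adjusted: dict[str, float]
    B: int
    completed: int
    failures: list[str]
    selected_sets: list[tuple[str, ...]]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": k,
                "apparent": self.apparent[k],
                "mean_optimism": self.optimism[k],
                "adjusted": self.adjusted[k],
            }
            for k in self.apparent
        ]
        return pd.DataFrame(rows)


def _recipe_metrics(model: CoxModel, df: pd.DataFrame, horizon: float) -> dict[str, float]:
    lp = model.predict_lp(df).to_numpy()
    time = np.asarray(df[TIME_COL], dtype=float)
    event = np.asarray(df[EVENT_COL], dtype=int)
    c = harrell_c(lp, time, event).value
    d, _ = royston_d(lp, time, event)
    cs = model.to_coefficient_set("tmp", horizon)
    risk = predicted_risk(lp, cs).to_numpy()
    pv = pseudo_values(time, event, horizon)
    _, slope = calibration_intercept_slope(pv, risk)
    return {"harrell_c": c, "royston_d": d.value, "cal_slope": slope.value}


def bootstrap_optimism(
    df: pd.DataFrame,
    recipe: ModelRecipe,
    B: int = 500,
    seed: int = 0,
    horizon: float = 10.0,
) -> BootstrapReport:
    """Bootstrap optimism correction, replaying the recipe per resample.

    Each replicate resamples subjects with replacement, reruns the whole
    recipe (selection included), and measures performance both in the
    resample and on the original cohort; optimism is the difference, and
    the adjusted statistic is apparent minus mean optimism.  Replicates
    that fail (for example, zero events) are logged and skipped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = substream(seed, f"bootstrap:{recipe.name}")
    model, _ = recipe.fit(df, seed)
    apparent = _recipe_metrics(model, df, horizon)

    n = len(df)
    optimisms: list[dict[str, float]] = []
    failures: list[str] = []
    selected_sets: list[tuple[str, ...]] = []
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model_b, selected = recipe.fit(boot, seed=int(rng.integers(0, 2**31 - 1)))
                m_boot = _recipe_metrics(model_b, boot, horizon)
                m_orig = _recipe_metrics(model_b, df, horizon)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data events
            failures.append(f"replicate {b}: {exc}")
            continue
        selected_sets.append(tuple(selected))
        optimisms.append({k: m_boot[k] - m_orig[k] for k in m_boot})
    if not optimisms:
        raise RuntimeError(f"all {B} bootstrap replicates failed: {failures[:3]}")
    mean_opt = {k: float(np.mean([o[k] for o in optimisms])) for k in apparent}
    adjusted = {k: apparent[k] - mean_opt[k] for k in apparent}
    return BootstrapReport(
        apparent=apparent,
        optimism=mean_opt,
        adjusted=adjusted,
        B=B,
        completed=len(optimisms),
        failures=failures,
        selected_sets=selected_sets,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Whole-study orchestration


@dataclass
class StudyConfig:
    """Configuration of one complete study run."""

    n: int = 50_000
    seed: int = 0
    horizon: float = 10.0
    bootstrap_B: int = 500
    lasso_folds: int = 10
    benchmark_miscalibration: float = 0.75
    incidence_10yr: float | None = None
    complete_case: bool = False  # sensitivity: drop rows with missing data
    min_age: float | None = None  # sensitivity: e.g. 25.0
    subgroups: tuple[str, ...] = ("age_group",)
    with_ineligibility: bool = True
    decision_thresholds: tuple[float, float, float] = (0.01, 0.99, 0.01)

    @classmethod
    def load(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("subgroups",):
            if key in d:
                d[key] = tuple(d[key])
        if "decision_thresholds" in d:
            d["decision_thresholds"] = tuple(d["decision_thresholds"])
        return cls(**d)


@dataclass
class StudyReport:
    """In-memory results of a study run (everything is also written out)."""

    config: StudyConfig
    exclusion_log: pd.DataFrame
    dropped_predictors: list[str]
    models: dict[str, CoefficientSet]
    performance: dict[str, PerformanceReport]
    decision_curves: dict[str, pd.DataFrame]
    subgroup_reports: dict[str, dict]
    hr_table: pd.DataFrame
    optimism: dict[str, BootstrapReport]


def _model1_lp_terms() -> list[Term]:
    # benchmark linear predictor entered through its two FP(3) terms
    return [
        Term("bench_lp_3", "fp", "bench_lp", power=3.0, shift=4.0),
        Term("bench_lp_3_ln", "fp", "bench_lp", power=3.0, with_log=True, shift=4.0),
    ]


def run_study(config: StudyConfig, out_dir) -> StudyReport:
    """Execute the full study graph and write one report per model.

    Stages: cohort generation -> eligibility filters -> (sensitivity
    restrictions) -> high-missingness exclusion -> single imputation ->
    benchmark scoring + validation -> baseline recalibration -> Model 1
    (benchmark LP as FP terms + pregnancy candidates), Model 2a
    (established predictors refit), Model 2b (established + pregnancy
    candidates) -> validation, subgroups, decision curves -> bootstrap
    optimism for the developed models.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "failure_manifest.yaml").unlink(missing_ok=True)
    stage = "simulate"
    try:
        spec = defaults.default_spec(
            config.n,
            config.seed,
            ineligibility=defaults.FIG1_INELIGIBILITY if config.with_ineligibility else None,
            incidence_10yr=config.incidence_10yr,
        )
        raw = generate_cohort(spec)

        stage = "eligibility"
        cohort, excl = apply_eligibility_filters(raw)
        if config.min_age is not None:
            before = len(cohort)
            cohort = cohort[cohort["age"] >= config.min_age].reset_index(drop=True)
            excl.steps.append((f"age < {config.min_age} (sensitivity)", before - len(cohort), len(cohort)))

        stage = "missing-data"
        missing_report(cohort).to_csv(out / "missingness.csv", index=False)
        cohort, dropped = drop_high_missingness(cohort)
        if config.complete_case:
            before = len(cohort)
            cohort = complete_case(cohort)
            excl.steps.append(("incomplete rows (sensitivity)", before - len(cohort), len(cohort)))
        cohort = single_impute(cohort, default_policy())
        if cohort[EVENT_COL].sum() == 0:
            raise RuntimeError("cohort has no events after filtering")
        excl.to_frame().to_csv(out / "exclusion_log.csv", index=False)

        # subgroup labels
        cohort["age_group"] = np.where(cohort["age"] < 35, "15-34", "35-49")

        models: dict[str, CoefficientSet] = {}
        performance: dict[str, PerformanceReport] = {}
        curves: dict[str, pd.DataFrame] = {}
        subgroup_reports: dict[str, dict] = {}
        optimism: dict[str, BootstrapReport] = {}
        lps: dict[str, np.ndarray] = {}

        def validate_model(name: str, cs: CoefficientSet) -> None:
            lp = linear_predictor(cohort, cs).to_numpy()
            risk = predicted_risk(lp, cs).to_numpy()
            lps[name] = lp
            models[name] = cs
            performance[name] = performance_report(cohort, lp, risk, config.horizon)
            lo, hi, step = config.decision_thresholds
            grid = np.arange(lo, hi + step / 2, step)
            curves[name] = net_benefit(
                risk, cohort[TIME_COL].to_numpy(), cohort[EVENT_COL].to_numpy(),
                config.horizon, grid,
            ).to_frame()
            for g in config.subgroups:
                subgroup_reports.setdefault(name, {})[g] = subgroup_performance(
                    cohort, lp, risk, g, config.horizon, with_curve=False
                )

        stage = "benchmark"
        bench = defaults.benchmark_equation(config.benchmark_miscalibration)
        validate_model("benchmark", bench)

        stage = "recalibration"
        recal = recalibrate_baseline(
            lps["benchmark"], cohort, bench, horizon=config.horizon
        )
        validate_model("recalibrated", recal)

        stage = "development"
        cohort["bench_lp"] = lps["benchmark"]
        established = [t for t in defaults.ESTABLISHED_TERMS]
        pregnancy = [t for t in defaults.PREGNANCY_CANDIDATE_TERMS if t.column not in dropped]
        recipes = {
            "model1": ModelRecipe(
                "model1", _model1_lp_terms(), pregnancy,
                n_folds=config.lasso_folds, horizon=config.horizon,
            ),
            "model2a": ModelRecipe(
                "model2a", established, [], n_folds=config.lasso_folds, horizon=config.horizon
            ),
            "model2b": ModelRecipe(
                "model2b", established, pregnancy,
                n_folds=config.lasso_folds, horizon=config.horizon,
            ),
        }
        for name, recipe in recipes.items():
            model, selected = recipe.fit(cohort, config.seed)
            cs = model.to_coefficient_set(name, config.horizon)
            validate_model(name, cs)
            if name == "model2b":
                hr_table = model.hazard_ratios()
            (out / f"selected_{name}.txt").write_text("\n".join(selected) + "\n")

        stage = "internal-validation"
        for name, recipe in recipes.items():
            optimism[name] = bootstrap_optimism(
                cohort, recipe, B=config.bootstrap_B, seed=config.seed, horizon=config.horizon
            )

        stage = "reporting"
        comparison = pd.concat(
            {name: rep.to_frame() for name, rep in performance.items()}, names=["model"]
        ).reset_index(level=0)
        comparison.to_csv(out / "model_comparison.csv", index=False)
        hr_table.to_csv(out / "hr_table_model2b.csv")
        for name in models:
            models[name].save(out / f"coefficients_{name}.yaml")
            curves[name].to_csv(out / f"decision_curve_{name}.csv", index=False)
            if performance[name].curve is not None:
                performance[name].curve.to_csv(out / f"calibration_curve_{name}.csv", index=False)
        pd.concat(
            {name: rep.to_frame() for name, rep in optimism.items()}, names=["model"]
        ).reset_index(level=0).to_csv(out / "optimism.csv", index=False)
        write_cohort(cohort.head(100), out / "cohort_preview.csv")
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {"config": {**config.__dict__, "subgroups": list(config.subgroups),
                            "decision_thresholds": list(config.decision_thresholds)},
                 "n_final": int(len(cohort)),
                 "n_events": int(cohort[EVENT_COL].sum()),
                 "models": list(models)},
                fh, sort_keys=False,
            )
    except Exception as exc:
        manifest = Path(out) / "failure_manifest.yaml"
        with open(manifest, "w") as fh:
            yaml.safe_dump({"failed_stage": stage, "error": str(exc)}, fh)
        raise RuntimeError(f"study aborted during stage {stage!r}: {exc}") from exc

    return StudyReport(
        config=config,
        exclusion_log=excl.to_frame(),
        dropped_predictors=dropped,
        models=models,
        performance=performance,
        decision_curves=curves,
        subgroup_reports=subgroup_reports,
        hr_table=hr_table,
        optimism=optimism,
    )
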