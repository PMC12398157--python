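#!/usr/bin/env python
"""Stage 3 — develop the updated risk models.

On the imputed eligible cohort: Model 1 forces the benchmark linear
predictor in through its two cubic fractional-polynomial terms and offers
the pregnancy/reproductive candidates to the LASSO; Model 2a refits the
established predictors; Model 2b forces the established predictors and
offers the pregnancy candidates.  Selection uses 10-fold cross-validated
partial likelihood with zero penalty on forced terms, followed by an
unpenalised Cox refit.  Writes hazard-ratio tables, selected-term lists,
in-sample validation metrics and coefficient sets to results/03_models/.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
stage1 = import_module("01_simulate_cohort")

from ppcvd.defaults import ESTABLISHED_TERMS, PREGNANCY_CANDIDATE_TERMS, benchmark_equation
from ppcvd.impute import default_policy, drop_high_missingness, single_impute
from ppcvd.internal import ModelRecipe, _model1_lp_terms
from ppcvd.riskeq import linear_predictor, predicted_risk
from ppcvd.validate import performance_report

OUT = Path(__file__).resolve().parents[1] / "results" / "03_models"
SEED = 2024


def build_recipes(dropped):
    pregnancy = [t for t in PREGNANCY_CANDIDATE_TERMS if t.column not in dropped]
    return {
        "model1": ModelRecipe("model1", _model1_lp_terms(), pregnancy),
        "model2a": ModelRecipe("model2a", list(ESTABLISHED_TERMS), []),
        "model2b": ModelRecipe("model2b", list(ESTABLISHED_TERMS), pregnancy),
    }


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort, _ = stage1.build_cohort()
    cohort, dropped = drop_high_missingness(cohort)
    cohort = single_impute(cohort, default_policy())
    cohort["bench_lp"] = linear_predictor(cohort, benchmark_equation())
    print(f"candidate predictors excluded for missingness: {dropped}")

    reports = {}
    for name, recipe in build_recipes(dropped).items():
        model, selected = recipe.fit(cohort, SEED)
        cs = model.to_coefficient_set(name, 10.0)
        cs.save(OUT / f"coefficients_{name}.yaml")
        model.hazard_ratios().to_csv(OUT / f"hr_table_{name}.csv")
        (OUT / f"selected_{name}.txt").write_text("\n".join(selected) + "\n")
        lp = model.predict_lp(cohort).to_numpy()
        risk = predicted_risk(lp, cs).to_numpy()
        rep = performance_report(cohort, lp, risk, 10.0)
        reports[name] = rep
        n_cand = len(recipe.candidates)
        kept = len(selected) - len(recipe.forced)
        print(f"{name:8s} kept {kept}/{n_cand} candidates | "
              f"C {rep.harrell_c.value:.3f} D {rep.royston_d.value:.3f} "
              f"O/E {rep.oe.value:.3f} slope {rep.slope.value:.3f} "
              f"LP sd {rep.lp_sd:.3f}")

    pd.concat({k: r.to_frame() for k, r in reports.items()},
              names=["model"]).reset_index(level=0).to_csv(OUT / "metrics.csv", index=False)
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
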