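#!/usr/bin/env python
"""Stage 2 — externally validate the benchmark equation, then recalibrate.

Scores the eligible cohort from stage 1 with the synthetic benchmark risk
equation (true predictor effects, baseline cumulative hazard deflated by
25% to emulate a general-population score transported to young postpartum
women), computes discrimination, pseudo-value calibration and decision
curves, then re-estimates the baseline by offset Cox regression and
re-validates.  Writes results/02_external/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

stage1 = import_module("01_simulate_cohort")

from ppcvd.defaults import benchmark_equation
from ppcvd.develop import recalibrate_baseline
from ppcvd.impute import default_policy, single_impute
from ppcvd.riskeq import linear_predictor, predicted_risk
from ppcvd.validate import net_benefit, performance_report

OUT = Path(__file__).resolve().parents[1] / "results" / "02_external"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort, _ = stage1.build_cohort()
    cohort = single_impute(cohort, default_policy())

    bench = benchmark_equation()
    lp = linear_predictor(cohort, bench).to_numpy()
    time, event = cohort["time"].to_numpy(), cohort["event"].to_numpy()

    reports = {}
    curves = {}
    for name, cs in (
        ("benchmark", bench),
        ("recalibrated", recalibrate_baseline(lp, cohort, bench, horizon=10.0)),
    ):
        risk = predicted_risk(lp, cs).to_numpy()
        rep = performance_report(cohort, lp, risk, 10.0)
        reports[name] = rep
        rep.curve.to_csv(OUT / f"calibration_curve_{name}.csv", index=False)
        curves[name] = net_benefit(risk, time, event, 10.0,
                                   np.arange(0.001, 0.101, 0.001))
        curves[name].to_frame().to_csv(OUT / f"decision_curve_{name}.csv", index=False)
        cs.save(OUT / f"coefficients_{name}.yaml")

    table = pd.concat({k: r.to_frame() for k, r in reports.items()},
                      names=["model"]).reset_index(level=0)
    table.to_csv(OUT / "metrics.csv", index=False)
    for name, rep in reports.items():
        print(f"{name:13s} C {rep.harrell_c.value:.3f} "
              f"D {rep.royston_d.value:.3f} O/E {rep.oe.value:.3f} "
              f"intercept {rep.intercept.value:+.3f} slope {rep.slope.value:.3f}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
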