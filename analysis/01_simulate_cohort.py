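#!/usr/bin/env python
"""Stage 1 — simulate the study population and apply the entry criteria.

Generates the default synthetic postpartum cohort (n = 100,000 before
eligibility screening, seed 2024) with flow-diagram-style ineligibility
rates, applies the eligibility filters in order, and writes the exclusion
log, the missing-data profile, and a baseline characteristics table to
results/01_cohort/.  Later stages regenerate the same cohort from the spec
(deterministic), so no large intermediate file is stored.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ppcvd.cohort import apply_eligibility_filters, generate_cohort
from ppcvd.defaults import FIG1_INELIGIBILITY, default_spec
from ppcvd.impute import missing_report

N, SEED = 100_000, 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "01_cohort"


def build_cohort():
    spec = default_spec(N, SEED, ineligibility=FIG1_INELIGIBILITY)
    raw = generate_cohort(spec)
    cohort, log = apply_eligibility_filters(raw)
    return cohort, log


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort, log = build_cohort()
    log.to_frame().to_csv(OUT / "exclusion_log.csv", index=False)
    missing_report(cohort).to_csv(OUT / "missingness.csv", index=False)

    rows = {
        "n": len(cohort),
        "events_observed": int(cohort["event"].sum()),
        "median_follow_up_years": float(np.median(cohort["time"])),
        "age_mean": float(cohort["age"].mean()),
        "age_sd": float(cohort["age"].std()),
        "bmi_mean": float(cohort["bmi"].mean()),
        "current_smoker_frac": float((cohort["smoking"] == "current").mean()),
        "preeclampsia_frac": float(cohort["preeclampsia"].mean()),
        "migraine_frac": float(cohort["migraine"].mean()),
    }
    pd.Series(rows).to_csv(OUT / "baseline_summary.csv", header=["value"])

    print(f"eligible cohort: {len(cohort)} of {log.initial} simulated women")
    print(log.to_frame().to_string(index=False))
    print(f"\nmedian follow-up {rows['median_follow_up_years']:.2f} y, "
          f"{rows['events_observed']} observed CVD events "
          f"({100 * rows['events_observed'] / rows['n']:.2f}%)")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
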