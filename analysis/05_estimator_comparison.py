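#!/usr/bin/env python
"""Compare the segmented fit against the two-point shortcut.

Two experiments:
1. On the simulated trial-like cohort (with noise), bias and RMSE of r_g,
   r_s and d for both estimators — the segmented fit uses every scan, the
   two-point one only three anchors.
2. A noise-free cohort whose baseline scan precedes treatment onset by
   0.5, 1 and 2 months: the first on-treatment interval then straddles the
   breakpoint, so the two-point r_s absorbs pre-treatment growth while the
   segmented fit stays exact.

Writes results/estimator_comparison.csv and results/misplaced_baseline.csv.
"""

from pathlib import Path

import pandas as pd

from tumorkinetics.io import read_results_table, read_scan_table, write_results_table
from tumorkinetics.simulate import (
    CohortScenario,
    PhenotypeSpec,
    TruncNormal,
    TruthRecord,
    generate_cohort,
)
from tumorkinetics.twopoint import compare_estimators

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def trial_like_comparison() -> pd.DataFrame:
    cohort = read_scan_table(OUT / "cohort.csv")
    truth_df = read_results_table(OUT / "truth.csv")
    truths = [
        TruthRecord(str(r.patient_id), r.true_y0, r.true_rg, r.true_rs, r.phenotype)
        for r in truth_df.itertuples()
    ]
    _, agg = compare_estimators(cohort, truths)
    return agg


def misplaced_baseline_grid() -> pd.DataFrame:
    rows = []
    for b in (0.5, 1.0, 2.0):
        scenario = CohortScenario(
            name="misplaced",
            n_patients=20,
            sigma_res=0.0,
            stop_at_pd=False,
            prebaseline_window=(-5.0, -4.0),
            baseline_window=(-b, -b),
            seed=SEED,
            phenotypes=[
                PhenotypeSpec(
                    name="stable", weight=1.0,
                    rg=TruncNormal(0.15, 0.0), rs=TruncNormal(-0.25, 0.0),
                    visits=(3, 3),
                )
            ],
        )
        cohort, truths = generate_cohort(scenario)
        _, agg = compare_estimators(cohort, truths)
        for _, r in agg.query("param == 'rs'").iterrows():
            rows.append({"t_baseline": -b, "method": r["method"], "rs_bias": r["bias"]})
    return pd.DataFrame(rows)


def main() -> None:
    agg = trial_like_comparison()
    write_results_table(agg, OUT / "estimator_comparison.csv")
    print("trial-like cohort, estimator error (bias / RMSE):")
    print(agg.to_string(index=False, float_format=lambda x: f"{x:+.4f}"))

    grid = misplaced_baseline_grid()
    write_results_table(grid, OUT / "misplaced_baseline.csv")
    print("\nnoise-free misplaced-baseline experiment (r_g=0.15, r_s=-0.25):")
    print(grid.pivot(index="t_baseline", columns="method", values="rs_bias")
              .to_string(float_format=lambda x: f"{x:+.4f}"))
    print("\nthe two-point on-treatment rate is pulled toward the pre-treatment "
          "rate, increasingly so the earlier the baseline scan; the segmented "
          "fit is exact throughout")


if __name__ == "__main__":
    main()
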