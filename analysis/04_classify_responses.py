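#!/usr/bin/env python
"""Classify patients by change in slope and cross-tabulate against RECIST.

Patients are improving (d < -0.05 month^-1), worsening (d > +0.05) or stable
(the negligible band in between); improving patients whose tumor was growing
pre-treatment (r_g > 0.05) while RECIST still calls them SD are the
therapeutically-induced-stable-disease cases the pre-baseline scan exists to
reveal.  Writes classes, the rate summary table, the BOR-by-slope cross-tab
and the two response rates under results/.
"""

from pathlib import Path

import pandas as pd

from tumorkinetics.classify import (
    classifications_frame,
    classify_cohort,
    crosstab_bor_slope,
    response_rates,
    summarize_rates,
    summary_frame,
)
from tumorkinetics.io import filter_evaluable, read_scan_table, write_results_table
from tumorkinetics.recist import bor_cohort
from tumorkinetics.segmented import fit_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_scan_table(OUT / "cohort.csv")
    evaluable, _ = filter_evaluable(cohort)
    fits = fit_cohort(evaluable).fits
    bors = bor_cohort(evaluable)
    classes = classify_cohort(fits, bors)

    write_results_table(classifications_frame(classes), OUT / "classes.csv")
    write_results_table(
        summary_frame(summarize_rates(classes)), OUT / "rates_summary.csv"
    )
    table, ue = crosstab_bor_slope(classes)
    table.to_csv(OUT / "bor_by_slope.csv")

    rates = response_rates(classes)
    tisd = [c for c in classes if c.tisd]
    tisd_sd = [c for c in tisd if c.bor == "SD"]
    print("BOR x slope-class cross-tab:")
    print(table.to_string())
    print(f"(UE patients excluded from the table: {ue})")
    print(f"RECIST response rate: {rates.recist_rate:.1f}% "
          f"({rates.n_recist}/{rates.n_evaluable})")
    print(f"growth-declination response rate: {rates.model_rate:.1f}% "
          f"({rates.n_model}/{rates.n_evaluable})")
    print(f"TISD (r_g > 0.05, d < -0.05): {len(tisd)} patients, "
          f"{len(tisd_sd)} of them RECIST-SD")
    print(f"wrote classes.csv, rates_summary.csv, bor_by_slope.csv under {OUT}")


if __name__ == "__main__":
    main()
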