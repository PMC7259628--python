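#!/usr/bin/env python
"""Derive each patient's RECIST 1.1 best overall response.

Visit categories come from the SLD relative to baseline (PR at -30%) and to
the running nadir (PD at +20% and +5 mm, or any new lesion); evaluation stops
at the first PD.  Writes results/bor.csv and prints the BOR distribution.
"""

from collections import Counter
from pathlib import Path

from tumorkinetics.io import filter_evaluable, read_scan_table, write_results_table
from tumorkinetics.recist import bor_cohort, bor_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_scan_table(OUT / "cohort.csv")
    evaluable, _ = filter_evaluable(cohort)
    results = bor_cohort(evaluable)
    write_results_table(bor_frame(results), OUT / "bor.csv")

    counts = Counter(r.bor for r in results)
    total = len(results)
    print(f"best overall response among {total} evaluable patients:")
    for cat in ("CR", "PR", "SD", "PD", "UE"):
        if counts[cat]:
            print(f"  {cat}: {counts[cat]:3d} ({100*counts[cat]/total:.1f}%)")
    print(f"wrote {OUT/'bor.csv'}")


if __name__ == "__main__":
    main()
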