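#!/usr/bin/env python
"""Simulate a trial-like cohort of SLD trajectories.

Generates 68 patients with the scan structure of an early-phase monotherapy
expansion cohort — one pre-baseline scan, one baseline scan, six-weekly
on-treatment scans stopping at RECIST progression — and writes the observed
scan table (results/cohort.csv) and the ground-truth parameters
(results/truth.csv, kept separate so fitting code cannot touch it).
"""

from pathlib import Path

from tumorkinetics.io import filter_evaluable, write_results_table, write_scan_table
from tumorkinetics.simulate import generate_cohort, preset_scenarios, truth_frame

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    scenario = preset_scenarios(n_patients=68, seed=SEED)["trial_like"]
    cohort, truths = generate_cohort(scenario)
    write_scan_table(cohort, OUT / "cohort.csv")
    write_results_table(truth_frame(truths), OUT / "truth.csv")

    evaluable, excluded = filter_evaluable(cohort)
    n_scans = [len(s.scans) for s in cohort]
    n_post = [s.n_post for s in cohort]
    print(f"simulated {len(cohort)} patients (seed {SEED}); "
          f"{len(evaluable)} evaluable, {len(excluded)} excluded")
    print(f"scans per patient: {min(n_scans)}-{max(n_scans)}; "
          f"post-baseline scans: {min(n_post)}-{max(n_post)}")
    print(f"wrote {OUT/'cohort.csv'} and {OUT/'truth.csv'}")


if __name__ == "__main__":
    main()
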