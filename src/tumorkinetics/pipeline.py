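"""End-to-end pipeline: simulate/read -> fit -> RECIST -> classify -> report.

A :class:`PipelineConfig` fully determines one run; outputs are plain CSV /
JSON / text files in the output directory plus a ``manifest.json`` recording
the configuration, its hash, the seed and a SHA-256 checksum per output.
Reruns with an identical configuration are byte-identical (no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, recist, segmented, simulate, twopoint
from .errors import TumorKineticsError
from .io import (
    filter_evaluable,
    read_scan_table,
    write_results_table,
    write_scan_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    #: Either a preset / scenario-file to simulate from, or an input CSV.
    scenario: str | None = "trial_like"
    input_path: str | None = None
    n_patients: int = 68
    seed: int = 0
    cutoff: float = classify.DEFAULT_CUTOFF
    zero_sld: str = "replace"
    zero_value: float = segmented.ZERO_SLD_REPLACEMENT_MM
    use_5mm_rule: bool = True
    stop_at_pd: bool = True
    min_sd_duration_months: float = 0.0
    tisd_requires_sd: bool = False
    estimators: tuple[str, ...] = ("segmented", "two_point")

    def validate(self) -> None:
        if (self.scenario is None) == (self.input_path is None):
            raise TumorKineticsError(
                "exactly one of 'scenario' and 'input_path' must be set"
            )
        if self.input_path is not None and not Path(self.input_path).exists():
            raise TumorKineticsError(f"input path does not exist: {self.input_path}")
        unknown = set(self.estimators) - {"segmented", "two_point"}
        if unknown:
            raise TumorKineticsError(f"unknown estimators: {sorted(unknown)}")
        if "segmented" not in self.estimators:
            raise TumorKineticsError(
                "the segmented estimator is required for classification"
            )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _resolve_scenario(config: PipelineConfig) -> simulate.CohortScenario:
    presets = simulate.preset_scenarios(n_patients=config.n_patients, seed=config.seed)
    if config.scenario in presets:
        return presets[config.scenario]
    path = Path(config.scenario)
    if path.exists():
        scenario = simulate.scenario_from_file(path)
        return dataclasses.replace(scenario, seed=config.seed)
    raise TumorKineticsError(
        f"scenario {config.scenario!r} is neither a preset "
        f"({sorted(presets)}) nor a file"
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all outputs and the manifest; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # --- stage: acquire cohort -------------------------------------------
    if config.scenario is not None:
        scenario = _resolve_scenario(config)
        cohort, truths = simulate.generate_cohort(scenario, seed=config.seed)
        cohort_path = out / "cohort.csv"
        write_scan_table(cohort, cohort_path)
        truth_path = out / "truth.csv"
        write_results_table(simulate.truth_frame(truths), truth_path)
        outputs += [cohort_path, truth_path]
        source = f"scenario:{scenario.name}"
    else:
        cohort = read_scan_table(config.input_path)
        source = f"file:{config.input_path}"

    evaluable, excluded = filter_evaluable(cohort)
    for ex in excluded:
        logger.info(
            "excluded patient %s: %s", ex.series.patient_id, ex.reason
        )
    logger.info(
        "cohort: %d patients, %d evaluable, %d excluded",
        len(cohort),
        len(evaluable),
        len(excluded),
    )
    if excluded:
        excl_path = out / "excluded.csv"
        write_results_table(
            [
                {"patient_id": ex.series.patient_id, "reason": ex.reason}
                for ex in excluded
            ],
            excl_path,
        )
        outputs.append(excl_path)

    # --- stage: growth-rate fits -----------------------------------------
    cohort_fit = segmented.fit_cohort(
        evaluable, zero_sld=config.zero_sld, zero_value=config.zero_value
    )
    for pid, msg in cohort_fit.failures:
        logger.warning("segmented fit failed for %s: %s", pid, msg)
    fits_path = out / "fits_segmented.csv"
    write_results_table(segmented.fits_frame(cohort_fit.fits), fits_path)
    outputs.append(fits_path)

    if "two_point" in config.estimators:
        tp_fits = [
            twopoint.fit_two_point(
                s, zero_sld=config.zero_sld, zero_value=config.zero_value
            )
            for s in evaluable
        ]
        tp_path = out / "fits_two_point.csv"
        write_results_table(twopoint.two_point_frame(tp_fits), tp_path)
        outputs.append(tp_path)

    # --- stage: RECIST BOR ------------------------------------------------
    bors = recist.bor_cohort(
        evaluable,
        stop_at_pd=config.stop_at_pd,
        use_5mm_rule=config.use_5mm_rule,
        min_sd_duration_months=config.min_sd_duration_months,
    )
    bor_path = out / "bor.csv"
    write_results_table(recist.bor_frame(bors), bor_path)
    outputs.append(bor_path)

    # --- stage: classification and report ---------------------------------
    classes = classify.classify_cohort(
        cohort_fit.fits,
        bors,
        cutoff=config.cutoff,
        tisd_requires_sd=config.tisd_requires_sd,
    )
    classes_path = out / "classes.csv"
    write_results_table(classify.classifications_frame(classes), classes_path)
    outputs.append(classes_path)

    summary = classify.summary_frame(classify.summarize_rates(classes))
    summary_path = out / "rates_summary.csv"
    write_results_table(summary, summary_path)
    outputs.append(summary_path)

    table, ue_count = classify.crosstab_bor_slope(classes)
    crosstab_path = out / "bor_by_slope.csv"
    table.to_csv(crosstab_path)
    outputs.append(crosstab_path)

    rates = classify.response_rates(classes)
    pooled = cohort_fit.pooled_sigma
    report_lines = [
        f"patients read: {len(cohort)}",
        f"evaluable: {len(evaluable)}  excluded: {len(excluded)}",
        f"pooled residual SD (log scale): "
        + (f"{pooled:.4f}" if pooled is not None else "not estimable"),
        f"RECIST response rate: {rates.recist_rate:.1f}% "
        f"({rates.n_recist}/{rates.n_evaluable})",
        f"model response rate (d < -{config.cutoff:g}): {rates.model_rate:.1f}% "
        f"({rates.n_model}/{rates.n_evaluable})",
        f"TISD-flagged patients: {sum(c.tisd for c in classes)}",
        f"UE (not in cross-tab): {ue_count}",
    ]
    report_path = out / "report.txt"
    report_path.write_text("\n".join(report_lines) + "\n")
    outputs.append(report_path)

    manifest = {
        "source": source,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
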