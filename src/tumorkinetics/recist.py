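"""RECIST 1.1 per-visit response categories and best overall response (BOR).

Target-lesion response is judged from the SLD relative to two anchors: the
baseline SLD (latest scan at t <= 0) for response, and the nadir (smallest
SLD seen so far, baseline included) for progression:

* CR — target-lesion SLD is 0 (complete disappearance) and no new lesion;
* PR — SLD down at least 30% from baseline;
* PD — a new lesion, or SLD up at least 20% from nadir with an absolute
  increase of at least 5 mm (the absolute rule can be disabled);
* SD — anything in between.

PD takes precedence over CR/PR at a visit.  BOR is the best category reached
across on-treatment visits under CR > PR > SD > PD; by default evaluation
stops at the first PD (trial conduct: scans until progression), and a patient
with no evaluable post-baseline visit is UE.  Non-target lesions are outside
the data model: CR here means target-lesion SLD = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import MissingBaselineError
from .io import PatientSeries

CR = "CR"
PR = "PR"
SD = "SD"
PD = "PD"
UE = "UE"

#: BOR ordering, best first.
_BOR_RANK = {CR: 4, PR: 3, SD: 2, PD: 1}

#: RECIST PD thresholds.
PD_NADIR_FRACTION = 0.20
PD_ABSOLUTE_MM = 5.0
PR_BASELINE_FRACTION = -0.30


def classify_visit(
    sld: float,
    baseline_sld: float,
    nadir: float,
    new_lesion: bool,
    *,
    use_5mm_rule: bool = True,
) -> str:
    """RECIST 1.1 category for a single on-treatment assessment."""
    if sld < 0:
        raise ValueError(f"SLD must be >= 0, got {sld}")
    if baseline_sld <= 0:
        raise ValueError("baseline SLD must be positive")
    if new_lesion:
        return PD
    increase = sld - nadir
    if nadir > 0 and increase / nadir >= PD_NADIR_FRACTION:
        if not use_5mm_rule or increase >= PD_ABSOLUTE_MM:
            return PD
    if sld == 0:
        return CR
    if (sld - baseline_sld) / baseline_sld <= PR_BASELINE_FRACTION:
        return PR
    return SD


@dataclass
class BorResult:
    patient_id: str
    baseline_sld: float
    visit_responses: list[tuple[float, str]]  # (t, category) for t > 0
    nadir_trail: list[float]  # running minimum, baseline first
    bor: str  # CR | PR | SD | PD | UE

    @property
    def first_pd_time(self) -> float:
        for t, cat in self.visit_responses:
            if cat == PD:
                return t
        return math.nan

    @property
    def n_visits(self) -> int:
        return len(self.visit_responses)


def best_overall_response(
    series: PatientSeries,
    *,
    stop_at_pd: bool = True,
    use_5mm_rule: bool = True,
    min_sd_duration_months: float = 0.0,
) -> BorResult:
    """Walk a patient's on-treatment visits and derive the BOR.

    The nadir used to judge progression at a visit is the minimum SLD over
    baseline and all *earlier* on-treatment visits; it is updated with the
    current visit afterwards.  With ``stop_at_pd`` (default) visits after the
    first PD are not evaluated.  ``min_sd_duration_months`` discounts SD
    visits earlier than the threshold when ranking the BOR (protocols
    sometimes require SD to persist a minimum time; default 0 = off).
    """
    baseline = series.baseline
    if baseline is None:
        raise MissingBaselineError(series.patient_id)
    baseline_sld = baseline.sld

    responses: list[tuple[float, str]] = []
    nadir = baseline_sld
    nadir_trail = [baseline_sld]
    for scan in series.post_scans:
        cat = classify_visit(
            scan.sld, baseline_sld, nadir, scan.new_lesion, use_5mm_rule=use_5mm_rule
        )
        responses.append((scan.t, cat))
        nadir = min(nadir, scan.sld)
        nadir_trail.append(nadir)
        if stop_at_pd and cat == PD:
            break

    if not responses:
        bor = UE
    else:
        candidates = [
            cat
            for t, cat in responses
            if not (cat == SD and t < min_sd_duration_months)
        ]
        bor = max(candidates, key=_BOR_RANK.__getitem__) if candidates else UE

    return BorResult(
        patient_id=series.patient_id,
        baseline_sld=baseline_sld,
        visit_responses=responses,
        nadir_trail=nadir_trail,
        bor=bor,
    )


def bor_cohort(
    cohort: Iterable[PatientSeries],
    *,
    stop_at_pd: bool = True,
    use_5mm_rule: bool = True,
    min_sd_duration_months: float = 0.0,
) -> list[BorResult]:
    return [
        best_overall_response(
            series,
            stop_at_pd=stop_at_pd,
            use_5mm_rule=use_5mm_rule,
            min_sd_duration_months=min_sd_duration_months,
        )
        for series in cohort
    ]


def bor_frame(results: Iterable[BorResult]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "baseline_sld": r.baseline_sld,
            "bor": r.bor,
            "n_visits": r.n_visits,
            "first_pd_time": r.first_pd_time,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "baseline_sld", "bor", "n_visits", "first_pd_time"]
    )
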