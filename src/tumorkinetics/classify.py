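"""Change-in-slope response classification and trial-style summary tables.

The per-patient treatment-effect statistic is ``d = r_s - r_g`` (month^-1).
Values in the closed band [-cutoff, +cutoff] (default cutoff 0.05 month^-1)
are considered negligible:

* improving — d < -cutoff (tumor growth declines on treatment),
* worsening — d > +cutoff,
* stable    — |d| <= cutoff.

*Therapeutically induced stable disease* (TISD) flags patients whose tumor
was growing before treatment (r_g > cutoff) and whose growth was arrested on
treatment (d < -cutoff); it is typically inspected within the RECIST-SD
subgroup, where it separates drug-induced stabilization from indolent
disease.

Summaries mirror the usual reporting shapes: per-group mean with a
t-distribution 95% CI, median and range for each of r_g, r_s and d; a
BOR-by-slope-class contingency table (UE patients footnoted, not tabulated);
and the two response rates (RECIST CR/PR vs model d < -cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import JoinError
from .recist import CR, PD, PR, SD, UE, BorResult
from .segmented import SegmentedFit

IMPROVING = "improving"
STABLE = "stable"
WORSENING = "worsening"

DEFAULT_CUTOFF = 0.05  # month^-1


@dataclass(frozen=True)
class PatientClassification:
    patient_id: str
    rg_hat: float
    rs_hat: float
    d_hat: float
    slope_class: str  # improving | stable | worsening
    tisd: bool
    bor: str  # CR | PR | SD | PD | UE
    responder_recist: bool  # bor in {CR, PR}
    responder_model: bool  # d_hat < -cutoff


@dataclass(frozen=True)
class SummaryRow:
    group: str
    param: str  # rg | rs | d
    n: int
    mean: float
    ci_low: float  # NaN when n < 2 (not estimable)
    ci_high: float
    median: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class ResponseRates:
    n_evaluable: int
    n_recist: int
    n_model: int

    @property
    def recist_rate(self) -> float:
        """RECIST CR/PR response rate, percent."""
        return 100.0 * self.n_recist / self.n_evaluable

    @property
    def model_rate(self) -> float:
        """Growth-declination (d < -cutoff) response rate, percent."""
        return 100.0 * self.n_model / self.n_evaluable


def slope_category(d: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Classify d with boundary values +/-cutoff assigned to 'stable'."""
    if d < -cutoff:
        return IMPROVING
    if d > cutoff:
        return WORSENING
    return STABLE


def classify_patient(
    fit: SegmentedFit,
    bor: BorResult,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    tisd_requires_sd: bool = False,
) -> PatientClassification:
    """Join one segmented fit with its BOR into a classification record.

    ``tisd_requires_sd`` restricts the TISD flag to RECIST-SD patients (the
    subgroup in which it is usually reported); by default the kinetic
    condition alone (r_g > cutoff and d < -cutoff) is flagged.
    """
    if fit.patient_id != bor.patient_id:
        raise JoinError(
            f"fit is for patient {fit.patient_id!r} but BOR for {bor.patient_id!r}"
        )
    d = fit.d_hat
    cls = slope_category(d, cutoff)
    tisd = cls == IMPROVING and fit.rg_hat > cutoff
    if tisd_requires_sd:
        tisd = tisd and bor.bor == SD
    return PatientClassification(
        patient_id=fit.patient_id,
        rg_hat=fit.rg_hat,
        rs_hat=fit.rs_hat,
        d_hat=d,
        slope_class=cls,
        tisd=tisd,
        bor=bor.bor,
        responder_recist=bor.bor in (CR, PR),
        responder_model=d < -cutoff,
    )


def classify_cohort(
    fits: Sequence[SegmentedFit],
    bors: Sequence[BorResult],
    *,
    cutoff: float = DEFAULT_CUTOFF,
    tisd_requires_sd: bool = False,
) -> list[PatientClassification]:
    bor_by_id = {b.patient_id: b for b in bors}
    missing = [f.patient_id for f in fits if f.patient_id not in bor_by_id]
    if missing:
        raise JoinError(f"fits without BOR results: {missing[:5]}")
    return [
        classify_patient(
            f, bor_by_id[f.patient_id], cutoff=cutoff, tisd_requires_sd=tisd_requires_sd
        )
        for f in fits
    ]


def _summary(group: str, param: str, values: np.ndarray, ci_method: str) -> SummaryRow:
    n = len(values)
    mean = float(np.mean(values))
    if n >= 2:
        se = float(np.std(values, ddof=1)) / math.sqrt(n)
        if ci_method == "t":
            q = float(stats.t.ppf(0.975, n - 1))
        else:
            q = float(stats.norm.ppf(0.975))
        lo, hi = mean - q * se, mean + q * se
    else:
        lo = hi = math.nan
    return SummaryRow(
        group=group,
        param=param,
        n=n,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        median=float(np.median(values)),
        minimum=float(np.min(values)),
        maximum=float(np.max(values)),
    )


def summarize_rates(
    classifications: Sequence[PatientClassification],
    grouping: Literal["all", "by_recist_responder"] = "by_recist_responder",
    *,
    ci_method: Literal["t", "normal"] = "t",
) -> list[SummaryRow]:
    """Mean [95% CI], median and range of rg, rs, d, overall and by responder.

    Responders are patients with BOR CR or PR.  The CI uses the t
    distribution with n-1 degrees of freedom (``ci_method='normal'`` switches
    to the normal approximation); a group of one reports NaN bounds.
    """
    if not classifications:
        raise ValueError("at least one classification is required")
    groups: list[tuple[str, list[PatientClassification]]] = [
        ("all", list(classifications))
    ]
    if grouping == "by_recist_responder":
        groups.append(
            ("responders", [c for c in classifications if c.responder_recist])
        )
        groups.append(
            ("non_responders", [c for c in classifications if not c.responder_recist])
        )
    rows: list[SummaryRow] = []
    for label, members in groups:
        if not members:
            continue
        for param, attr in (("rg", "rg_hat"), ("rs", "rs_hat"), ("d", "d_hat")):
            values = np.array([getattr(c, attr) for c in members], dtype=float)
            rows.append(_summary(label, param, values, ci_method))
    return rows


def summary_frame(rows: Iterable[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=[
            "group",
            "param",
            "n",
            "mean",
            "ci_low",
            "ci_high",
            "median",
            "minimum",
            "maximum",
        ],
    )


def crosstab_bor_slope(
    classifications: Sequence[PatientClassification],
) -> tuple[pd.DataFrame, int]:
    """BOR x slope-class contingency table with totals, plus the UE count.

    Rows CR, PR, SD, PD (then Total); columns worsening, stable, improving
    (then Total).  UE patients are excluded from the table body and returned
    as a separate footnote count.
    """
    bor_order = [CR, PR, SD, PD]
    col_order = [WORSENING, STABLE, IMPROVING]
    table = pd.DataFrame(0, index=bor_order, columns=col_order, dtype=int)
    ue_count = 0
    for c in classifications:
        if c.bor == UE:
            ue_count += 1
            continue
        table.loc[c.bor, c.slope_class] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "bor"
    return table, ue_count


def response_rates(
    classifications: Sequence[PatientClassification],
) -> ResponseRates:
    """RECIST (CR/PR) and model-based (d < -cutoff) response rates in percent."""
    n = len(classifications)
    if n == 0:
        raise ValueError("response rates are undefined for an empty cohort")
    return ResponseRates(
        n_evaluable=n,
        n_recist=sum(c.responder_recist for c in classifications),
        n_model=sum(c.responder_model for c in classifications),
    )


def classifications_frame(
    classifications: Iterable[PatientClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        [c.__dict__ for c in classifications],
        columns=[
            "patient_id",
            "rg_hat",
            "rs_hat",
            "d_hat",
            "slope_class",
            "tisd",
            "bor",
            "responder_recist",
            "responder_model",
        ],
    )
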