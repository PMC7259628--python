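"""Per-patient segmented log-linear growth model with a fixed breakpoint.

Tumor burden is assumed to change exponentially at a pre-treatment rate
``r_g`` up to treatment onset and at an on-treatment rate ``r_s`` thereafter:

    y(t) = y0 * exp(r_g * t * I(t <= 0) + r_s * t * I(t > 0)) * exp(eps)

so that on the log scale the model is ordinary least squares of ``ln(SLD)``
on the design ``{1, t*I(t <= 0), t*I(t > 0)}``.  The breakpoint is fixed at
``t = 0`` (treatment start); it is never estimated.  The intercept ``y0`` is
the model SLD at onset, ``d = r_s - r_g`` is the change-in-slope treatment
statistic, and rates convert to doubling / halving times via ``ln(2)/r`` and
``ln(0.5)/r``.

Each patient is fit independently (no shrinkage or mixed effects); the
residual standard deviation is pooled across patients with positive residual
degrees of freedom as ``sqrt(sum RSS_i / sum dof_i)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, IdentifiabilityError, ZeroSldError
from .io import PatientSeries

#: Half the 5-mm RECIST measurability floor; substituted for SLD = 0
#: (complete disappearance of target lesions) before log transform.
ZERO_SLD_REPLACEMENT_MM = 2.5

#: Condition-number threshold on the normal equations above which the design
#: is declared non-identifiable rather than numerically noisy.
_COND_LIMIT = 1e10

ZeroSldRule = Literal["replace", "error"]


@dataclass(frozen=True)
class SegmentedFit:
    """Per-patient estimates from the segmented regression.

    Rates are in month^-1; ``sigma_hat`` is the residual SD on the log scale.
    ``saturated`` marks fits with zero residual degrees of freedom, where the
    standard errors are undefined (NaN), not zero.
    """

    patient_id: str
    y0_hat: float
    rg_hat: float
    rs_hat: float
    sigma_hat: float
    n_obs: int
    dof: int
    saturated: bool
    se_rg: float
    se_rs: float
    rss: float

    @property
    def d_hat(self) -> float:
        return self.rs_hat - self.rg_hat


@dataclass
class CohortFit:
    fits: list[SegmentedFit]
    pooled_sigma: float | None  # None when no patient has dof > 0
    failures: list[tuple[str, str]] = field(default_factory=list)  # (patient_id, message)


def design_matrix(t: np.ndarray) -> np.ndarray:
    """Design {1, t*I(t<=0), t*I(t>0)} with the breakpoint fixed at onset."""
    t = np.asarray(t, dtype=float)
    return np.column_stack(
        [np.ones_like(t), np.where(t <= 0, t, 0.0), np.where(t > 0, t, 0.0)]
    )


def _prepare_log_sld(
    series: PatientSeries, zero_sld: ZeroSldRule, zero_value: float
) -> np.ndarray:
    sld = series.slds()
    if np.any(sld == 0):
        if zero_sld == "error":
            t_zero = series.times()[sld == 0][0]
            raise ZeroSldError(series.patient_id, float(t_zero))
        sld = np.where(sld == 0, zero_value, sld)
    return np.log(sld)


def _identifiability_check(series: PatientSeries, X: np.ndarray) -> None:
    cond = np.linalg.cond(X.T @ X)
    if cond < _COND_LIMIT and np.linalg.matrix_rank(X) == 3:
        return
    pre_t = {s.t for s in series.pre_scans}
    post_t = {s.t for s in series.post_scans}
    if len(pre_t - {0.0}) == 0 and len(pre_t) <= 1:
        segment = "pre-treatment"
    elif len(post_t) == 0:
        segment = "on-treatment"
    elif len(pre_t) == 1 and len(post_t) == 1:
        segment = "joint (intercept)"
    else:
        segment = "joint"
    raise IdentifiabilityError(series.patient_id, segment)


def fit_patient(
    series: PatientSeries,
    *,
    zero_sld: ZeroSldRule = "replace",
    zero_value: float = ZERO_SLD_REPLACEMENT_MM,
) -> SegmentedFit:
    """Fit the segmented log-linear model to one patient by closed-form OLS.

    Requires an eligible series (>= 2 scans at t <= 0, >= 1 at t > 0).  With
    exactly three scans the fit interpolates the data (saturated model).
    SLD = 0 is replaced by ``zero_value`` mm before the log transform under
    the default rule, or raises :class:`ZeroSldError` with ``zero_sld='error'``.
    """
    if not series.eligible:
        raise ValueError(
            f"patient {series.patient_id!r} is not eligible for segmented fitting "
            f"(n_pre={series.n_pre}, n_post={series.n_post})"
        )
    t = series.times()
    logy = _prepare_log_sld(series, zero_sld, zero_value)
    X = design_matrix(t)
    _identifiability_check(series, X)

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ logy)
    resid = logy - X @ beta
    rss = float(resid @ resid)

    n_obs = len(t)
    dof = n_obs - 3
    saturated = dof == 0
    if saturated:
        sigma_hat = 0.0
        se_rg = se_rs = math.nan
    else:
        sigma_hat = math.sqrt(rss / dof)
        cov = sigma_hat**2 * np.linalg.inv(XtX)
        se_rg = math.sqrt(cov[1, 1])
        se_rs = math.sqrt(cov[2, 2])

    return SegmentedFit(
        patient_id=series.patient_id,
        y0_hat=float(np.exp(beta[0])),
        rg_hat=float(beta[1]),
        rs_hat=float(beta[2]),
        sigma_hat=sigma_hat,
        n_obs=n_obs,
        dof=dof,
        saturated=saturated,
        se_rg=se_rg,
        se_rs=se_rs,
        rss=rss,
    )


def fit_cohort(
    cohort: Iterable[PatientSeries],
    *,
    zero_sld: ZeroSldRule = "replace",
    zero_value: float = ZERO_SLD_REPLACEMENT_MM,
) -> CohortFit:
    """Fit every eligible patient; pool the residual SD across patients.

    ``pooled_sigma = sqrt(sum_i RSS_i / sum_i dof_i)`` over patients with
    positive residual degrees of freedom; ``None`` (not estimable) when every
    fit is saturated.  Patients whose individual fit fails are collected in
    ``failures`` rather than aborting the cohort.
    """
    fits: list[SegmentedFit] = []
    failures: list[tuple[str, str]] = []
    n_seen = 0
    for series in cohort:
        n_seen += 1
        try:
            fits.append(
                fit_patient(series, zero_sld=zero_sld, zero_value=zero_value)
            )
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            failures.append((series.patient_id, str(exc)))
    if n_seen == 0 or not fits:
        raise EmptyCohortError("no eligible patients could be fit")

    total_rss = sum(f.rss for f in fits if f.dof > 0)
    total_dof = sum(f.dof for f in fits if f.dof > 0)
    pooled = math.sqrt(total_rss / total_dof) if total_dof > 0 else None
    return CohortFit(fits=fits, pooled_sigma=pooled, failures=failures)


def doubling_time(r: float) -> float:
    """Months for tumor burden to double: ln(2)/r; NaN unless r > 0."""
    if not np.isfinite(r) or r <= 0:
        return math.nan
    return math.log(2.0) / r


def halving_time(r: float) -> float:
    """Months for tumor burden to halve: ln(0.5)/r > 0; NaN unless r < 0."""
    if not np.isfinite(r) or r >= 0:
        return math.nan
    return math.log(0.5) / r


def fits_frame(fits: Iterable[SegmentedFit]) -> pd.DataFrame:
    """Tabulate fits in the canonical fits.csv schema."""
    rows = [
        {
            "patient_id": f.patient_id,
            "y0_hat": f.y0_hat,
            "rg_hat": f.rg_hat,
            "rs_hat": f.rs_hat,
            "d_hat": f.d_hat,
            "se_rg": f.se_rg,
            "se_rs": f.se_rs,
            "sigma_hat": f.sigma_hat,
            "n_obs": f.n_obs,
            "dof": f.dof,
            "saturated": f.saturated,
        }
        for f in fits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "y0_hat",
            "rg_hat",
            "rs_hat",
            "d_hat",
            "se_rg",
            "se_rs",
            "sigma_hat",
            "n_obs",
            "dof",
            "saturated",
        ],
    )
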