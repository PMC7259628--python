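"""Longitudinal scan-table data model, CSV I/O and the eligibility filter.

The unit of analysis is one radiological assessment (:class:`ScanRecord`):
a time ``t`` in months relative to the first dose (negative = pre-treatment,
``t = 0`` is treatment onset), the sum of longest diameters (SLD, mm) and a
flag for the appearance of any new lesion.  Scans are grouped per patient
into a :class:`PatientSeries`.

A patient is *evaluable* for segmented growth-rate estimation when at least
two scans fall at ``t <= 0`` (a pre-baseline scan and a baseline scan) and at
least one at ``t > 0``.  A scan at exactly ``t = 0`` belongs to the
pre-treatment segment, matching the indicator convention of the growth model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateTimeError,
    MissingColumnError,
    RowParseError,
    ScanTableError,
)

logger = logging.getLogger(__name__)

#: Fixed calendar convention: 1 month = 365.25 / 12 days.
DAYS_PER_MONTH = 365.25 / 12

#: Reason codes attached to excluded patients.
REASON_TOO_FEW_PRE = "too_few_pre"
REASON_NO_POST = "no_post"

_TRUE_STRINGS = {"true", "1", "yes", "t", "y"}
_FALSE_STRINGS = {"false", "0", "no", "f", "n", ""}


@dataclass(frozen=True)
class ScanRecord:
    """One radiological assessment for one patient."""

    patient_id: str
    t: float  # months relative to first dose; negative = pre-treatment
    sld: float  # sum of longest diameters, mm, >= 0
    new_lesion: bool = False

    def __post_init__(self):
        if not np.isfinite(self.t):
            raise ValueError(f"scan time must be finite, got {self.t}")
        if not np.isfinite(self.sld) or self.sld < 0:
            raise ValueError(f"SLD must be finite and >= 0, got {self.sld}")


@dataclass
class PatientSeries:
    """Time-ordered scans for one patient.

    ``scans`` are sorted by ``t`` on construction; duplicate times raise
    :class:`DuplicateTimeError`.
    """

    patient_id: str
    scans: list[ScanRecord] = field(default_factory=list)

    def __post_init__(self):
        self.scans = sorted(self.scans, key=lambda s: s.t)
        for a, b in zip(self.scans, self.scans[1:]):
            if a.t == b.t:
                raise DuplicateTimeError(self.patient_id, a.t)

    @property
    def n_pre(self) -> int:
        return sum(1 for s in self.scans if s.t <= 0)

    @property
    def n_post(self) -> int:
        return sum(1 for s in self.scans if s.t > 0)

    @property
    def eligible(self) -> bool:
        return self.n_pre >= 2 and self.n_post >= 1

    @property
    def pre_scans(self) -> list[ScanRecord]:
        return [s for s in self.scans if s.t <= 0]

    @property
    def post_scans(self) -> list[ScanRecord]:
        return [s for s in self.scans if s.t > 0]

    @property
    def baseline(self) -> ScanRecord | None:
        """The baseline scan: latest scan at t <= 0, if any."""
        pre = self.pre_scans
        return pre[-1] if pre else None

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.scans], dtype=float)

    def slds(self) -> np.ndarray:
        return np.array([s.sld for s in self.scans], dtype=float)


@dataclass(frozen=True)
class ExcludedPatient:
    series: PatientSeries
    reason: str  # REASON_TOO_FEW_PRE | REASON_NO_POST


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        if pd.isna(value):
            return False
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ScanTableError(f"cannot interpret new_lesion value {value!r} as boolean")


def _coerce_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    raw = df[column]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & coerced.isna()
    if bad.any():
        raise RowParseError(column, list(np.flatnonzero(bad.to_numpy())))
    return coerced


def read_scan_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    date_mode: bool = False,
) -> list[PatientSeries]:
    """Read a delimited scan table into one :class:`PatientSeries` per patient.

    Expected columns: ``patient_id``, ``sld``, ``new_lesion`` (optional,
    defaults to all-false with a warning) and either ``t`` (months relative to
    first dose) or, with ``date_mode=True``, an ISO-8601 date pair
    ``first_dose_date``/``scan_date`` converted using 1 month = 365.25/12 days.

    Rows with missing SLD are dropped with a logged count.  Patients are
    returned sorted by identifier; scans within a patient sorted by time.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    if df.empty:
        warnings.warn(f"scan table {path} contains no data rows", stacklevel=2)
        return []

    for col in ("patient_id", "sld"):
        if col not in df.columns:
            raise MissingColumnError(col)

    if date_mode:
        for col in ("first_dose_date", "scan_date"):
            if col not in df.columns:
                raise MissingColumnError(col)
        first = pd.to_datetime(df["first_dose_date"], format="ISO8601")
        scan = pd.to_datetime(df["scan_date"], format="ISO8601")
        df = df.assign(t=(scan - first).dt.days / DAYS_PER_MONTH)
    elif "t" not in df.columns:
        raise MissingColumnError("t")

    t = _coerce_numeric(df, "t")
    sld = _coerce_numeric(df, "sld")

    if "new_lesion" in df.columns:
        new_lesion = df["new_lesion"].map(_parse_bool)
    else:
        warnings.warn(
            "scan table has no 'new_lesion' column; assuming no new lesions "
            "(growth-rate fitting does not need it; RECIST progression does)",
            stacklevel=2,
        )
        new_lesion = pd.Series(False, index=df.index)

    missing_sld = sld.isna()
    if missing_sld.any():
        logger.warning(
            "dropping %d row(s) with missing SLD from %s", int(missing_sld.sum()), path
        )
    keep = ~missing_sld
    if t.isna().any():
        raise RowParseError("t", list(np.flatnonzero(t.isna().to_numpy())))

    records = pd.DataFrame(
        {
            "patient_id": df.loc[keep, "patient_id"],
            "t": t[keep],
            "sld": sld[keep],
            "new_lesion": new_lesion[keep],
        }
    )

    cohort = []
    for pid, group in records.groupby("patient_id", sort=True):
        scans = [
            ScanRecord(str(pid), float(r.t), float(r.sld), bool(r.new_lesion))
            for r in group.itertuples()
        ]
        cohort.append(PatientSeries(str(pid), scans))
    return cohort


def write_scan_table(cohort: Iterable[PatientSeries], path: str | Path) -> None:
    """Write a cohort back to the canonical CSV dialect."""
    rows = [
        {
            "patient_id": series.patient_id,
            "t": scan.t,
            "sld": scan.sld,
            "new_lesion": scan.new_lesion,
        }
        for series in cohort
        for scan in series.scans
    ]
    frame = pd.DataFrame(rows, columns=["patient_id", "t", "sld", "new_lesion"])
    frame.to_csv(path, index=False, float_format="%.12g")


def filter_evaluable(
    cohort: Iterable[PatientSeries],
) -> tuple[list[PatientSeries], list[ExcludedPatient]]:
    """Partition a cohort into evaluable patients and excluded ones with reasons.

    Evaluable means >= 2 scans at t <= 0 and >= 1 scan at t > 0.  A patient
    failing both requirements is reported with the pre-treatment reason.
    """
    evaluable: list[PatientSeries] = []
    excluded: list[ExcludedPatient] = []
    for series in cohort:
        if series.n_pre < 2:
            excluded.append(ExcludedPatient(series, REASON_TOO_FEW_PRE))
        elif series.n_post < 1:
            excluded.append(ExcludedPatient(series, REASON_NO_POST))
        else:
            evaluable.append(series)
    return evaluable, excluded


def write_results_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    *,
    columns: Sequence[str] | None = None,
) -> None:
    """Write per-patient result mappings as a headered CSV.

    Floats are written with 12 significant digits so that a write/read
    round-trip preserves them to well under 1e-9 relative error.  For an empty
    collection, pass ``columns`` to still emit a header-only file.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        frame = pd.DataFrame(list(rows), columns=columns)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
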