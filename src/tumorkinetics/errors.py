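"""Exception types shared across the package."""


class TumorKineticsError(Exception):
    """Base class for all package-specific errors."""


class ScanTableError(TumorKineticsError):
    """Malformed scan table (missing columns, unparseable rows, ...)."""


class MissingColumnError(ScanTableError):
    def __init__(self, column: str):
        self.column = column
        super().__init__(f"required column missing from scan table: {column!r}")


class RowParseError(ScanTableError):
    def __init__(self, column: str, rows):
        self.column = column
        self.rows = list(rows)
        super().__init__(
            f"non-numeric values in column {column!r} at rows (0-based, data only): {self.rows}"
        )


class DuplicateTimeError(ScanTableError):
    def __init__(self, patient_id: str, t: float):
        self.patient_id = patient_id
        self.t = t
        super().__init__(
            f"duplicate scan time for patient {patient_id!r} at t = {t} months; "
            "duplicates indicate an upstream merge problem and are not averaged"
        )


class ZeroSldError(TumorKineticsError):
    def __init__(self, patient_id: str, t: float):
        self.patient_id = patient_id
        self.t = t
        super().__init__(
            f"SLD = 0 for patient {patient_id!r} at t = {t}; cannot log-transform "
            "(set zero_sld='replace' to substitute half the RECIST measurability floor)"
        )


class IdentifiabilityError(TumorKineticsError):
    def __init__(self, patient_id: str, segment: str):
        self.patient_id = patient_id
        self.segment = segment
        super().__init__(
            f"segmented regression design is rank deficient for patient "
            f"{patient_id!r}: the {segment} segment is not identifiable"
        )


class MissingBaselineError(TumorKineticsError):
    def __init__(self, patient_id: str):
        self.patient_id = patient_id
        super().__init__(f"patient {patient_id!r} has no scan at t <= 0 (no baseline)")


class DegenerateIntervalError(TumorKineticsError):
    def __init__(self, patient_id: str, which: str):
        self.patient_id = patient_id
        super().__init__(
            f"two-point estimator for patient {patient_id!r}: {which} anchor scans "
            "are coincident in time"
        )


class JoinError(TumorKineticsError):
    """Patient identifiers do not line up between two result collections."""


class EmptyCohortError(TumorKineticsError):
    """An operation requiring at least one eligible patient received none."""


class ScenarioError(TumorKineticsError):
    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid scenario field {field!r}: {message}")
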