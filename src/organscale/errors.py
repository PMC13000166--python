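"""Exception hierarchy shared across the package."""


class OrganScaleError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OrganScaleError):
    """A cohort file does not conform to the expected column schema."""


class CohortValidationError(OrganScaleError):
    """A cohort row or value violates a data invariant.

    Carries ``row`` (1-based data-row index, header excluded) when the
    problem is attributable to a single row.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class SpecError(OrganScaleError):
    """A generator or scenario specification is invalid."""


class DegenerateTestError(OrganScaleError):
    """A statistical test cannot be computed (e.g. zero pooled variance)."""


class DesignMatrixError(OrganScaleError):
    """A regression design matrix is rank deficient or too small."""
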