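"""Exception hierarchy shared across the pipeline stages."""


class AminoscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AminoscreenError):
    """Invalid generator or run configuration (e.g. a non-positive-definite
    correlation block, degenerate marginals)."""


class SchemaError(AminoscreenError):
    """A cohort table does not conform to the fixed schema (missing or
    misnamed columns, duplicate ids, non-numeric or non-positive
    concentrations)."""


class MatchingError(AminoscreenError):
    """One or more cases could not be matched at the requested ratio."""

    def __init__(self, message: str, failed_case_ids: list[str] | None = None):
        super().__init__(message)
        self.failed_case_ids = list(failed_case_ids or [])


class FitError(AminoscreenError):
    """A regression fit could not be attempted (single-class outcome,
    rank-deficient design, no within-stratum information)."""


class SearchError(AminoscreenError):
    """The exhaustive model search produced no usable candidate."""
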