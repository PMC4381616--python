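"""Exception hierarchy for metspread."""


class MetspreadError(Exception):
    """Base class for all metspread errors."""


class SchemaError(MetspreadError):
    """A registry file is missing a required column or has an invalid layout."""


class RegistryParseError(MetspreadError):
    """A registry row could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class VocabularyError(MetspreadError):
    """An unknown primary-site label or secondary-site code was used."""


class ConfigError(MetspreadError):
    """A synthetic-registry configuration is invalid."""


class ComparisonError(MetspreadError):
    """A subgroup comparison cannot be formed (e.g. an empty stratum)."""


class FitError(MetspreadError):
    """A model fit failed (no events, absent class, non-convergence)."""


class ConsistencyError(MetspreadError):
    """Two inputs that must describe the same cohort disagree."""
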