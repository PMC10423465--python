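"""Exception hierarchy for the budget-impact pipeline.

Every error raised by this package derives from :class:`BIAError` so callers
can catch pipeline failures without masking programming errors.
"""


class BIAError(Exception):
    """Base class for all package errors."""


class SchemaError(BIAError):
    """A CSV/YAML input does not match the documented schema."""


class RecordValidationError(BIAError):
    """A record or record set violates a domain invariant."""


class DrugLookupError(BIAError, KeyError):
    """An operation referenced a drug absent from the record set metadata."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return BIAError.__str__(self)


class MissingYearError(BIAError):
    """A computation needs a year that is absent from the series."""


class AggregationError(BIAError):
    """Savings series cannot be aggregated (empty input or mixed sectors)."""
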