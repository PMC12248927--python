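"""Exception hierarchy for feedlot_econ.

All package-specific failures derive from :class:`FeedlotEconError` so callers
(and the CLI) can catch one base class. ``DomainError`` subclasses
``ValueError`` because it always signals an argument outside the model's
domain (negative rate, non-positive weight, ...).
"""


class FeedlotEconError(Exception):
    """Base class for all feedlot_econ errors."""


class DomainError(FeedlotEconError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UndefinedRatioError(DomainError):
    """A ratio with a non-positive denominator (e.g. FCR of a zero-gain
    animal). Signals a degenerate/unprofitable record, not a crash path."""


class SchemaError(FeedlotEconError):
    """An input file does not match the documented column schema."""


class CohortValidationError(FeedlotEconError):
    """A cohort row violates a production-data invariant."""


class DuplicateCellError(FeedlotEconError):
    """Two cohorts map to the same (production profile, diet) grid cell."""
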