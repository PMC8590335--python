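"""Named validation and data-sufficiency errors raised across the package.

Every loader/validator failure maps to a distinct exception class so that
callers (and the CLI exit-code logic) can react to the specific defect
rather than parsing messages.
"""


class SurveillanceDataError(ValueError):
    """Base class for all input-validation failures."""


class MissingColumnError(SurveillanceDataError):
    """A required column is absent from an input table."""


class NoDataError(SurveillanceDataError):
    """An input table contains no rows."""


class InvalidCountError(SurveillanceDataError):
    """A count is negative, non-integer, or otherwise not a valid tally."""


class InvalidPeriodError(SurveillanceDataError):
    """A year/quarter pair does not describe a calendar quarter."""


class DuplicatePeriodError(SurveillanceDataError):
    """The same (year, quarter) appears more than once."""


class PeriodGapError(SurveillanceDataError):
    """Consecutive rows skip one or more calendar quarters."""


class StratumConsistencyError(SurveillanceDataError):
    """An age stratum reports more deaths than cases."""


class InsufficientDataError(ValueError):
    """A series is too short for the requested computation."""
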