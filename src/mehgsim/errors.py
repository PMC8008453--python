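"""Exception hierarchy for mehgsim.

All package errors derive from :class:`MehgsimError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class MehgsimError(Exception):
    """Base class for all mehgsim errors."""


class InvalidParameterError(MehgsimError, ValueError):
    """A numeric argument violates its domain (non-positive mean, limit <= 0, ...)."""


class InsufficientDataError(MehgsimError, ValueError):
    """Too few observations to perform the requested fit."""


class DegenerateDataError(MehgsimError, ValueError):
    """Data with zero spread; no scale distribution can be fitted."""


class DegenerateGroupError(MehgsimError, ValueError):
    """A consumption group with no positive amounts (or no records at all)."""


class PathologicalTruncationError(MehgsimError, ValueError):
    """Truncation limit so low that rejection sampling would almost never accept."""


class NumericDomainError(MehgsimError, FloatingPointError):
    """A CDF value hit 0 or 1 at machine precision where the formula needs (0, 1)."""


class MissingTagError(MehgsimError, KeyError):
    """A subgroup filter references demographic tags the records do not carry."""


class CalibrationError(MehgsimError, ValueError):
    """Synthetic-data calibration targets that cannot be inverted (zero share, ...)."""


class UndefinedContributionError(MehgsimError, ZeroDivisionError):
    """Group contribution shares requested for a result whose mean intake is zero."""
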