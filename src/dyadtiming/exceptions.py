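"""Exception hierarchy shared across the package."""


class DyadTimingError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DyadTimingError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(InvalidInputError):
    """Not enough observations to carry out the requested computation."""


class FormatError(DyadTimingError, ValueError):
    """A file does not conform to the documented plain-text format."""


class UndefinedMetricError(DyadTimingError, ValueError):
    """A summary metric has no defined value for this input (e.g. empty trace)."""
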