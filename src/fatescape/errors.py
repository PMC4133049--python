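"""Named exceptions for rejected inputs.

Every precondition failure raises a subclass of :class:`FatescapeError`
so callers (and the CLI) can distinguish bad data from bugs.
"""


class FatescapeError(Exception):
    """Base class for all package errors."""


class ValidationError(FatescapeError, ValueError):
    """An input violated a documented precondition."""


class NonPositiveDataError(ValidationError):
    """Raw expression values must be strictly positive."""


class NonFiniteDataError(ValidationError):
    """NaN or infinite values where finite values are required."""


class ConstantColumnError(ValidationError):
    """A column with all-tied values cannot be rank-transformed."""


class GeneMismatchError(ValidationError):
    """Gene identifiers or orderings disagree between tables."""


class EmptyIntersectionError(ValidationError):
    """Two gene panels share no identifiers."""


class SingularCorrelationError(ValidationError):
    """The fate correlation matrix is (numerically) singular."""


class DimensionMismatchError(ValidationError):
    """Array shapes are inconsistent with the panel."""
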