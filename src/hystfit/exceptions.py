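"""Exception and warning hierarchy for hystfit."""


class HystfitError(Exception):
    """Base class for all hystfit errors."""


class InvalidInputError(HystfitError, ValueError):
    """A scalar argument violates its declared domain (non-finite, out of bounds)."""


class InsufficientDataError(HystfitError, ValueError):
    """Too few cells / drawers / directions to identify the requested model."""


class IncompleteDesignError(HystfitError, ValueError):
    """A factorial profile is missing cells of the balanced 2 x D design."""


class UnsupportedTaskError(HystfitError, ValueError):
    """The requested operation has no meaning for this task type (e.g. a
    direction-based prediction for a randomized task)."""


class UndefinedVarianceError(HystfitError, ValueError):
    """A variance ratio is requested but its denominator is exactly zero."""


class NoEventError(HystfitError, ValueError):
    """No grasp event (local maximum) could be found in a trajectory."""


class ParseError(HystfitError, ValueError):
    """A trial table file is malformed; the message lists offending lines."""


class HystfitWarning(UserWarning):
    """Base class for all hystfit warnings."""


class DegenerateFitWarning(HystfitWarning):
    """The data admit no identifiable sigmoid (e.g. perfectly flat profile)."""


class UndefinedVarianceWarning(HystfitWarning):
    """Captured variance is undefined (zero total variance); NaN is reported."""


class ZeroResidualWarning(HystfitWarning):
    """All residuals are identical; standardized residuals are returned as zeros."""
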