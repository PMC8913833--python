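"""Exception hierarchy shared across the package."""


class MetabnetError(Exception):
    """Base class for all metabnet errors."""


class InvalidParameterError(MetabnetError, ValueError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(MetabnetError, ValueError):
    """Not enough records/subjects to perform the requested computation."""


class TemplateError(MetabnetError, ValueError):
    """A correlation template is malformed or not repairably positive
    semidefinite; the message names the offending (group, time point)."""


class QCError(MetabnetError, ValueError):
    """Quality control removed everything (or was handed nothing)."""


class UndefinedRatioError(MetabnetError, ArithmeticError):
    """A normalized efficiency ratio has a zero denominator, i.e. the
    degree-matched null ensemble has zero mean efficiency."""


class DegenerateMetricError(MetabnetError, RuntimeError):
    """A curve/AUC metric could not be evaluated on a (permuted) split."""
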