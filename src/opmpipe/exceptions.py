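"""Exception hierarchy shared across the pipeline."""


class OpmPipeError(Exception):
    """Base class for all package errors."""


class GeometryError(OpmPipeError):
    """Invalid sensor/source geometry (outside conductor, at origin, ...)."""


class FilterDesignError(OpmPipeError):
    """Requested filter cannot be designed (band outside (0, Nyquist), ...)."""


class ParadigmError(OpmPipeError):
    """Inconsistent task timing (events outside the recording span, ...)."""


class EmptySetError(OpmPipeError):
    """An operation that requires at least one element received none."""


class UndefinedStatisticError(OpmPipeError):
    """A statistic (gradient fit, correlation) is undefined on this input."""


class DegenerateArrayError(OpmPipeError):
    """Channel orientation matrix is rank deficient."""
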