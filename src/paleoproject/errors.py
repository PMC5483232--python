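"""Exception hierarchy shared across the package."""


class PaleoprojectError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PaleoprojectError, ValueError):
    """A parameter is out of its documented domain."""


class InsufficientDataError(PaleoprojectError, ValueError):
    """Not enough usable observations/sites/blocks to compute the quantity."""


class UndefinedStatisticError(PaleoprojectError, ZeroDivisionError):
    """A ratio statistic has a zero denominator."""


class ConvergenceError(PaleoprojectError, RuntimeError):
    """Numerical optimization failed to converge.

    Carries the best iterate found so callers can inspect it.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
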