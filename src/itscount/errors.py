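"""Exception and warning types shared across the package."""


class ItsCountError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(ItsCountError, ValueError):
    """The requested segmented design is ill-formed (odd/too-small n, bad split)."""


class ConfigError(ItsCountError, ValueError):
    """A configuration file or option set violates a validation rule."""


class EvaluationError(ItsCountError, ValueError):
    """The conditional-mean recursion produced a non-finite value.

    Carries the 1-based time index at which evaluation failed.
    """

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class ExplosionError(ItsCountError, OverflowError):
    """The conditional mean left the representable range (runaway feedback)."""


class NotConvergedError(ItsCountError, RuntimeError):
    """An operation required a converged fit but got a non-converged one."""


class SingularCovarianceError(ItsCountError, ValueError):
    """The covariance submatrix needed for a Wald test is not invertible."""


class NonstationaryWarning(UserWarning):
    """|gamma1| >= 1: the feedback recursion has no stationary regime."""
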