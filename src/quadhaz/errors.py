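"""Exception hierarchy used across the package."""


class QuadhazError(Exception):
    """Base class for all package-specific errors."""


class FormatError(QuadhazError, ValueError):
    """Input table does not have the expected layout (missing columns, ...)."""


class ParseError(FormatError):
    """A cell could not be parsed as a number; carries the offending row."""


class ValidationError(QuadhazError, ValueError):
    """Data violates a structural invariant (ordering, duplicate visits, ...)."""


class ConversionError(QuadhazError, ValueError):
    """Discrete <-> continuous coefficient conversion is not defined here."""


class EstimationError(QuadhazError, RuntimeError):
    """A model fit cannot be carried out on the given data."""


class RankDeficiencyError(EstimationError):
    """Regression design is rank deficient (e.g. a constant covariate)."""


class ConvergenceError(EstimationError):
    """Optimizer did not converge; ``last_iterate`` holds the best point found."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NumericalError(QuadhazError, ArithmeticError):
    """Numerical blow-up during ODE integration; ``t`` is the failure time."""

    def __init__(self, message, t=None):
        super().__init__(message)
        self.t = t


class SimulationError(QuadhazError, RuntimeError):
    """Non-finite trajectory during cohort simulation."""


class UnsupportedConfigurationError(QuadhazError, ValueError):
    """Requested model configuration is outside the implemented scope."""
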