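"""Exception hierarchy for tslecc."""


class TsleccError(Exception):
    """Base class for all package-specific errors."""


class InputValidationError(TsleccError, ValueError):
    """An input value violates a documented precondition."""


class UnderDeterminedError(TsleccError, ValueError):
    """A fit was requested with fewer data points than free parameters."""


class FitQualityError(TsleccError, RuntimeError):
    """A fitted model fails its quality requirements (residual, monotonicity)."""


class NoDecayError(TsleccError, ValueError):
    """A half-life fit was requested on data with no measurable decay."""


class ExtrapolationError(TsleccError, ValueError):
    """AUC tail extrapolation requested but the terminal slope is not negative."""


class OutOfRangeError(TsleccError, ValueError):
    """A value lies outside the calibrated/valid range of a curve."""


class FeasibilityError(TsleccError, ValueError):
    """A requested constraint (e.g. a target mean efficacy) is unattainable."""


class IntegrationError(TsleccError, RuntimeError):
    """The ODE solver failed to converge; diagnostics in the message."""
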