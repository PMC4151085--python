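"""Exception types shared across the pipeline."""


class WingpolError(Exception):
    """Base class for package errors."""


class InvalidParameterError(WingpolError, ValueError):
    """A parameter violates a documented precondition."""


class ConvergenceError(WingpolError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class IntegrationError(WingpolError, RuntimeError):
    """The ODE integrator failed (NaN or negative state beyond tolerance)."""


class FormatError(WingpolError, ValueError):
    """An input file is missing, unreadable, or malformed."""


class EmptyHistogramError(WingpolError, ValueError):
    """No data survived filtering; a histogram cannot be formed."""
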