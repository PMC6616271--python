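"""Package-wide exception types."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class QCError(RuntimeError):
    """Raised when a sensor series fails quality control (too many excluded points)."""


class FitError(RuntimeError):
    """Raised when a nonlinear model fit fails to converge."""
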