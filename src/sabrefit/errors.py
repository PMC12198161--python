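"""Exception hierarchy shared across the package."""


class SabrefitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SabrefitError, ValueError):
    """Invalid parameter values, datasets or specifications."""


class ConfigurationError(SabrefitError, ValueError):
    """A fitting strategy or pipeline configuration that cannot be honoured."""


class FitFailureError(SabrefitError, RuntimeError):
    """Nonlinear least squares failed to converge.

    Carries per-start diagnostics in ``details`` so the caller can see what
    was tried.
    """

    def __init__(self, message: str, details=None):
        super().__init__(message)
        self.details = details


class EstimationError(SabrefitError, RuntimeError):
    """A closed-form estimator produced an inadmissible result
    (e.g. double-reciprocal regression with slope <= 1)."""


class DiagnosticsUnavailableError(SabrefitError, RuntimeError):
    """A diagnostic was requested for a fit lacking the required internals."""
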