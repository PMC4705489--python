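"""Exception hierarchy for ambdimer."""


class AmbdimerError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AmbdimerError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class CalibrationError(AmbdimerError):
    """Surface calibration failed to reach the requested tolerances.

    Carries the residual dictionary so the caller can inspect which
    target was missed.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or {}


class IntegrationError(AmbdimerError):
    """A stochastic integrator produced an unstable step."""


class SamplingGapError(AmbdimerError):
    """Adjacent umbrella windows (or histogram bins) have no overlap."""


class ConvergenceError(AmbdimerError):
    """An iterative solver did not converge within its iteration budget."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


class ConsistencyError(AmbdimerError):
    """Two artifacts that must describe the same run do not match."""


class PartitionError(AmbdimerError, ValueError):
    """Basin regions overlap or fail to cover the bound area."""


class CoordinateError(AmbdimerError, ValueError):
    """An operation received a surface tagged with the wrong angle coordinate."""


class SaturationError(AmbdimerError):
    """The bound state engulfs the whole sampled domain (P_bound -> 1)."""


class InsufficientSamplingError(AmbdimerError):
    """Autocorrelation time is comparable to the series length."""


class FitError(AmbdimerError):
    """A model fit (e.g. Gaussian to an angular distribution) failed."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AlignmentError(AmbdimerError, ValueError):
    """Spectra are defined on different wavelength grids."""


class ParseError(AmbdimerError, ValueError):
    """A text input file is malformed."""
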