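"""Exception taxonomy shared across the package."""


class HergLqtError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HergLqtError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(HergLqtError, ValueError):
    """A configuration file or object is malformed or inconsistent."""


class NumericalFailureError(HergLqtError, RuntimeError):
    """A numerical routine lost accuracy or stability beyond tolerance."""


class ProtocolFailureError(HergLqtError, RuntimeError):
    """A stimulation protocol failed to evoke the expected response."""


class MeasurementError(HergLqtError, RuntimeError):
    """A trace does not contain the feature a measurement requires."""


class OptimizationFailureError(HergLqtError, RuntimeError):
    """All optimisation attempts failed; carries the best result so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DependencyError(HergLqtError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
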