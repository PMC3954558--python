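"""Exception hierarchy for asmgrowth."""


class AsmGrowthError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AsmGrowthError, ValueError):
    """A parameter, state or configuration violates a model invariant."""


class ConfigError(ValidationError):
    """A configuration file or flag set could not be validated."""


class IntegrationError(AsmGrowthError, RuntimeError):
    """The ODE integrator failed or produced an inadmissible state."""


class EnsembleRunError(AsmGrowthError, RuntimeError):
    """A Monte Carlo ensemble member failed; carries the offending seed."""

    def __init__(self, message: str, seed: int | None = None):
        super().__init__(message)
        self.seed = seed


class InsufficientDataError(AsmGrowthError, ValueError):
    """Not enough data points for the requested analysis."""
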