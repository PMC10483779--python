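"""Exception hierarchy shared across the package."""


class RbaleError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RbaleError, ValueError):
    """Inconsistent or invalid parameters/configuration."""


class NegativeBiomassError(RbaleError, ValueError):
    """A backscatter value below the calibration offset maps to X < 0."""


class IntegrationError(RbaleError, RuntimeError):
    """The ODE solver failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
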