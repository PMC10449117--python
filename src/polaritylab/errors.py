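"""Exception types shared across the package."""


class PolarityLabError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PolarityLabError):
    """Invalid model name, preset label, or inconsistent configuration."""


class DomainError(PolarityLabError, ValueError):
    """Input outside the mathematical domain of an operation."""


class NumericalError(PolarityLabError):
    """A numerical procedure failed (root finding, integration, continuation)."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class FormatError(PolarityLabError):
    """Corrupt or version-mismatched artifact file."""
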