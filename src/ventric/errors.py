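"""Exception hierarchy for ventric."""


class VentricError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VentricError):
    """Invalid or inconsistent user configuration."""


class GenerationError(VentricError):
    """Synthetic-anatomy generation could not satisfy its contract."""


class NumericalError(VentricError):
    """Non-finite or diverging quantities during integration."""


class ConvergenceError(VentricError):
    """An iterative procedure failed to reach its tolerance."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class AnalysisError(VentricError):
    """A marker or post-processing quantity is undefined on this input."""
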