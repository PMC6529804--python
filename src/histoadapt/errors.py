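"""Exception types shared across the package."""


class HistoAdaptError(Exception):
    """Base class for all package-specific errors."""


class SpecError(HistoAdaptError, ValueError):
    """A synthetic domain specification violates its invariants."""


class GenerationIntegrityError(HistoAdaptError):
    """Two domains that should differ produced identical pixel content."""


class InsufficientTissueError(HistoAdaptError):
    """Too few high-optical-density pixels for stain estimation."""


class DegenerateStainError(HistoAdaptError):
    """The optical-density cloud is rank deficient (single stain)."""


class WithheldLabelError(HistoAdaptError):
    """Attempted to read class labels of label-withheld manifest rows."""


class SamplingError(HistoAdaptError):
    """The requested sample composition is impossible for the data."""


class StratificationError(HistoAdaptError):
    """Patient-level splitting failed to place every class in every split."""


class ConfigError(HistoAdaptError, ValueError):
    """A network or training configuration is internally inconsistent."""


class DivergenceError(HistoAdaptError):
    """A training loss became non-finite; carries the offending state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
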