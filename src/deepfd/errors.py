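"""Exception hierarchy shared across the pipeline stages."""


class DeepFDError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DeepFDError):
    """Invalid simulation or analysis parameter (e.g. negative variance)."""


class GenerationError(DeepFDError):
    """Trait-to-measurement inversion failed (non-positive ratio trait)."""


class TraitDerivationError(DeepFDError):
    """A required raw measurement is missing or non-positive."""

    def __init__(self, measurement: str, reason: str):
        self.measurement = measurement
        super().__init__(f"cannot derive traits: measurement {measurement!r} {reason}")


class NormalizationError(DeepFDError):
    """Trait table cannot be z-scored (too few rows or zero variance)."""


class UnresolvableOccurrenceError(DeepFDError):
    """A species-by-cell occurrence has no measurable individual at any level."""


class UndefinedMetricError(DeepFDError):
    """Metric undefined for the given cell (too few species/points)."""


class DegenerateGeometryError(DeepFDError):
    """Point configuration degenerate for kernel-density volume estimation."""


class DesignError(DeepFDError):
    """Model design matrix cannot be constructed (too few distinct values)."""
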