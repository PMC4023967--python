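"""Exception hierarchy shared across the package."""


class GaitBalanceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitBalanceError):
    """Invalid parameters (ranges, dependence structure, grid setup)."""


class SchemaError(GaitBalanceError):
    """A tabular or JSON payload does not match the documented schema."""


class GenerationError(GaitBalanceError):
    """A synthetic trial cannot realize the requested balance outcome."""


class GeometryError(GaitBalanceError):
    """Degenerate or self-intersecting polygon input."""


class FlightPhaseError(GeometryError):
    """No foot in contact with the ground at the requested frame."""


class FilterParameterError(GaitBalanceError):
    """Butterworth filter preconditions violated (rate, length, cutoff)."""


class NormalizationError(GaitBalanceError):
    """Min-max normalization cannot be fitted (constant column)."""


class TrainingError(GaitBalanceError):
    """Levenberg-Marquardt update failed beyond recoverable damping."""
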