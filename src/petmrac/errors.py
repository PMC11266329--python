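"""Exception types shared across the pipeline."""


class PetmracError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(PetmracError, ValueError):
    """A lesion, bone or air-pocket site violates a geometric containment rule."""


class ConfigurationError(PetmracError, ValueError):
    """A calibration curve, class-LAC table or config block is invalid."""


class AnalysisError(PetmracError, ValueError):
    """A metric is undefined for the given inputs (empty contour, zero SUV, ...)."""
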