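"""Exception hierarchy for voxfract."""


class VoxfractError(Exception):
    """Base class for all voxfract errors."""


class ValidationError(VoxfractError):
    """Input fails a structural precondition (shape, dtype, value domain)."""


class EmptyMaskError(VoxfractError):
    """A measurement was requested on an occupancy grid with no occupied cells."""


class ScaleSelectionError(VoxfractError):
    """Fewer admissible scales than required for a log-log fit."""


class ScaleTooLargeError(VoxfractError):
    """A gliding window does not fit (at >= 2 positions) inside the mask bounding box."""


class DegenerateWindowError(VoxfractError):
    """All evaluated gliding-window masses are zero; lacunarity is undefined."""


class InsufficientScalesError(VoxfractError):
    """Fewer than three usable scales survive for the lacunarity-index fit."""


class MissingFeatureError(VoxfractError):
    """A scoring-table variable is absent from the supplied feature set."""
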