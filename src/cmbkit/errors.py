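"""Exception hierarchy shared across the pipeline stages."""


class CmbkitError(Exception):
    """Base class for all package errors."""


class DimensionalityError(CmbkitError):
    """Input volume is not a 3D scalar image."""


class MetadataError(CmbkitError):
    """Spatial metadata (spacing, affine) is missing or invalid."""


class EmptyMaskError(CmbkitError):
    """A brain mask with no foreground voxels was supplied."""


class DegenerateIntensityError(CmbkitError):
    """Image is constant inside the brain mask; normalization undefined."""


class ParameterError(CmbkitError):
    """A numeric parameter is outside its valid range."""


class ContractError(CmbkitError):
    """An operation precondition was violated (shape mismatch, empty set, ...)."""


class InpaintImpossibleError(CmbkitError):
    """The removal mask covers the whole brain; nothing to inpaint from."""


class PlacementError(CmbkitError):
    """Phantom object placement failed after bounded retries."""


class PrerequisiteError(CmbkitError):
    """A pipeline stage was invoked before its prerequisite artefacts exist."""
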