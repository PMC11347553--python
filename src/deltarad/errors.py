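"""Exception hierarchy for the delta-radiomics pipeline."""


class DeltaRadError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(DeltaRadError):
    """Image is not a 3D scalar volume."""


class GeometryError(DeltaRadError):
    """Volume and mask grids disagree (shape, spacing or origin)."""


class EmptyRoiError(DeltaRadError):
    """Mask contains no foreground voxel."""


class DegenerateAxisError(DeltaRadError):
    """An operation requiring >=2 voxels per axis met a singleton axis."""


class DegenerateMatrixError(DeltaRadError):
    """A texture matrix has no valid entry (e.g. single isolated voxel GLCM)."""


class ConfigError(DeltaRadError, ValueError):
    """Invalid configuration value."""


class SchemaError(DeltaRadError):
    """Feature vectors / tables with incompatible keys."""


class SelectionError(DeltaRadError):
    """Feature selection cannot proceed (e.g. zero-variance target)."""
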