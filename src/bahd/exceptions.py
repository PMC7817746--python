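"""Exception hierarchy shared across the package."""


class BahdError(Exception):
    """Base class for all package-specific errors."""


class EmptyMaskError(BahdError):
    """A distance operation received a mask or point set with no foreground."""


class UnitMismatchError(BahdError):
    """Two point sets with different units were combined."""


class GeometryMismatchError(BahdError):
    """Two volumes disagree in shape or voxel spacing."""


class DimensionalityError(BahdError):
    """An image on disk is not a 3D volume."""


class ParameterError(BahdError):
    """An operation received infeasible or inconsistent parameters."""


class PlacementError(BahdError):
    """The requested number of disjoint error patches could not be placed."""


class PatchConflictError(BahdError):
    """An error patch is inconsistent with the volume it is applied to."""


class DegenerateSampleError(BahdError):
    """A statistical test received a sample with no information (all-zero differences)."""
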