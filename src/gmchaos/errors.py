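"""Exception hierarchy.

Every stage raises a subclass of :class:`GMChaosError` so the pipeline can
tag errors with the stage that produced them.
"""


class GMChaosError(Exception):
    """Base class for all package errors."""


class VolumeReadError(GMChaosError):
    """File missing or unreadable as a NIfTI volume."""


class NonThreeDimensionalError(GMChaosError):
    """Input image does not have exactly 3 spatial dimensions."""


class AffineError(GMChaosError):
    """Affine is singular or otherwise unusable."""


class CovariateTableError(GMChaosError):
    """Malformed covariate table (duplicates, missing columns, NaNs)."""


class EmptyVolumeError(GMChaosError):
    """Volume has no strictly positive voxel."""


class SelectionError(GMChaosError):
    """Fewer strictly positive voxels than requested for selection."""


class ShapeMismatchError(GMChaosError):
    """Array shapes or affines do not match between inputs."""


class SeriesTooShortError(GMChaosError):
    """Series shorter than the delay embedding requires."""


class DegenerateFitError(GMChaosError):
    """Not enough valid points to fit the divergence slope."""


class DegenerateSeriesError(GMChaosError):
    """No positive neighbor distances; divergence undefined."""


class DesignMatrixError(GMChaosError):
    """Rank-deficient design or too few subjects per group."""


class PermutationError(GMChaosError):
    """Too few permutations or empty analysis mask."""


class PhantomConfigError(GMChaosError):
    """Phantom shell does not fit in the requested grid."""
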