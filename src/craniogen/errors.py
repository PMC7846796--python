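"""Exception hierarchy for craniogen.

All package errors derive from :class:`CraniogenError` so callers can catch
one base class at pipeline boundaries (the CLI maps them to exit status 1).
"""


class CraniogenError(Exception):
    """Base class for all craniogen errors."""


class ContractError(CraniogenError, ValueError):
    """An input violates a documented precondition or type invariant."""


class FormatError(CraniogenError):
    """A file is malformed or uses an unsupported dialect."""


class DimensionalityError(FormatError):
    """Data on disk is not a 3D volume."""


class ResolutionError(CraniogenError, ValueError):
    """A physical size cannot be represented at the given voxel spacing."""


class PlacementError(CraniogenError):
    """Defect placement failed (no candidates, or retries exhausted)."""


class DegenerateMaskError(CraniogenError):
    """A realized defect mask is empty after clipping to the volume."""


class VoxelizationError(CraniogenError):
    """A mesh cannot be voxelized (e.g. it has open edges)."""


class PackagingError(CraniogenError):
    """A dataset is incomplete or inconsistent at packaging time."""
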