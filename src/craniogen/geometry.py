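"""Core volumetric containers.

Volumes are indexed ``(x, y, z)`` with ``z`` the axial (slice) axis; the
voxel at index ``(i, j, k)`` has its center at the physical point
``origin + (i, j, k) * spacing`` in millimetres.  Only axis-aligned
geometry is supported: orientation matrices with off-diagonal terms are
rejected at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

__all__ = ["VolumeGeometry", "CtVolume", "SkullMask"]


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid shape, spacing and origin of a volume.

    Parameters
    ----------
    dims : tuple of int
        Grid size ``(nx, ny, nz)``; every entry must be >= 1.
    spacing : tuple of float
        Physical voxel size in mm along each axis; every entry must be > 0.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ContractError("geometry requires 3D dims, spacing and origin")
        if any(d < 1 for d in self.dims):
            raise ContractError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ContractError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def physical_size_mm(self) -> tuple[float, float, float]:
        """Extent of the grid (mm) along each axis, measured center-to-center+1."""
        return tuple(d * s for d, s in zip(self.dims, self.spacing))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of all voxels along one axis."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    def index_to_physical(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index, float) * np.asarray(self.spacing)


def _check_shape(geometry: VolumeGeometry, array: np.ndarray, what: str) -> None:
    if array.ndim != 3 or array.shape != geometry.dims:
        raise ContractError(
            f"{what} shape {array.shape} does not match geometry dims {geometry.dims}"
        )


@dataclass
class CtVolume:
    """A CT-like scalar volume in Hounsfield units."""

    geometry: VolumeGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_shape(self.geometry, self.values, "CtVolume values")


@dataclass
class SkullMask:
    """A binary bone label map (1 = bone) sharing CT geometry."""

    geometry: VolumeGeometry
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        bad = np.setdiff1d(np.unique(labels), [0, 1])
        if bad.size:
            raise ContractError(f"mask contains non-binary values {bad.tolist()}")
        self.labels = labels.astype(np.uint8, copy=False)
        _check_shape(self.geometry, self.labels, "SkullMask labels")

    @classmethod
    def from_bool(cls, geometry: VolumeGeometry, array: np.ndarray) -> "SkullMask":
        return cls(geometry, np.asarray(array, bool).astype(np.uint8))

    @property
    def voxel_count(self) -> int:
        return int(self.labels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_mm3

    @property
    def is_empty(self) -> bool:
        return self.voxel_count == 0

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)
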