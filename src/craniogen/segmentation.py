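"""Threshold-based skull extraction from CT volumes.

The pipeline mirrors the standard semi-manual workflow for producing a
binary cranium map from clinical head CT: crop to the skull region,
threshold at a bone HU value (>= 150 by default, per-case up to 200),
remove noise (CT table, intracranial calcification speckles) by keeping
the largest connected component, optionally apply median smoothing with a
physical radius (2 mm default) for speckles fused to the skull, and
optionally fill small intra-bone holes slice by slice.

All neighbourhoods are defined in physical millimetres, so anisotropic
slice spacing is handled correctly.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import yaml
from scipy import ndimage

from .errors import ContractError
from .geometry import CtVolume, SkullMask, VolumeGeometry

__all__ = [
    "SegmentationConfig",
    "crop_volume",
    "threshold_segment",
    "largest_connected_component",
    "median_smooth",
    "fill_holes_slicewise",
    "segment_skull",
    "load_config",
    "load_cohort_table",
]

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class SegmentationConfig:
    """Per-case skull-extraction parameters.

    ``crop`` is an axis-aligned half-open index box
    ``((x0, x1), (y0, y1), (z0, z1))`` or ``None`` for no cropping.
    ``smooth`` and ``fill_holes`` default off: post-processing is applied
    per case, as on clinical data where only some scans need it.
    """

    threshold_hu: float = 150.0
    crop: Optional[Box] = None
    smooth: bool = False
    smooth_radius_mm: float = 2.0
    fill_holes: bool = False
    fill_axis: str = "z"
    cavity_protection: bool = True
    cavity_fraction: float = 0.05
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold_hu):
            raise ContractError("threshold_hu must be finite")
        if self.smooth_radius_mm <= 0:
            raise ContractError("smooth_radius_mm must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ContractError("connectivity must be 6, 18 or 26")
        if self.fill_axis not in _AXES:
            raise ContractError("fill_axis must be one of 'x', 'y', 'z'")


def _validate_box(box: Box, dims: tuple[int, int, int]) -> Box:
    box = tuple((int(a), int(b)) for a, b in box)
    for axis, ((a, b), d) in enumerate(zip(box, dims)):
        if not (0 <= a < b <= d):
            raise ContractError(
                f"crop box {box} out of bounds for dims {dims} on axis {axis}"
            )
    return box


def crop_volume(volume: Union[CtVolume, SkullMask], box: Box):
    """Crop to a half-open index box; origin shifts by ``start * spacing``."""
    geo = volume.geometry
    box = _validate_box(box, geo.dims)
    (x0, x1), (y0, y1), (z0, z1) = box
    new_geo = VolumeGeometry(
        (x1 - x0, y1 - y0, z1 - z0),
        geo.spacing,
        tuple(geo.origin[i] + box[i][0] * geo.spacing[i] for i in range(3)),
    )
    if isinstance(volume, SkullMask):
        return SkullMask(new_geo, volume.labels[x0:x1, y0:y1, z0:z1].copy())
    return CtVolume(new_geo, volume.values[x0:x1, y0:y1, z0:z1].copy())


def threshold_segment(ct: CtVolume, threshold_hu: float = 150.0) -> SkullMask:
    """Label 1 exactly where HU >= threshold (inclusive boundary)."""
    return SkullMask.from_bool(ct.geometry, ct.values >= threshold_hu)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def largest_connected_component(mask: SkullMask, connectivity: int = 26) -> SkullMask:
    """Keep only the largest foreground component.

    Ties on voxel count are broken deterministically in favour of the
    component containing the lexicographically smallest ``(x, y, z)``
    voxel.  An empty input yields an empty output.
    """
    labels, n = ndimage.label(mask.labels, structure=_structure(connectivity))
    if n == 0:
        return SkullMask(mask.geometry, np.zeros(mask.geometry.dims, np.uint8))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    tied = np.flatnonzero(counts == counts.max())
    if len(tied) == 1:
        winner = tied[0]
    else:
        # arrays are (x, y, z) C-ordered, so the first flat hit among the
        # tied components is the lexicographically smallest voxel
        flat = labels.ravel()
        winner = flat[np.flatnonzero(np.isin(flat, tied))[0]]
    return SkullMask.from_bool(mask.geometry, labels == winner)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _ellipsoid_footprint(radii_vox: tuple[int, int, int]) -> np.ndarray:
    grids = np.meshgrid(
        *(np.arange(-r, r + 1) for r in radii_vox), indexing="ij"
    )
    q = np.zeros(grids[0].shape)
    for g, r in zip(grids, radii_vox):
        if r > 0:
            q = q + (g / r) ** 2
    return q <= 1.0


def median_smooth(mask: SkullMask, radius_mm: float = 2.0) -> SkullMask:
    """Majority filter over the ellipsoidal physical-radius neighbourhood.

    The per-axis radius in voxels is ``radius_mm / spacing`` rounded half
    up, so the neighbourhood is ellipsoidal when spacing is anisotropic.
    A voxel becomes 1 iff strictly more than half of the neighbourhood is
    1 (ties go to background).  Edges replicate, so a constant mask is
    invariant.  If the radius is below half the largest spacing the
    neighbourhood degenerates to a single voxel: a warning is issued and
    the mask is returned unchanged.
    """
    if radius_mm <= 0:
        raise ContractError("radius_mm must be > 0")
    radii = tuple(_round_half_up(radius_mm / s) for s in mask.geometry.spacing)
    if all(r == 0 for r in radii):
        warnings.warn(
            f"median radius {radius_mm} mm spans no neighbours at spacing "
            f"{mask.geometry.spacing}; mask returned unchanged",
            stacklevel=2,
        )
        return SkullMask(mask.geometry, mask.labels.copy())
    footprint = _ellipsoid_footprint(radii)
    counts = ndimage.correlate(
        mask.labels.astype(np.int32), footprint.astype(np.int32), mode="nearest"
    )
    return SkullMask.from_bool(mask.geometry, counts * 2 > int(footprint.sum()))


def fill_holes_slicewise(
    mask: SkullMask,
    axis: str = "z",
    cavity_protection: bool = True,
    cavity_fraction: float = 0.05,
) -> SkullMask:
    """Fill enclosed background regions slice by slice.

    In every 2D slice perpendicular to ``axis``, background regions
    (4-connected) with no path to the slice border are set to foreground.
    With ``cavity_protection`` on (default), a slice region is skipped if
    it belongs to a 3D background component (6-connected) that is both
    enclosed (no path to the volume border) and larger than
    ``cavity_fraction`` of the volume — this leaves the cranial cavity
    untouched in slices where the bone cross-section encloses it, while
    still filling small intra-bone holes and gaps open along the slicing
    axis.
    """
    ax = _AXES.get(axis)
    if ax is None:
        raise ContractError("axis must be one of 'x', 'y', 'z'")
    labels = np.moveaxis(mask.labels, ax, 0)  # view: slices first
    out = labels.copy()
    protected = None
    if cavity_protection:
        bg3d, n3 = ndimage.label(mask.labels == 0, structure=_structure(6))
        if n3 > 0:
            counts = np.bincount(bg3d.ravel())
            counts[0] = 0
            on_border = np.unique(
                np.concatenate(
                    [
                        bg3d[0].ravel(), bg3d[-1].ravel(),
                        bg3d[:, 0].ravel(), bg3d[:, -1].ravel(),
                        bg3d[:, :, 0].ravel(), bg3d[:, :, -1].ravel(),
                    ]
                )
            )
            counts[on_border] = 0  # border-connected background is exterior
            big = np.flatnonzero(counts > cavity_fraction * mask.labels.size)
            protected = np.moveaxis(np.isin(bg3d, big), ax, 0)
    s2d = ndimage.generate_binary_structure(2, 1)
    for k in range(labels.shape[0]):
        bg = labels[k] == 0
        lab2, n2 = ndimage.label(bg, structure=s2d)
        if n2 == 0:
            continue
        border = np.unique(
            np.concatenate(
                [lab2[0, :], lab2[-1, :], lab2[:, 0], lab2[:, -1]]
            )
        )
        enclosed = bg & ~np.isin(lab2, border)
        if protected is not None:
            enclosed &= ~protected[k]
        out[k][enclosed] = 1
    return SkullMask(mask.geometry, np.moveaxis(out, 0, ax))


def segment_skull(ct: CtVolume, config: SegmentationConfig | None = None) -> SkullMask:
    """Full extraction pipeline with fixed stage order.

    crop -> threshold -> largest connected component -> optional median
    smoothing -> optional slice-wise hole filling.
    """
    if config is None:
        config = SegmentationConfig()
    if config.crop is not None:
        ct = crop_volume(ct, config.crop)
    mask = threshold_segment(ct, config.threshold_hu)
    mask = largest_connected_component(mask, config.connectivity)
    if config.smooth:
        mask = median_smooth(mask, config.smooth_radius_mm)
    if config.fill_holes:
        mask = fill_holes_slicewise(
            mask, config.fill_axis, config.cavity_protection, config.cavity_fraction
        )
    return mask


# ---------------------------------------------------------------------------
# configuration files


def _parse_crop(text: str) -> Optional[Box]:
    text = text.strip()
    if not text or text.lower() in ("none", "no", "-"):
        return None
    parts = text.replace(" ", "").split(",")
    if len(parts) != 3:
        raise ContractError(f"crop must have three 'a:b' ranges, got {text!r}")
    return tuple(tuple(int(v) for v in p.split(":")) for p in parts)  # type: ignore


def load_config(path) -> SegmentationConfig:
    """Load a single-case config from a flat YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ContractError(f"{path}: config must be a flat mapping")
    if isinstance(data.get("crop"), str):
        data["crop"] = _parse_crop(data["crop"])
    try:
        return SegmentationConfig(**data)
    except TypeError as exc:
        raise ContractError(f"{path}: {exc}") from exc


def load_cohort_table(path) -> dict[str, SegmentationConfig]:
    """Load a per-case CSV table: case,crop,threshold_hu,smooth,fill_holes.

    ``crop`` is given as ``x0:x1,y0:y1,z0:z1`` (quoted) or empty.
    """
    truthy = {"1", "true", "yes", "y"}
    out: dict[str, SegmentationConfig] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cfg = SegmentationConfig(
                threshold_hu=float(row.get("threshold_hu") or 150.0),
                crop=_parse_crop(row.get("crop") or ""),
                smooth=(row.get("smooth") or "").strip().lower() in truthy,
                fill_holes=(row.get("fill_holes") or "").strip().lower() in truthy,
            )
            out[row["case"]] = cfg
    return out
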