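"""Randomized artificial craniotomy-defect injection.

A defect is carved out of a complete binary skull by intersecting it with
a randomly placed erasing mask — a cube, cuboid or sphere sized in
physical millimetres — optionally decorated with small spheres ("drill
holes") on its corners to mimic the roundish gap a craniotome leaves at
the defect border.  The removed bone is the implant:

    defective = complete AND NOT mask
    implant   = complete AND mask

so with zero implant offset the pair partitions the complete skull
exactly (union restores it, intersection is empty) — the supervised
ground truth for automatic implant-design models.  Placement is
restricted to the cranial vault (the top fraction of the skull's bounding
box along z) and rejection-sampled until the removed volume exceeds a
minimum, so grazing masks that shave off slivers are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import ContractError, DegenerateMaskError, PlacementError
from .geometry import SkullMask, VolumeGeometry

__all__ = [
    "DefectSpec",
    "RealizedDefect",
    "DefectPair",
    "DefectDataset",
    "CaseRecord",
    "make_defect_mask",
    "sample_center",
    "inject_defect",
    "enlarge_dataset",
    "apply_implant_offset",
]

SHAPES = ("cube", "cuboid", "sphere")


@dataclass(frozen=True)
class DefectSpec:
    """Template for one randomized defect.

    ``shape=None`` draws a shape kind uniformly from cube/cuboid/sphere;
    sizes (cube edge, cuboid edges, sphere diameter) are drawn uniformly
    from ``size_range_mm``.  ``n_drill_holes=None`` draws 1-4 corner
    holes; 0 disables them.  ``vault_fraction`` restricts candidate
    centers to the top fraction of the skull bounding box along z.
    """

    shape: Optional[str] = None
    size_range_mm: tuple[float, float] = (40.0, 90.0)
    n_drill_holes: Optional[int] = None
    hole_radius_mm: float = 5.0
    vault_fraction: float = 0.5
    min_removed_mm3: float = 5000.0
    max_attempts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range_mm
        if not (0 < lo <= hi):
            raise ContractError(f"invalid size range {self.size_range_mm}")
        if self.shape is not None and self.shape not in SHAPES:
            raise ContractError(f"shape must be one of {SHAPES} or None")
        if self.n_drill_holes is not None and not (0 <= self.n_drill_holes <= 4):
            raise ContractError("n_drill_holes must be in 0..4")
        if self.hole_radius_mm < 0 or self.hole_radius_mm >= lo:
            raise ContractError("hole_radius_mm must be >= 0 and < min shape size")
        if not (0 < self.vault_fraction <= 1):
            raise ContractError("vault_fraction must be in (0, 1]")
        if self.max_attempts < 1:
            raise ContractError("max_attempts must be >= 1")


@dataclass(frozen=True)
class RealizedDefect:
    """The concrete values drawn for one defect mask."""

    shape: str
    size_mm: tuple[float, ...]  # (edge,)*3 for cube/cuboid, (diameter,) for sphere
    hole_radius_mm: float
    hole_centers_mm: tuple[tuple[float, float, float], ...]
    center_index: tuple[int, int, int]
    seed: int


@dataclass
class DefectPair:
    """(complete, defective, implant) triple over shared geometry."""

    complete: SkullMask
    defective: SkullMask
    implant: SkullMask
    spec_used: RealizedDefect
    mask_center: tuple[int, int, int]
    offset_mm: float = 0.0

    def __post_init__(self) -> None:
        g = self.complete.geometry
        if self.defective.geometry != g or self.implant.geometry != g:
            raise ContractError("pair members do not share geometry")
        self.validate()

    def validate(self) -> None:
        """Assert the set-algebra invariants (never assumed, always checked)."""
        comp = self.complete.as_bool()
        dfct = self.defective.as_bool()
        impl = self.implant.as_bool()
        if (dfct & impl).any():
            raise ContractError("defective and implant overlap")
        if self.offset_mm == 0.0:
            if not np.array_equal(dfct | impl, comp):
                raise ContractError("defective OR implant != complete")
        else:
            if (impl & ~(comp & ~dfct)).any():
                raise ContractError("offset implant exceeds the removed region")


@dataclass
class CaseRecord:
    case_id: str
    complete: SkullMask
    pairs: list[DefectPair]


@dataclass
class DefectDataset:
    cases: list[CaseRecord]

    @property
    def n_pairs(self) -> int:
        return sum(len(c.pairs) for c in self.cases)

    @property
    def n_skull_volumes(self) -> int:
        """Complete skulls plus defective variants."""
        return len(self.cases) + self.n_pairs


# ---------------------------------------------------------------------------
# mask construction


def _realize(
    spec: DefectSpec,
    center: tuple[int, int, int],
    geometry: VolumeGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, RealizedDefect]:
    """Draw a concrete mask; returns (bool labels, realized parameters)."""
    shape = spec.shape or SHAPES[rng.integers(len(SHAPES))]
    lo, hi = spec.size_range_mm
    if shape == "cube":
        size = (float(rng.uniform(lo, hi)),) * 3
    elif shape == "cuboid":
        size = tuple(float(v) for v in rng.uniform(lo, hi, size=3))
    else:
        size = (float(rng.uniform(lo, hi)),)
    n_holes = (
        spec.n_drill_holes
        if spec.n_drill_holes is not None
        else int(rng.integers(1, 5))
    )
    c_mm = geometry.index_to_physical(center)
    if shape == "sphere":
        radius = size[0] / 2
        corners = c_mm + radius * _random_unit(rng, n_holes)
    else:
        half = np.asarray(size if len(size) == 3 else size * 3) / 2
        signs = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
            float,
        )
        picks = rng.choice(8, size=n_holes, replace=False) if n_holes else []
        corners = c_mm + signs[picks] * half
    labels = _rasterize(geometry, c_mm, shape, size, corners, spec.hole_radius_mm)
    realized = RealizedDefect(
        shape=shape,
        size_mm=size,
        hole_radius_mm=spec.hole_radius_mm,
        hole_centers_mm=tuple(tuple(float(v) for v in c) for c in corners),
        center_index=tuple(int(v) for v in center),
        seed=spec.seed,
    )
    return labels, realized


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True) if n else v.reshape(0, 3)


def _rasterize(geometry, c_mm, shape, size, hole_centers, hole_radius) -> np.ndarray:
    """Voxelize base shape + corner holes inside their joint bounding box only."""
    if shape == "sphere":
        half = np.full(3, size[0] / 2)
    else:
        half = np.asarray(size) / 2
    pad = half + (hole_radius if len(hole_centers) else 0.0) + 1.0
    spacing = np.asarray(geometry.spacing)
    origin = np.asarray(geometry.origin)
    lo_idx = np.maximum(np.floor((c_mm - pad - origin) / spacing).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil((c_mm + pad - origin) / spacing).astype(int) + 1,
        np.asarray(geometry.dims),
    )
    labels = np.zeros(geometry.dims, bool)
    if (lo_idx >= hi_idx).any():
        return labels
    coords = [
        origin[a] + np.arange(lo_idx[a], hi_idx[a]) * spacing[a] for a in range(3)
    ]
    dx = (coords[0] - c_mm[0])[:, None, None]
    dy = (coords[1] - c_mm[1])[None, :, None]
    dz = (coords[2] - c_mm[2])[None, None, :]
    if shape == "sphere":
        r = size[0] / 2
        window = dx**2 + dy**2 + dz**2 <= r**2
    else:
        window = (
            (np.abs(dx) <= half[0]) & (np.abs(dy) <= half[1]) & (np.abs(dz) <= half[2])
        )
    for hc in hole_centers:
        hx = (coords[0] - hc[0])[:, None, None]
        hy = (coords[1] - hc[1])[None, :, None]
        hz = (coords[2] - hc[2])[None, None, :]
        window |= hx**2 + hy**2 + hz**2 <= hole_radius**2
    labels[lo_idx[0] : hi_idx[0], lo_idx[1] : hi_idx[1], lo_idx[2] : hi_idx[2]] = window
    return labels


def make_defect_mask(
    spec: DefectSpec,
    center: tuple[int, int, int],
    geometry: VolumeGeometry,
    rng: np.random.Generator | None = None,
) -> SkullMask:
    """Build one erasing mask centered at a voxel index.

    Deterministic for fixed ``spec.seed`` and ``center`` when no external
    random generator is supplied.

    Raises
    ------
    DegenerateMaskError
        If the realized mask is empty after clipping to the volume.
    """
    center = tuple(int(v) for v in center)
    if any(not (0 <= c < d) for c, d in zip(center, geometry.dims)):
        raise ContractError(f"center {center} outside geometry dims {geometry.dims}")
    if rng is None:
        rng = np.random.default_rng([spec.seed, *center])
    labels, _ = _realize(spec, center, geometry, rng)
    if not labels.any():
        raise DegenerateMaskError(
            f"defect mask at center {center} is empty after clipping"
        )
    return SkullMask.from_bool(geometry, labels)


# ---------------------------------------------------------------------------
# placement and injection


def _vault_candidates(skull: SkullMask, vault_fraction: float) -> np.ndarray:
    idx = np.argwhere(skull.labels == 1)
    if idx.size == 0:
        raise PlacementError("cannot place a defect in an empty skull")
    z = idx[:, 2]
    z_lo, z_hi = int(z.min()), int(z.max())
    z_cut = z_hi - vault_fraction * (z_hi - z_lo)
    cand = idx[z >= z_cut]
    if cand.size == 0:
        raise PlacementError(
            f"no candidate bone voxels in top {vault_fraction:.0%} of the vault"
        )
    return cand


def sample_center(
    skull: SkullMask, spec: DefectSpec, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Uniformly sample a bone voxel within the vault placement region."""
    cand = _vault_candidates(skull, spec.vault_fraction)
    return tuple(int(v) for v in cand[rng.integers(len(cand))])


def inject_defect(
    complete: SkullMask,
    spec: DefectSpec,
    rng: np.random.Generator | None = None,
) -> DefectPair:
    """Carve one randomized defect out of a complete skull.

    Retries with fresh centers from the same random stream (up to
    ``spec.max_attempts``) until the removed bone volume reaches
    ``spec.min_removed_mm3``.

    Raises
    ------
    PlacementError
        If no attempt removes enough bone; the message names the realized
        parameters of the last attempt.
    """
    if complete.is_empty:
        raise PlacementError("cannot inject a defect into an empty skull")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    geometry = complete.geometry
    cand = _vault_candidates(complete, spec.vault_fraction)
    comp = complete.as_bool()
    voxvol = geometry.voxel_volume_mm3
    last: RealizedDefect | None = None
    for _ in range(spec.max_attempts):
        center = tuple(int(v) for v in cand[rng.integers(len(cand))])
        labels, realized = _realize(spec, center, geometry, rng)
        last = realized
        impl = comp & labels
        if impl.sum() * voxvol < spec.min_removed_mm3:
            continue
        dfct = comp & ~labels
        return DefectPair(
            complete=complete,
            defective=SkullMask.from_bool(geometry, dfct),
            implant=SkullMask.from_bool(geometry, impl),
            spec_used=realized,
            mask_center=center,
        )
    raise PlacementError(
        f"no valid placement after {spec.max_attempts} attempts; "
        f"last realized defect: {last}"
    )


def enlarge_dataset(
    skulls: Sequence[Union[SkullMask, tuple[str, SkullMask]]],
    n_defects_per_skull: int = 10,
    spec_template: DefectSpec | None = None,
    seed: int = 0,
    max_reseeds: int = 5,
) -> DefectDataset:
    """Create ``n_defects_per_skull`` randomized pairs for every skull.

    Each (case, defect) slot gets an independently derived seed from
    ``(seed, case index, defect index)``, so the realized defects vary in
    shape, size and position, and the whole dataset is reproducible from
    ``seed`` alone.  A slot whose placement fails is retried with a fresh
    derived seed up to ``max_reseeds`` times before the failure is
    reported.

    ``skulls`` may be plain masks or ``(case_id, mask)`` pairs; plain
    masks get identifiers "Case01", "Case02", ...
    """
    if n_defects_per_skull < 1:
        raise ContractError("n_defects_per_skull must be >= 1")
    if spec_template is None:
        spec_template = DefectSpec()
    width = max(2, len(str(len(skulls))))
    cases: list[CaseRecord] = []
    for i, item in enumerate(skulls):
        if isinstance(item, tuple):
            case_id, mask = item
        else:
            case_id, mask = f"Case{i + 1:0{width}d}", item
        pairs: list[DefectPair] = []
        for j in range(n_defects_per_skull):
            err: PlacementError | None = None
            for retry in range(max_reseeds + 1):
                child = int(
                    np.random.SeedSequence([seed, i, j, retry]).generate_state(1)[0]
                    % (2**31)
                )
                spec = replace(spec_template, seed=child)
                try:
                    pairs.append(inject_defect(mask, spec))
                    err = None
                    break
                except PlacementError as exc:
                    err = exc
            if err is not None:
                raise PlacementError(
                    f"{case_id} defect {j + 1}: placement failed after "
                    f"{max_reseeds + 1} reseeds"
                ) from err
        cases.append(CaseRecord(case_id, mask, pairs))
    return DefectDataset(cases)


def apply_implant_offset(pair: DefectPair, offset_mm: float) -> DefectPair:
    """Erode the implant by a spherical element of physical radius ``offset_mm``.

    Models the clinical implant offset (the drilling gap between implant
    and defect border).  ``offset_mm == 0`` is the identity; the defective
    skull is never modified, and the partition invariant is relaxed to
    ``implant <= complete AND NOT defective``.
    """
    if offset_mm < 0:
        raise ContractError("offset_mm must be >= 0")
    if offset_mm == 0:
        return pair
    # erosion by a physical-radius ball == thresholding the Euclidean
    # distance to background (anisotropic spacing handled by sampling)
    dist = ndimage.distance_transform_edt(
        pair.implant.as_bool(), sampling=pair.complete.geometry.spacing
    )
    eroded = dist > offset_mm
    if not eroded.any():
        raise ContractError(
            f"offset {offset_mm} mm erodes the implant to nothing"
        )
    return DefectPair(
        complete=pair.complete,
        defective=pair.defective,
        implant=SkullMask.from_bool(pair.complete.geometry, eroded),
        spec_used=pair.spec_used,
        mask_center=pair.mask_center,
        offset_mm=offset_mm,
    )
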