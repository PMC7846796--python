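"""Parametric CT head phantom with a known ground-truth skull mask.

The phantom models the neurocranium as a closed ellipsoidal bone shell
(difference of two concentric ellipsoids) surrounded by air, with soft
tissue filling the cranial cavity.  Two optional nuisance structures
reproduce the noise sources a threshold-based skull segmentation has to
cope with on clinical CT:

* intracranial *calcification speckles* — small high-density spheres in
  the soft tissue, some floating freely and some touching the inner shell
  surface (the latter survive connected-component filtering and must be
  removed by smoothing);
* a *CT-table slab* — a flat high-density bar under the head (low y),
  disjoint from the skull, which thresholding picks up as a separate
  connected component.

Everything above the 150 HU bone threshold that is not the shell is, by
construction, either a speckle or the table, so the ground-truth mask is
known exactly and every downstream stage can be tested without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ContractError, ResolutionError
from .geometry import CtVolume, SkullMask, VolumeGeometry

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_cohort",
    "paper_scale_geometry",
    "default_geometry",
]

#: Fast test-scale grid: 128 x 128 x 96 voxels at 1.5 mm isotropic.
def default_geometry() -> VolumeGeometry:
    return VolumeGeometry((128, 128, 96), (1.5, 1.5, 1.5))


def paper_scale_geometry() -> VolumeGeometry:
    """Clinical-CT-scale grid: 512 x 512 x 150 at (0.98, 0.98, 1.25) mm."""
    return VolumeGeometry((512, 512, 150), (0.98, 0.98, 1.25))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head volume.

    HU values follow the CT convention: air -1000, soft tissue ~+40,
    calcifications ~+400, compact bone ~+1000.  The bone threshold used
    throughout the package is 150 HU, so ``bone_hu`` and
    ``calcification_hu`` must be >= 150 and all background values < 150.
    """

    geometry: VolumeGeometry = field(default_factory=default_geometry)
    outer_radii: tuple[float, float, float] = (65.0, 80.0, 55.0)  # mm semi-axes
    shell_thickness: float = 6.0  # mm
    bone_hu: float = 1000.0
    air_hu: float = -1000.0
    soft_tissue_hu: float = 40.0
    n_calcifications: int = 8
    calcification_hu: float = 400.0
    calcification_radius_mm: float = 3.0
    calcification_touch_fraction: float = 0.3
    include_table: bool = False
    table_hu: float = 800.0
    table_thickness_mm: float = 3.0
    table_width_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_thickness <= 0 or self.shell_thickness >= min(self.outer_radii):
            raise ContractError(
                "shell_thickness must be in (0, min(outer_radii)), got "
                f"{self.shell_thickness} vs radii {self.outer_radii}"
            )
        if self.bone_hu < 150 or self.calcification_hu < 150:
            raise ContractError("bone_hu and calcification_hu must be >= 150 HU")
        if max(self.air_hu, self.soft_tissue_hu) >= 150:
            raise ContractError("background HU values must be < 150")
        if self.n_calcifications < 0:
            raise ContractError("n_calcifications must be >= 0")


def _ellipsoid(geometry: VolumeGeometry, center_mm, semiaxes_mm) -> np.ndarray:
    xs = (geometry.axis_coordinates(0) - center_mm[0]) / semiaxes_mm[0]
    ys = (geometry.axis_coordinates(1) - center_mm[1]) / semiaxes_mm[1]
    zs = (geometry.axis_coordinates(2) - center_mm[2]) / semiaxes_mm[2]
    return (
        xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
    ) <= 1.0


def _sphere(geometry: VolumeGeometry, center_mm, radius_mm) -> np.ndarray:
    return _ellipsoid(geometry, center_mm, (radius_mm,) * 3)


def generate_phantom(spec: PhantomSpec) -> tuple[CtVolume, SkullMask]:
    """Generate one phantom.

    Returns the HU volume and the ground-truth bone mask (the ellipsoidal
    shell only — calcifications and the table are deliberately excluded).
    Deterministic for a fixed ``spec.seed``.

    Raises
    ------
    ResolutionError
        If the shell is thinner than one voxel at the given spacing.
    """
    geo = spec.geometry
    if spec.shell_thickness < max(geo.spacing):
        raise ResolutionError(
            f"shell thickness {spec.shell_thickness} mm is thinner than one voxel "
            f"at spacing {geo.spacing}"
        )
    rng = np.random.default_rng(spec.seed)
    center = tuple(
        geo.origin[i] + 0.5 * (geo.dims[i] - 1) * geo.spacing[i] for i in range(3)
    )
    outer = _ellipsoid(geo, center, spec.outer_radii)
    inner_radii = tuple(r - spec.shell_thickness for r in spec.outer_radii)
    inner = _ellipsoid(geo, center, inner_radii)
    shell = outer & ~inner

    hu = np.full(geo.dims, spec.air_hu, dtype=np.float32)
    hu[outer] = spec.soft_tissue_hu

    if spec.include_table:
        table = _table_slab(spec, outer)
        hu[table] = spec.table_hu

    for _ in range(spec.n_calcifications):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r_c = spec.calcification_radius_mm
        if rng.random() < spec.calcification_touch_fraction:
            # seat the speckle against the inner shell surface
            boundary = np.asarray(center) + np.asarray(inner_radii) * u
            c = boundary - u * r_c
        else:
            # float it well inside the cavity (2 mm clearance)
            scale = rng.random() ** (1 / 3)
            safe = np.asarray(inner_radii) - r_c - 2.0
            if (safe <= 0).any():
                continue
            c = np.asarray(center) + safe * u * scale
        speckle = _sphere(geo, c, r_c) & inner
        hu[speckle] = spec.calcification_hu

    hu[shell] = spec.bone_hu  # bone written last: shell HU wins everywhere
    return CtVolume(geo, hu), SkullMask.from_bool(geo, shell)


def _table_slab(spec: PhantomSpec, head: np.ndarray) -> np.ndarray:
    """Flat slab at low y spanning z, clipped away from the head."""
    geo = spec.geometry
    nx, ny, nz = geo.dims
    t_vox = max(1, round(spec.table_thickness_mm / geo.spacing[1]))
    half_w = max(1, int(0.5 * spec.table_width_fraction * nx))
    table = np.zeros(geo.dims, bool)
    x0, x1 = nx // 2 - half_w, nx // 2 + half_w
    table[x0:x1, 1 : 1 + t_vox, :] = True
    # guarantee a one-voxel gap to the head so thresholding yields a
    # separate connected component
    table &= ~ndimage.binary_dilation(
        head, structure=ndimage.generate_binary_structure(3, 3)
    )
    return table


def generate_cohort(
    n_cases: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    radius_jitter: float = 0.08,
    thickness_jitter: float = 0.15,
) -> list[tuple[str, CtVolume, SkullMask]]:
    """Generate a cohort of per-case jittered phantoms.

    Each case gets radii and shell thickness independently jittered by a
    uniform fraction (``+- radius_jitter`` / ``+- thickness_jitter``) and
    an independently derived seed, so no two cases are voxel-identical.
    Case identifiers are "Case01", "Case02", ... zero-padded to width 2.

    Returns a list of ``(case_id, ct, ground_truth_mask)`` triples.
    """
    if n_cases < 1:
        raise ContractError("n_cases must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    width = max(2, len(str(n_cases)))
    out = []
    for i in range(n_cases):
        ss = np.random.SeedSequence([seed, i])
        jit_rng = np.random.default_rng(ss)
        radii = tuple(
            r * (1 + jit_rng.uniform(-radius_jitter, radius_jitter))
            for r in base_spec.outer_radii
        )
        thickness = base_spec.shell_thickness * (
            1 + jit_rng.uniform(-thickness_jitter, thickness_jitter)
        )
        child_seed = int(ss.generate_state(1)[0] % (2**31))
        spec = replace(
            base_spec, outer_radii=radii, shell_thickness=thickness, seed=child_seed
        )
        ct, mask = generate_phantom(spec)
        out.append((f"Case{i + 1:0{width}d}", ct, mask))
    return out
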