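"""Conversions among volume, mesh and point-cloud skull representations.

``binary_to_mesh`` runs marching cubes at iso-level 0.5 on the binary
field (no pre-smoothing by default) and returns vertices in physical mm.
``mesh_to_binary`` performs solid voxelization of a watertight mesh with
a voxel-center inside test: a column of rays along +z accumulates surface
crossings per voxel column, and a center is inside iff the number of
crossings below it is odd.  For a shell mesh with two nested closed
components this parity rule labels exactly the material between the
surfaces.  ``volume_to_pointcloud`` emits voxel centers, either all
foreground voxels or only those on the 6-connected surface.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ContractError, VoxelizationError
from .geometry import SkullMask, VolumeGeometry
from .mesh_types import PointCloud, SurfaceMesh

__all__ = [
    "binary_to_mesh",
    "mesh_to_binary",
    "volume_to_pointcloud",
    "write_xyz",
    "read_xyz",
]


def binary_to_mesh(mask: SkullMask, smooth_sigma_mm: float = 0.0) -> SurfaceMesh:
    """Extract the iso-surface of a binary mask with marching cubes.

    Parameters
    ----------
    mask : SkullMask
        Non-empty binary volume.
    smooth_sigma_mm : float
        Optional Gaussian pre-smoothing of the scalar field (mm).  Off by
        default: the raw 0.5 iso-surface of the {0,1} field is extracted,
        so meshes show the usual marching-cubes staircase rather than the
        smoothed surfaces interactive tools export.

    Returns
    -------
    SurfaceMesh
        Vertices in physical mm; watertight for shells not touching the
        volume border (the field is zero-padded so border-touching masks
        still close).  Zero-area triangles are dropped.
    """
    if mask.is_empty:
        raise ContractError("cannot mesh an empty mask")
    geo = mask.geometry
    field = np.pad(mask.labels.astype(np.float32), 1)
    if smooth_sigma_mm > 0:
        sigma = [smooth_sigma_mm / s for s in geo.spacing]
        field = ndimage.gaussian_filter(field, sigma=sigma)
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=geo.spacing)
    verts = verts - np.asarray(geo.spacing) + np.asarray(geo.origin)
    mesh = SurfaceMesh(verts, faces)
    areas = mesh.triangle_areas()
    keep = areas > 1e-12
    if not keep.all():
        mesh = _drop_faces(mesh, keep)
    return mesh


def _drop_faces(mesh: SurfaceMesh, keep: np.ndarray) -> SurfaceMesh:
    faces = mesh.triangles[keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces])


def mesh_to_binary(mesh: SurfaceMesh, geometry: VolumeGeometry) -> SkullMask:
    """Solid-voxelize a closed mesh onto a voxel grid.

    A voxel is labelled 1 iff its center lies inside the closed surface
    by the ray-crossing parity rule; for nested shells the material
    between the outer and inner surface is labelled.

    Raises
    ------
    VoxelizationError
        If the mesh is not watertight (the message reports the open
        edges).
    """
    open_edges = mesh.open_edges()
    if len(open_edges):
        sample = open_edges[:5].tolist()
        raise VoxelizationError(
            f"mesh is not watertight: {len(open_edges)} open edges, "
            f"e.g. vertex pairs {sample}"
        )
    nx, ny, nz = geometry.dims
    # vertices in continuous index coordinates; tiny irrational-ish shifts
    # in x/y keep ray-through-edge hits measure-zero
    v = (mesh.vertices - np.asarray(geometry.origin)) / np.asarray(geometry.spacing)
    v = v + np.array([2.30009e-4, 3.70013e-4, 0.0])
    tris = v[mesh.triangles]  # (M, 3, 3)
    flips = np.zeros((nx, ny, nz + 1), dtype=np.int32)
    for a, b, c in tris:
        xy = np.array([a[:2], b[:2], c[:2]])
        lo = np.maximum(np.ceil(xy.min(axis=0)).astype(int), 0)
        hi = np.minimum(np.floor(xy.max(axis=0)).astype(int), [nx - 1, ny - 1])
        if (lo > hi).any():
            continue
        d1, d2 = xy[1] - xy[0], xy[2] - xy[0]
        denom = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(denom) < 1e-12:
            continue  # vertical triangle: projects to a line, no crossing
        ii = np.arange(lo[0], hi[0] + 1)
        jj = np.arange(lo[1], hi[1] + 1)
        px = ii[:, None] - xy[0, 0]
        py = jj[None, :] - xy[0, 1]
        l1 = (px * d2[1] - py * d2[0]) / denom
        l2 = (py * d1[0] - px * d1[1]) / denom
        inside = (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1)
        if not inside.any():
            continue
        zc = a[2] + l1 * (b[2] - a[2]) + l2 * (c[2] - a[2])
        k = np.clip(np.floor(zc[inside] + 1e-9).astype(int) + 1, 0, nz)
        iw, jw = np.nonzero(inside)
        np.add.at(flips, (ii[iw], jj[jw], k), 1)
    parity = np.cumsum(flips, axis=2)[:, :, :nz] % 2
    return SkullMask.from_bool(geometry, parity == 1)


def volume_to_pointcloud(mask: SkullMask, mode: str = "surface") -> PointCloud:
    """Extract voxel-center points from a binary volume.

    mode "all": one point per foreground voxel.  mode "surface": only
    foreground voxels with at least one 6-connected background neighbour
    (the volume boundary counts as background).
    """
    if mode not in ("all", "surface"):
        raise ContractError("mode must be 'all' or 'surface'")
    if mask.is_empty:
        raise ContractError("cannot extract points from an empty mask")
    fg = mask.as_bool()
    if mode == "surface":
        padded = np.pad(fg, 1)
        has_bg = np.zeros_like(fg)
        for axis in range(3):
            for shift in (-1, 1):
                neigh = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
                has_bg |= ~neigh
        fg = fg & has_bg
    idx = np.argwhere(fg)
    points = idx * np.asarray(mask.geometry.spacing) + np.asarray(mask.geometry.origin)
    return PointCloud(points)


def write_xyz(cloud: PointCloud, path) -> None:
    """Write a point cloud as whitespace-delimited XYZ text (mm)."""
    np.savetxt(path, cloud.points, fmt="%.6f")


def read_xyz(path) -> PointCloud:
    return PointCloud(np.loadtxt(path, ndmin=2))
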