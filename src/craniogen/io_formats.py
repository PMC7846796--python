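"""Reading and writing the dataset's file formats: NRRD volumes, STL meshes
and PNG previews.

The reader is permissive (raw or gzip NRRD encoding, ASCII or binary STL);
the writer is canonical: gzip-compressed NRRD with binary masks stored as
unsigned 8-bit and HU volumes as signed 16-bit (float data as 32-bit float),
and binary STL.  Both writers are byte-deterministic for fixed input, which
the packaging stage relies on for checksum-reproducible releases.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np
import SimpleITK as sitk
import trimesh
from PIL import Image

from .errors import ContractError, DimensionalityError, FormatError
from .geometry import CtVolume, SkullMask, VolumeGeometry
from .mesh_types import SurfaceMesh

__all__ = [
    "read_nrrd",
    "write_nrrd",
    "read_stl",
    "write_stl",
    "write_preview_png",
]

Volume = Union[CtVolume, SkullMask]

_IDENTITY = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


def read_nrrd(path: str | os.PathLike, as_mask: bool = False) -> Volume:
    """Read a 3D NRRD volume.

    Parameters
    ----------
    path : path-like
        NRRD file (raw or gzip encoding; attached header).
    as_mask : bool
        Interpret the volume as a binary :class:`SkullMask`.  Requires the
        voxel values to be exactly {0, 1}.

    Returns
    -------
    CtVolume or SkullMask

    Raises
    ------
    FormatError
        Malformed file, or an orientation with off-diagonal terms (only
        axis-aligned volumes are supported).
    DimensionalityError
        The file does not hold 3D data.
    """
    try:
        img = sitk.ReadImage(os.fspath(path))
    except RuntimeError as exc:  # ITK signals parse errors as RuntimeError
        raise FormatError(f"cannot read NRRD {path!s}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path!s}: expected 3D data, got {img.GetDimension()}D"
        )
    direction = img.GetDirection()
    off_diag = [direction[i] for i in (1, 2, 3, 5, 6, 7)]
    if any(abs(v) > 1e-9 for v in off_diag):
        raise FormatError(
            f"{path!s}: non-axis-aligned orientation {direction} is not supported"
        )
    # sitk arrays come back (z, y, x); transpose to this package's (x, y, z).
    array = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    geometry = VolumeGeometry(array.shape, img.GetSpacing(), img.GetOrigin())
    if as_mask:
        return SkullMask(geometry, array)
    return CtVolume(geometry, array)


def write_nrrd(volume: Volume, path: str | os.PathLike, compressed: bool = True) -> None:
    """Write a volume as NRRD.

    Masks are stored as unsigned 8-bit; integer HU volumes as signed 16-bit;
    floating-point HU volumes as 32-bit float.  Spacing and origin are
    encoded in the header.  Output bytes are deterministic for fixed input.
    """
    if isinstance(volume, SkullMask):
        array = volume.labels.astype(np.uint8)
    elif isinstance(volume, CtVolume):
        if np.issubdtype(volume.values.dtype, np.floating):
            array = volume.values.astype(np.float32)
        else:
            array = volume.values.astype(np.int16)
    else:
        raise ContractError(f"cannot write object of type {type(volume).__name__}")
    img = sitk.GetImageFromArray(array.transpose(2, 1, 0))
    img.SetSpacing(tuple(volume.geometry.spacing))
    img.SetOrigin(tuple(volume.geometry.origin))
    try:
        sitk.WriteImage(img, os.fspath(path), compressed)
    except RuntimeError as exc:
        raise OSError(f"cannot write NRRD {path!s}: {exc}") from exc


def write_stl(mesh: SurfaceMesh, path: str | os.PathLike) -> None:
    """Write a triangle mesh as binary STL (vertices stored single-precision)."""
    if len(mesh.triangles) < 1:
        raise ContractError("cannot write a mesh with no triangles")
    if not np.isfinite(mesh.vertices).all():
        raise ContractError("mesh has non-finite vertex coordinates")
    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    data = tm.export(file_type="stl")
    with open(path, "wb") as fh:
        fh.write(data)


def read_stl(path: str | os.PathLike) -> SurfaceMesh:
    """Read an STL mesh (binary or ASCII).

    STL stores an unindexed triangle soup, so exactly coincident vertices
    are welded back into a shared-vertex mesh on read.  Round-tripping a
    mesh through :func:`write_stl` preserves the triangle count and vertex
    coordinates to single precision (vertex order is not preserved).
    """
    try:
        tm = trimesh.load(os.fspath(path), file_type="stl", process=False)
    except Exception as exc:
        raise FormatError(f"cannot read STL {path!s}: {exc}") from exc
    verts = np.asarray(tm.vertices, float)
    faces = np.asarray(tm.faces, int)
    if faces.size == 0:
        raise FormatError(f"{path!s}: STL contains no triangles")
    unique, inverse = np.unique(verts, axis=0, return_inverse=True)
    return SurfaceMesh(unique, inverse[faces])


def write_preview_png(mask: SkullMask, path: str | os.PathLike) -> None:
    """Save a 2D preview of a mask as PNG.

    The preview is a lateral (sagittal-direction) maximum-intensity
    projection along y with the superior (+z) direction up, rendered as an
    8-bit grayscale depth-shaded image.  Byte-deterministic for fixed input.
    """
    if mask.is_empty:
        raise ContractError("cannot render a preview of an empty mask")
    bone = mask.as_bool()
    # Depth shading: nearer-to-viewer (low y) bone renders brighter.
    ny = mask.geometry.dims[1]
    depth = np.where(bone, np.arange(ny)[None, :, None], ny)
    nearest = depth.min(axis=1)  # (nx, nz)
    img = np.where(nearest < ny, 255 - (nearest * 128) // max(ny, 1), 0)
    # rows = z (flipped so +z is up), columns = x
    img2d = img.astype(np.uint8).T[::-1]
    Image.fromarray(img2d, mode="L").save(os.fspath(path), format="PNG")
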