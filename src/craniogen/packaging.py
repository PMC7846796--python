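"""Assemble a generated dataset into the published release layout.

Each case gets a folder ``CaseNN/`` holding the complete (healthy) skull
as same-stem NRRD + STL + PNG, and three zip archives alongside: one for
the healthy data and one each for the injected defects and the matching
implants (``CaseNN Defects.zip`` / ``CaseNN Implants.zip``; a
``safe_names`` switch substitutes underscores for the spaces).  Archives
are written with fixed timestamps and sorted members so re-running a
packaging step produces byte-identical trees.
"""

from __future__ import annotations

import os
import zipfile
from dataclasses import dataclass
from pathlib import Path

from . import io_formats, mesh_ops
from .defects import DefectDataset
from .errors import PackagingError
from .geometry import SkullMask

__all__ = ["ReleaseLayout", "package_release", "validate_release"]

_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)


@dataclass
class ReleaseLayout:
    """Index of a packaged release tree."""

    root: Path
    case_ids: list[str]

    def archives_for(self, case_id: str) -> list[Path]:
        return sorted(self.root.glob(f"{case_id} *.zip")) + sorted(
            self.root.glob(f"{case_id}_*.zip")
        )


def _archive_name(case_id: str, kind: str, safe_names: bool) -> str:
    sep = "_" if safe_names else " "
    return f"{case_id}{sep}{kind}.zip"


def _write_zip(path: Path, members: list[tuple[str, bytes]]) -> None:
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, data in sorted(members):
            info = zipfile.ZipInfo(name, date_time=_ZIP_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)


def _mask_bytes(mask: SkullMask, tmp: Path, stem: str) -> bytes:
    path = tmp / f"{stem}.nrrd"
    io_formats.write_nrrd(mask, path)
    data = path.read_bytes()
    path.unlink()
    return data


def package_release(
    dataset: DefectDataset,
    root: str | os.PathLike,
    safe_names: bool = False,
    with_mesh: bool = True,
    with_preview: bool = True,
) -> ReleaseLayout:
    """Write the release tree for a generated dataset.

    Raises
    ------
    PackagingError
        If any case is missing its complete skull or any pair member,
        naming the case and defect index.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    case_ids = []
    for case in dataset.cases:
        cid = case.case_id
        if case.complete is None or case.complete.is_empty:
            raise PackagingError(f"{cid}: missing or empty complete skull")
        if not case.pairs:
            raise PackagingError(f"{cid}: no defect pairs to package")
        for k, pair in enumerate(case.pairs, start=1):
            for part in ("defective", "implant"):
                member = getattr(pair, part, None)
                if member is None or member.is_empty:
                    raise PackagingError(f"{cid}: defect {k} has no usable {part}")

        folder = root / cid
        folder.mkdir(exist_ok=True)
        io_formats.write_nrrd(case.complete, folder / f"{cid}.nrrd")
        if with_mesh:
            mesh = mesh_ops.binary_to_mesh(case.complete)
            io_formats.write_stl(mesh, folder / f"{cid}.stl")
        if with_preview:
            io_formats.write_preview_png(case.complete, folder / f"{cid}.png")

        healthy = [
            (p.name, p.read_bytes()) for p in sorted(folder.iterdir()) if p.is_file()
        ]
        _write_zip(root / _archive_name(cid, "Healthy", safe_names), healthy)
        defects = [
            (f"{cid}_defect_{k}.nrrd", _mask_bytes(pair.defective, root, "_tmp"))
            for k, pair in enumerate(case.pairs, start=1)
        ]
        _write_zip(root / _archive_name(cid, "Defects", safe_names), defects)
        implants = [
            (f"{cid}_implant_{k}.nrrd", _mask_bytes(pair.implant, root, "_tmp"))
            for k, pair in enumerate(case.pairs, start=1)
        ]
        _write_zip(root / _archive_name(cid, "Implants", safe_names), implants)
        case_ids.append(cid)
    return ReleaseLayout(root=root, case_ids=case_ids)


def validate_release(root: str | os.PathLike) -> ReleaseLayout:
    """Check the release-layout invariants of a packaged tree.

    Every case folder must come with exactly three archives, and the
    defect and implant archives must contain equal file counts with
    matching indices.
    """
    root = Path(root)
    case_ids = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not case_ids:
        raise PackagingError(f"{root}: no case folders found")
    layout = ReleaseLayout(root=root, case_ids=case_ids)
    for cid in case_ids:
        archives = layout.archives_for(cid)
        if len(archives) != 3:
            raise PackagingError(
                f"{cid}: expected 3 archives, found {[a.name for a in archives]}"
            )
        indices = {}
        for kind in ("Defects", "Implants"):
            matches = [a for a in archives if kind in a.name]
            if len(matches) != 1:
                raise PackagingError(f"{cid}: missing {kind} archive")
            with zipfile.ZipFile(matches[0]) as zf:
                names = sorted(zf.namelist())
            indices[kind] = [n.rsplit("_", 1)[-1].removesuffix(".nrrd") for n in names]
        if indices["Defects"] != indices["Implants"]:
            raise PackagingError(
                f"{cid}: defect/implant archive indices differ: "
                f"{indices['Defects']} vs {indices['Implants']}"
            )
    return layout
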