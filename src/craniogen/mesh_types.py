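"""Surface-mesh and point-cloud containers (physical mm coordinates)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import ContractError

__all__ = ["SurfaceMesh", "PointCloud"]


@dataclass
class SurfaceMesh:
    """An indexed triangle mesh.

    vertices : (N, 3) float array, physical mm coordinates.
    triangles : (M, 3) int array of vertex indices.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles) < 1:
            raise ContractError("a SurfaceMesh needs at least one triangle")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise ContractError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def surface_area(self) -> float:
        return float(self.triangle_areas().sum())

    def open_edges(self) -> np.ndarray:
        """Edges not shared by exactly two triangles; empty iff watertight."""
        edges = np.sort(
            self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        return uniq[counts != 2]

    @property
    def is_watertight(self) -> bool:
        return len(self.open_edges()) == 0

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def connected_component_count(self) -> int:
        return len(self.to_trimesh().split(only_watertight=False))


@dataclass
class PointCloud:
    """An unordered set of 3D points in physical mm coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)
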