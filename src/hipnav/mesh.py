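"""Triangulated bone surfaces and exact point-to-surface queries.

``SurfaceMesh`` is a thin validated container over vertex/face arrays with
STL/PLY IO (via trimesh) and a closest-point query returning the exact
nearest point on any triangle (interior, edge, or vertex), accelerated by an
AABB tree with branch-and-bound traversal (see ``hipnav._bvh``). The tree
prunes boxes that cannot beat the current best distance, so the query is
exact, not approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._bvh import build_aabb_tree, query_aabb_tree
from .rigid import RigidTransform

_DEGENERATE_AREA = 1e-10  # mm^2


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface with vertices in mm. Watertightness not required."""

    vertices: np.ndarray
    faces: np.ndarray
    _tree: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        v = np.ascontiguousarray(self.vertices, dtype=float)
        f = np.ascontiguousarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 3:
            raise ValueError(f"vertices must be (N>=3, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices contain non-finite coordinates")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) < 1:
            raise ValueError(f"faces must be (M>=1, 3), got {f.shape}")
        if f.min() < 0 or f.max() >= len(v):
            raise ValueError("face indices out of vertex range")
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        areas = 0.5 * np.linalg.norm(cross, axis=1)
        if np.any(areas <= _DEGENERATE_AREA):
            raise ValueError(
                f"{int(np.sum(areas <= _DEGENERATE_AREA))} degenerate "
                "(near-zero-area) faces"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- geometry ----------------------------------------------------------

    def nearest(self, points):
        """Closest surface points for an (N, 3) array of queries (mm).

        Returns ``(closest_points (N,3), distances (N,), face_ids (N,))``.
        """
        if not self._tree:
            self._tree.append(build_aabb_tree(self.vertices, self.faces))
        pts = np.ascontiguousarray(np.atleast_2d(np.asarray(points, float)))
        return query_aabb_tree(pts, self.vertices, self.faces, *self._tree[0])

    def face_areas(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def transformed(self, t: RigidTransform) -> "SurfaceMesh":
        return SurfaceMesh(t.apply(self.vertices), self.faces.copy())

    def mirrored_x(self) -> "SurfaceMesh":
        """Mirror across the sagittal (x = 0) plane, keeping outward winding."""
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        return SurfaceMesh(v, self.faces[:, [0, 2, 1]].copy())

    # -- IO ----------------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))

    def save(self, path) -> None:
        """Write STL or PLY (by extension)."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        if tm.is_empty:
            raise ValueError(f"empty mesh in {path}")
        return cls.from_trimesh(tm)


def nearest_surface_point(mesh: SurfaceMesh, p):
    """Closest point on the mesh to a single query ``p`` and its distance (mm)."""
    cp, d, _ = mesh.nearest(np.asarray(p, float)[None, :])
    return cp[0], float(d[0])
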