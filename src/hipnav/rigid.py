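"""Rigid-body transforms and least-squares superposition.

All lengths are millimetres and all angles degrees at the API boundary;
rotations are stored as proper orthonormal 3x3 matrices. This module is the
currency of every alignment step in the pipeline: intra-operative patient
alignment, post-op-to-pre-op registration, and cup-pose transfer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-9


def _as_vec3(x, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {np.asarray(x).shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` of 3D space.

    Parameters
    ----------
    rotation : (3, 3) array
        Orthonormal with determinant +1 (checked to 1e-9).
    translation : (3,) array
        Offset in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = _as_vec3(self.translation, "translation")
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)):
            raise ValueError("rotation contains non-finite values")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from an axis-angle vector whose norm is the angle in degrees."""
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(R.as_matrix(), np.asarray(translation, dtype=float))

    def apply(self, points) -> np.ndarray:
        """Apply to a single 3-vector or an (N, 3) array of points (mm)."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def apply_vector(self, v) -> np.ndarray:
        """Rotate a direction vector (no translation)."""
        return self.rotation @ np.asarray(v, dtype=float)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other``: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation magnitude in [0, 180] degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"], float), np.asarray(d["translation"], float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """``compose(a, b)(x) == a(b(x))``."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def rotation_angle_deg(t: RigidTransform) -> float:
    return t.rotation_angle_deg()


@dataclass(frozen=True)
class PointSet:
    """Ordered 3D points (mm) with optional per-point region labels."""

    points: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
            raise ValueError(f"points must be (N>=1, 3), got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("points contain non-finite coordinates")
        object.__setattr__(self, "points", p)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != len(p):
                raise ValueError("labels length must match points")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, t: RigidTransform) -> "PointSet":
        return PointSet(t.apply(self.points), self.labels)


def kabsch_align(src, dst) -> RigidTransform:
    """Least-squares rigid superposition (Kabsch/Umeyama, no scaling).

    Returns the proper rigid transform ``T`` minimizing
    ``sum_i || T(src_i) - dst_i ||^2``. Reflections are rejected by flipping
    the sign of the smallest singular vector when the determinant of the
    covariance solution is negative (bone surfaces must never be mirrored).

    Raises
    ------
    ValueError
        If point counts differ, fewer than 3 pairs are given, or the source
        cloud is degenerate (collinear / coincident points: covariance rank
        below 2).
    """
    s = src.points if isinstance(src, PointSet) else np.asarray(src, dtype=float)
    d = dst.points if isinstance(dst, PointSet) else np.asarray(dst, dtype=float)
    if s.shape != d.shape:
        raise ValueError(f"source and destination differ in shape: {s.shape} vs {d.shape}")
    if s.ndim != 2 or s.shape[1] != 3 or len(s) < 3:
        raise ValueError("need at least 3 correspondences of 3-vectors")
    sc = s.mean(axis=0)
    dc = d.mean(axis=0)
    H = (s - sc).T @ (d - dc)
    U, sig, Vt = np.linalg.svd(H)
    scale = max(sig[0], np.linalg.norm(s - sc) * np.linalg.norm(d - dc), 1.0)
    if sig[1] <= 1e-12 * scale:
        raise ValueError(
            "degenerate correspondences: covariance rank < 2 "
            "(points collinear or coincident); rotation is not determined"
        )
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, dc - R @ sc)


def random_rigid_transform(
    rng: np.random.Generator,
    max_rotation_deg: float = 180.0,
    max_translation_mm: float = 100.0,
) -> RigidTransform:
    """Seeded random rigid motion: uniform axis, uniform angle in
    [0, max_rotation_deg], translation uniform in the ball of the given radius."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_rotation_deg)
    # uniform in ball: direction * radius with r ~ U^(1/3)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    radius = max_translation_mm * rng.uniform() ** (1.0 / 3.0)
    return RigidTransform.from_rotvec_deg(axis * angle, tdir * radius)
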