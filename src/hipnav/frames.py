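"""Pelvic reference frames from anatomical landmarks.

The anterior pelvic plane (APP) is the plane through both anterior superior
iliac spines (ASIS) and the pubic-landmark midpoint (~symphysis); it is the
standard pelvic reference for cup angles. The functional pelvic plane (FPP)
is the APP rotated about the inter-ASIS axis by the patient's pelvic tilt.

Frame convention (right-handed, unit axes):

* ``lateral_axis``   — along right ASIS -> left ASIS,
* ``anterior_axis``  — APP normal, pointing anteriorly,
* ``superior_axis``  — in-plane, pointing cranially,
* origin at the ASIS midpoint.

Cup angles for right hips are handled by mirroring the lateral component of
the cup axis at angle-computation time (``side="right"``), so a single frame
convention serves both sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .rigid import RigidTransform, _as_vec3

APP = "APP"
FPP = "FPP"


@dataclass(frozen=True)
class PelvicLandmarks:
    """ASIS and pubic landmark coordinates in mm (CT/model frame)."""

    asis_left: np.ndarray
    asis_right: np.ndarray
    pubic_left: np.ndarray
    pubic_right: np.ndarray

    def __post_init__(self):
        for name in ("asis_left", "asis_right", "pubic_left", "pubic_right"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name), name))
        if np.allclose(self.asis_left, self.asis_right):
            raise ValueError("left and right ASIS coincide")

    def transformed(self, t: RigidTransform) -> "PelvicLandmarks":
        return PelvicLandmarks(*(t.apply(getattr(self, n)) for n in
                                 ("asis_left", "asis_right", "pubic_left", "pubic_right")))

    def swapped_asis(self) -> "PelvicLandmarks":
        return replace(self, asis_left=self.asis_right, asis_right=self.asis_left)

    # -- IO ----------------------------------------------------------------

    _NAMES = ("asis_left", "asis_right", "pubic_left", "pubic_right")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"name": n, "x": v[0], "y": v[1], "z": v[2]}
                for n, v in ((n, getattr(self, n)) for n in self._NAMES)]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PelvicLandmarks":
        df = pd.read_csv(path).set_index("name")
        try:
            coords = {n: df.loc[n, ["x", "y", "z"]].to_numpy(float) for n in cls._NAMES}
        except KeyError as exc:
            raise ValueError(f"landmark file {path} is missing landmark {exc}") from exc
        return cls(**coords)

    @classmethod
    def from_json(cls, path) -> "PelvicLandmarks":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{n: np.asarray(d[n], float) for n in cls._NAMES})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({n: getattr(self, n).tolist() for n in self._NAMES}, fh, indent=2)


@dataclass(frozen=True)
class PelvicFrame:
    """Orthonormal anatomical frame (axes in world/CT coordinates, mm origin)."""

    origin: np.ndarray
    lateral_axis: np.ndarray
    anterior_axis: np.ndarray
    superior_axis: np.ndarray
    kind: str = APP
    tilt_deg: float = 0.0

    def __post_init__(self):
        for name in ("origin", "lateral_axis", "anterior_axis", "superior_axis"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name), name))
        A = self.axes
        if np.abs(A @ A.T - np.eye(3)).max() > 1e-9:
            raise ValueError("frame axes are not orthonormal")
        if self.kind not in (APP, FPP):
            raise ValueError(f"kind must be {APP!r} or {FPP!r}")

    @property
    def axes(self) -> np.ndarray:
        """Rows: lateral, anterior, superior."""
        return np.vstack([self.lateral_axis, self.anterior_axis, self.superior_axis])

    def is_right_handed(self) -> bool:
        return bool(np.dot(np.cross(self.lateral_axis, self.anterior_axis),
                           self.superior_axis) > 0)

    def axis_components(self, v) -> np.ndarray:
        """(lateral, anterior, superior) components of a world vector."""
        return self.axes @ np.asarray(v, dtype=float)

    def vector_from_components(self, las) -> np.ndarray:
        return self.axes.T @ np.asarray(las, dtype=float)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "lateral_axis": self.lateral_axis.tolist(),
            "anterior_axis": self.anterior_axis.tolist(),
            "superior_axis": self.superior_axis.tolist(),
            "kind": self.kind,
            "tilt_deg": self.tilt_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PelvicFrame":
        return cls(
            np.asarray(d["origin"], float),
            np.asarray(d["lateral_axis"], float),
            np.asarray(d["anterior_axis"], float),
            np.asarray(d["superior_axis"], float),
            d.get("kind", APP),
            float(d.get("tilt_deg", 0.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PelvicFrame":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate landmark geometry: {what} has zero length")
    return v / n


def build_app_frame(landmarks: PelvicLandmarks) -> PelvicFrame:
    """Construct the APP frame from ASIS and pubic landmarks.

    The lateral axis runs right ASIS -> left ASIS. The anterior axis is the
    normal of the plane through both ASIS and the pubic midpoint, with its
    sign fixed anteriorly by the pubic left/right ordering (so it does not
    flip if the ASIS labels are swapped). The superior axis completes the
    triad by Gram-Schmidt on the (pubic midpoint -> ASIS midpoint) direction.

    Raises ``ValueError`` for collinear landmark configurations.
    """
    al, ar = landmarks.asis_left, landmarks.asis_right
    pm = 0.5 * (landmarks.pubic_left + landmarks.pubic_right)
    am = 0.5 * (al + ar)

    lateral = _unit(al - ar, "inter-ASIS axis")
    normal = np.cross(al - pm, ar - pm)
    if np.linalg.norm(normal) < 1e-9 * max(np.linalg.norm(al - pm), 1.0):
        raise ValueError("landmarks are collinear: APP is not defined")
    normal = _unit(normal, "APP normal")
    # anterior sign reference built only from label-symmetric midpoints and the
    # pubic left/right order, so swapping ASIS labels leaves anterior unchanged
    reference = np.cross(landmarks.pubic_right - landmarks.pubic_left, am - pm)
    sign = np.dot(normal, reference)
    if abs(sign) < 1e-12:
        raise ValueError("cannot orient APP normal: pubic landmarks degenerate")
    anterior = normal * np.sign(sign)

    v = am - pm
    sup = v - np.dot(v, lateral) * lateral - np.dot(v, anterior) * anterior
    superior = _unit(sup, "superior axis")
    return PelvicFrame(am, lateral, anterior, superior, kind=APP, tilt_deg=0.0)


def apply_pelvic_tilt(frame: PelvicFrame, tilt_deg: float) -> PelvicFrame:
    """Rotate an APP frame about its lateral axis into the functional plane.

    Positive tilt is anterior tilt: the superior axis leans forward (toward
    anterior). Requires ``frame.kind == "APP"`` and ``|tilt| <= 90`` degrees.
    """
    if frame.kind != APP:
        raise ValueError("pelvic tilt is applied to an APP frame")
    if abs(tilt_deg) > 90.0:
        raise ValueError(f"non-physiological pelvic tilt {tilt_deg} deg (|tilt| > 90)")
    # superior' = cos*superior + sin*anterior requires rotating about lateral
    # by -tilt in the right-hand sense (lateral x superior = -anterior).
    rot = Rotation.from_rotvec(frame.lateral_axis * np.radians(-tilt_deg)).as_matrix()
    return PelvicFrame(
        frame.origin,
        frame.lateral_axis,
        rot @ frame.anterior_axis,
        rot @ frame.superior_axis,
        kind=FPP,
        tilt_deg=float(tilt_deg),
    )
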