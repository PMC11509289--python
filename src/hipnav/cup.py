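"""Acetabular cup orientation and depth metrics.

Cup orientation is described by the unit *opening axis* of the cup (pointing
out of the acetabulum, laterally). With ``(l, a, s)`` the components of that
axis on the pelvic frame's (lateral, anterior, superior) axes, the three
classical angle conventions (Murray) read

* operative:     inclination ``OI = asin(l)``,      anteversion ``OA = atan2(a, s)``
* radiographic:  inclination ``RI = atan2(l, s)``,  anteversion ``RA = asin(a)``
* anatomic:      inclination ``AI = acos(s)``,      anteversion ``AA = atan2(a, l)``

These satisfy the closed-form identities ``tan(RI) = tan(OI)/cos(OA)`` and
``sin(RA) = sin(OA) * cos(OI)``. The guide tool displays the operative pair,
so operative is the primary readout here; the other conventions are provided
as tested conversions.

The signed depth difference between two cup poses is the displacement of the
cup centre projected on the cup opening axis: positive when the first cup
sits lateral (shallower) to the second, negative when medial (deeper) — in
contrast to an always-positive 3D distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .frames import PelvicFrame
from .rigid import _as_vec3

OPERATIVE = "operative"
RADIOGRAPHIC = "radiographic"
ANATOMIC = "anatomic"
_DEFINITIONS = (OPERATIVE, RADIOGRAPHIC, ANATOMIC)

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class CupPose:
    """Cup centre of rotation (mm) and unit opening axis in a named frame."""

    center: np.ndarray
    axis: np.ndarray
    frame_id: str = "preop"

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))
        ax = _as_vec3(self.axis, "axis")
        n = np.linalg.norm(ax)
        if n < 1e-9:
            raise ValueError("cup axis has zero length")
        object.__setattr__(self, "axis", ax / n)

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "axis": self.axis.tolist(),
                "frame_id": self.frame_id}

    @classmethod
    def from_dict(cls, d: dict) -> "CupPose":
        return cls(np.asarray(d["center"], float), np.asarray(d["axis"], float),
                   d.get("frame_id", "preop"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CupPose":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CupAngles:
    """Anteversion/inclination pair in degrees under a named convention."""

    anteversion: float
    inclination: float
    definition: str = OPERATIVE

    def __post_init__(self):
        if self.definition not in _DEFINITIONS:
            raise ValueError(f"unknown angle definition {self.definition!r}")
        if not (-90.0 < self.anteversion < 90.0):
            raise ValueError(f"anteversion {self.anteversion} outside (-90, 90) deg")
        if not (0.0 <= self.inclination <= 90.0):
            raise ValueError(f"inclination {self.inclination} outside [0, 90] deg")


def _side_sign(side: str) -> float:
    if side == LEFT:
        return 1.0
    if side == RIGHT:
        return -1.0
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def _las_components(pose: CupPose, frame: PelvicFrame, side: str) -> np.ndarray:
    las = frame.axis_components(pose.axis)
    las[0] *= _side_sign(side)  # mirror lateral component for right hips
    return las


def operative_angles(pose: CupPose, frame: PelvicFrame, side: str = LEFT) -> CupAngles:
    """Operative anteversion/inclination of a cup pose in a pelvic frame.

    The cup axis must point laterally (out of the acetabulum) on the operated
    ``side``; a medially pointing axis raises ``ValueError``.
    """
    l, a, s = _las_components(pose, frame, side)
    if l < 0:
        raise ValueError(
            "cup axis points medially after side normalization "
            f"(lateral component {l:.4f} <= 0); check the axis orientation or side"
        )
    inclination = np.degrees(np.arcsin(np.clip(l, -1.0, 1.0)))
    anteversion = np.degrees(np.arctan2(a, s))
    return CupAngles(float(anteversion), float(inclination), OPERATIVE)


def _axis_components_from_angles(angles: CupAngles) -> np.ndarray:
    """Unit (l, a, s) axis components for any angle convention."""
    av = np.radians(angles.anteversion)
    inc = np.radians(angles.inclination)
    if angles.definition == OPERATIVE:
        l = np.sin(inc)
        a = np.cos(inc) * np.sin(av)
        s = np.cos(inc) * np.cos(av)
    elif angles.definition == RADIOGRAPHIC:
        a = np.sin(av)
        l = np.cos(av) * np.sin(inc)
        s = np.cos(av) * np.cos(inc)
    else:  # anatomic
        s = np.cos(inc)
        l = np.sin(inc) * np.cos(av)
        a = np.sin(inc) * np.sin(av)
    return np.array([l, a, s])


def _angles_from_axis_components(las: np.ndarray, definition: str) -> CupAngles:
    l, a, s = np.clip(las, -1.0, 1.0)
    if definition == OPERATIVE:
        inc = np.arcsin(l)
        av = np.arctan2(a, s)
    elif definition == RADIOGRAPHIC:
        av = np.arcsin(a)
        inc = np.arctan2(l, s)
    elif definition == ANATOMIC:
        inc = np.arccos(s)
        av = np.arctan2(a, l)
    else:
        raise ValueError(f"unknown angle definition {definition!r}")
    return CupAngles(float(np.degrees(av)), float(np.degrees(inc)), definition)


def axis_from_operative_angles(angles: CupAngles, frame: PelvicFrame,
                               side: str = LEFT) -> np.ndarray:
    """World-frame unit cup axis realizing the given operative angles.

    Inverse of :func:`operative_angles`; requires ``definition="operative"``
    and inclination strictly inside (0, 90) degrees so that the axis has a
    positive lateral component.
    """
    if angles.definition != OPERATIVE:
        raise ValueError("axis_from_operative_angles requires operative angles")
    if not (0.0 < angles.inclination < 90.0):
        raise ValueError("inclination must lie strictly in (0, 90) deg")
    las = _axis_components_from_angles(angles)
    las[0] *= _side_sign(side)
    return frame.vector_from_components(las)


def convert_definitions(angles: CupAngles, to: str) -> CupAngles:
    """Convert cup angles between operative/radiographic/anatomic conventions.

    Conversion goes through the unit axis components, which is equivalent to
    the Murray closed-form identities (e.g. ``tan RI = tan OI / cos OA``).
    Undefined at inclination 90 deg (the axis lies in the transverse plane and
    the anteversion of other conventions degenerates), which raises.
    """
    if to not in _DEFINITIONS:
        raise ValueError(f"unknown angle definition {to!r}")
    if angles.inclination >= 90.0 - 1e-12:
        raise ValueError("angle-convention conversion undefined at inclination 90 deg")
    return _angles_from_axis_components(_axis_components_from_angles(angles), to)


def signed_depth_difference(guide: CupPose, reference: CupPose) -> float:
    """Signed cup depth difference in mm along the *guide* cup axis.

    ``(guide.center - reference.center) . guide.axis``: positive when the
    guide cup sits lateral (shallower) to the reference, negative when medial
    (deeper). Both poses must be expressed in the same frame.
    """
    if guide.frame_id != reference.frame_id:
        raise ValueError(
            f"poses in different frames: {guide.frame_id!r} vs {reference.frame_id!r}"
        )
    return float(np.dot(guide.center - reference.center, guide.axis))
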