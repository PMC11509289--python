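"""Seeded synthetic study scenes with known ground truth.

Generates everything one cadaver side / patient contributes to the study: a
parametric hemipelvis surface with landmarks, a ground-truth implanted cup,
per-rater noisy 26-point surface samples expressed in rater-specific tracker
frames, and a rigidly displaced, noise-perturbed "post-op" copy of the scene.

The pelvis is a stylized stand-in for a CT-segmented bone: a smoothly
deformed ellipsoidal iliac blade carved with an exactly spherical acetabular
cavity (so the acetabular-centre oracle is exact), with ASIS/pubic landmarks
at parametrically defined sites. It reproduces the *structure* the analysis
relies on — a rigid, featureful surface with named probing regions — not the
anatomy of any real pelvis.

Every stage records its ground truth, and everything is deterministic given
``SceneConfig.seed`` (per-stage streams are spawned from one SeedSequence).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import trimesh
import yaml
from scipy.spatial.transform import Rotation

from .cup import (CupAngles, CupPose, LEFT, OPERATIVE, RIGHT,
                  axis_from_operative_angles, operative_angles)
from .frames import PelvicFrame, PelvicLandmarks, apply_pelvic_tilt, build_app_frame
from .mesh import SurfaceMesh
from .rigid import PointSet, RigidTransform, random_rigid_transform

# canonical landmark sites (mm) in the APP frame of a LEFT-side scene:
# x lateral (to patient's left), y anterior, z superior, origin ASIS midpoint
_ASIS_OP = np.array([120.0, 0.0, 0.0])
_ASIS_CONTRA = np.array([-120.0, 0.0, 0.0])
_PUBIC_OP = np.array([25.0, 0.0, -95.0])
_PUBIC_CONTRA = np.array([-25.0, 0.0, -95.0])

# iliac-blade ellipsoid: centre and semi-axes (lateral, anterior, superior)
_BLADE_CENTER = np.array([75.0, -15.0, -30.0])
_BLADE_SEMI = np.array([28.0, 52.0, 70.0])
# acetabular cavity direction (from blade centre), radially outward
_CAVITY_DIR = np.array([0.45, 0.05, -0.89]) / np.linalg.norm([0.45, 0.05, -0.89])

REGIONS = ("iliac_crest", "anterior_wall", "posterior_wall", "acetabular_rim")
_DEFAULT_REGION_COUNTS = {"iliac_crest": 8, "anterior_wall": 6,
                          "posterior_wall": 6, "acetabular_rim": 6}


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one simulated surgery.

    Defaults encode the study design: 26 probed points, 3 raters, Lewinnek
    cup target (operative 15 deg anteversion / 40 deg inclination), 0.5 mm
    probing noise, 0.3 mm post-op surface noise (giving ~0.25 mm expected
    pre/post-op surface agreement), and no manual-overlay noise.
    """

    seed: int = 0
    side: str = LEFT
    mesh_subdivisions: int = 3
    acetabular_radius_mm: float = 24.0
    shape_variation: float = 0.05
    cup_anteversion_deg: float = 15.0
    cup_inclination_deg: float = 40.0
    cup_depth_mm: float = 0.0
    point_noise_sigma: float = 0.5
    n_points: int = 26
    region_counts: Mapping[str, int] | None = None
    n_raters: int = 3
    rater_rot_deg: float = 45.0
    rater_trans_mm: float = 100.0
    postop_rot_deg: float = 10.0
    postop_trans_mm: float = 20.0
    postop_vertex_noise_sigma: float = 0.3
    overlay_rot_sigma_deg: float = 0.0
    overlay_trans_sigma_mm: float = 0.0
    pelvic_tilt_deg: float = 0.0

    def __post_init__(self):
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in ("point_noise_sigma", "postop_vertex_noise_sigma",
                     "overlay_rot_sigma_deg", "overlay_trans_sigma_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_points < 6:
            raise ValueError("n_points must be >= 6")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")
        if self.mesh_subdivisions < 2:
            raise ValueError("mesh_subdivisions < 2 is too coarse for region sampling")
        counts = dict(self.region_counts) if self.region_counts else \
            _scale_region_counts(self.n_points)
        if sum(counts.values()) != self.n_points:
            raise ValueError("region_counts must sum to n_points")
        object.__setattr__(self, "region_counts", counts)

    def cup_target(self) -> CupAngles:
        return CupAngles(self.cup_anteversion_deg, self.cup_inclination_deg,
                         OPERATIVE)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["region_counts"] = dict(self.region_counts)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _scale_region_counts(n_points: int) -> dict:
    """Distribute n_points over the four probing regions, 26 -> (8,6,6,6)."""
    base = np.array([8, 6, 6, 6], float) * n_points / 26.0
    counts = np.floor(base).astype(int)
    # hand out the remainder by largest fractional part, deterministically
    order = np.argsort(-(base - counts), kind="stable")
    for i in range(n_points - counts.sum()):
        counts[order[i % 4]] += 1
    return {name: int(c) for name, c in zip(REGIONS, counts)}


@dataclass(frozen=True)
class PelvisModel:
    """Generated bone surface plus the constructed ground-truth anatomy."""

    mesh: SurfaceMesh
    landmarks: PelvicLandmarks
    acetabular_center: np.ndarray
    acetabular_radius: float
    regions: Mapping[str, np.ndarray]          # region name -> face indices
    cavity_vertex_mask: np.ndarray
    side: str

    def region_centroids(self) -> dict:
        """Area-weighted surface centroid of each probing region."""
        areas = self.mesh.face_areas()
        cents = self.mesh.face_centroids()
        out = {}
        for name, fidx in self.regions.items():
            w = areas[fidx]
            out[name] = (cents[fidx] * w[:, None]).sum(axis=0) / w.sum()
        return out


def generate_pelvis(config: SceneConfig) -> PelvisModel:
    """Deterministic-given-seed parametric hemipelvis with landmarks.

    The surface is built radially over icosphere directions from the blade
    centre: a seeded smooth deformation of an ellipsoid, then carved by a
    sphere of ``acetabular_radius_mm`` (exact ray-sphere intersection), so
    cavity vertices lie exactly on the acetabular sphere.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    ico = trimesh.creation.icosphere(subdivisions=config.mesh_subdivisions,
                                     radius=1.0)
    dirs = np.asarray(ico.vertices, float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, np.int64)

    # ellipsoid radius along each direction
    r_ell = 1.0 / np.sqrt(((dirs / _BLADE_SEMI) ** 2).sum(axis=1))
    # smooth seeded low-frequency deformation (bounded by shape_variation)
    bump = np.zeros(len(dirs))
    for _ in range(4):
        g = rng.normal(size=3)
        h = rng.normal(size=3)
        g /= np.linalg.norm(g)
        h /= np.linalg.norm(h)
        bump += rng.uniform(-1, 1) * (dirs @ g) * (dirs @ h)
    r_def = r_ell * (1.0 + config.shape_variation * bump / 4.0)

    # acetabular sphere centre: along the cavity direction, recessed half a
    # radius from the (deformed) surface so the sphere pokes out
    i_cav = int(np.argmax(dirs @ _CAVITY_DIR))
    surf_r = float(r_def[i_cav])
    r_cup = float(config.acetabular_radius_mm)
    center_dist = surf_r - 0.5 * r_cup
    cav_center_local = center_dist * _CAVITY_DIR

    # exact first ray-sphere intersection per direction (rays from origin)
    b = dirs @ cav_center_local
    disc = b**2 - (center_dist**2 - r_cup**2)
    hits = disc > 0
    t1 = np.where(hits, b - np.sqrt(np.clip(disc, 0, None)), np.inf)
    carved = hits & (t1 > 0) & (t1 < r_def)
    radius = np.where(carved, t1, r_def)

    vertices = _BLADE_CENTER + radius[:, None] * dirs
    cav_center = _BLADE_CENTER + cav_center_local

    landmarks = PelvicLandmarks(_ASIS_OP, _ASIS_CONTRA, _PUBIC_OP, _PUBIC_CONTRA)
    mesh = SurfaceMesh(vertices, faces)

    regions = _classify_regions(mesh, carved, cav_center, r_cup)
    for name, fidx in regions.items():
        if len(fidx) == 0:
            raise ValueError(
                f"mesh resolution too low: region {name!r} has no faces"
            )

    model = PelvisModel(mesh, landmarks, cav_center, r_cup, regions, carved, LEFT)
    if config.side == RIGHT:
        model = _mirror_model(model)
    return model


def _classify_regions(mesh: SurfaceMesh, cavity_mask: np.ndarray,
                      cav_center: np.ndarray, r_cup: float) -> dict:
    """Assign probing-region face indices by geometric predicates."""
    f = mesh.faces
    cents = mesh.face_centroids()
    n_cavity_verts = cavity_mask[f].sum(axis=1)
    face_cavity = n_cavity_verts == 3
    face_rim = (n_cavity_verts >= 1) & ~face_cavity
    crest = (cents[:, 2] > 10.0) & ~face_cavity & ~face_rim
    lower = ~face_cavity & ~face_rim & ~crest
    anterior = lower & (cents[:, 1] > 5.0)
    posterior = lower & (cents[:, 1] < -35.0)
    return {
        "iliac_crest": np.flatnonzero(crest),
        "anterior_wall": np.flatnonzero(anterior),
        "posterior_wall": np.flatnonzero(posterior),
        "acetabular_rim": np.flatnonzero(face_rim | face_cavity),
    }


def _mirror_model(model: PelvisModel) -> PelvisModel:
    def mx(v):
        out = np.asarray(v, float).copy()
        out[0] *= -1
        return out

    lm = model.landmarks
    mirrored_lm = PelvicLandmarks(
        asis_left=mx(lm.asis_right), asis_right=mx(lm.asis_left),
        pubic_left=mx(lm.pubic_right), pubic_right=mx(lm.pubic_left),
    )
    return PelvisModel(
        model.mesh.mirrored_x(), mirrored_lm, mx(model.acetabular_center),
        model.acetabular_radius, model.regions, model.cavity_vertex_mask, RIGHT,
    )


def pelvic_frame_for(model: PelvisModel, tilt_deg: float = 0.0) -> PelvicFrame:
    frame = build_app_frame(model.landmarks)
    if tilt_deg != 0.0:
        frame = apply_pelvic_tilt(frame, tilt_deg)
    return frame


def implant_cup(model: PelvisModel, frame: PelvicFrame, target: CupAngles,
                depth_mm: float = 0.0) -> CupPose:
    """Ground-truth cup pose: centre at the acetabular centre offset by
    ``depth_mm`` along the target axis; axis from the operative target."""
    axis = axis_from_operative_angles(target, frame, side=model.side)
    return CupPose(model.acetabular_center + depth_mm * axis, axis, "preop")


def sample_registration_points(model: PelvisModel,
                               region_counts: Mapping[str, int],
                               sigma_mm: float,
                               rng: np.random.Generator) -> PointSet:
    """Noisy surface samples from the named probing regions (model frame).

    Points are drawn area-weighted over each region's faces with uniform
    barycentric coordinates, then displaced by isotropic Gaussian noise of
    ``sigma_mm``. Labels record the region of each point.
    """
    areas = model.mesh.face_areas()
    v, f = model.mesh.vertices, model.mesh.faces
    pts, labels = [], []
    for name, count in region_counts.items():
        if count == 0:
            continue
        fidx = np.asarray(model.regions[name])
        if len(fidx) == 0 or areas[fidx].sum() <= 0:
            raise ValueError(f"region {name!r} has zero surface area")
        w = areas[fidx] / areas[fidx].sum()
        chosen = rng.choice(fidx, size=count, p=w)
        r1 = np.sqrt(rng.uniform(size=count))
        r2 = rng.uniform(size=count)
        a, bb, c = v[f[chosen, 0]], v[f[chosen, 1]], v[f[chosen, 2]]
        p = (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * bb \
            + (r1 * r2)[:, None] * c
        pts.append(p)
        labels.extend([name] * count)
    points = np.vstack(pts)
    if sigma_mm > 0:
        points = points + rng.normal(0.0, sigma_mm, points.shape)
    return PointSet(points, tuple(labels))


def simulate_postop(preop_mesh: SurfaceMesh, true_cup: CupPose,
                    config: SceneConfig, rng: np.random.Generator):
    """Post-op scene: pre-op mesh under a bounded random rigid displacement
    plus vertex noise; the cup carried by the same displacement plus optional
    manual-overlay noise. Returns ``(postop_mesh, postop_cup, displacement)``
    with the displacement (preop -> postop) as ground truth."""
    disp = random_rigid_transform(rng, config.postop_rot_deg,
                                  config.postop_trans_mm)
    verts = disp.apply(preop_mesh.vertices)
    if config.postop_vertex_noise_sigma > 0:
        verts = verts + rng.normal(0.0, config.postop_vertex_noise_sigma,
                                   verts.shape)
    postop_mesh = SurfaceMesh(verts, preop_mesh.faces.copy())

    center = disp.apply(true_cup.center)
    axis = disp.apply_vector(true_cup.axis)
    if config.overlay_rot_sigma_deg > 0:
        rotvec = np.radians(rng.normal(0.0, config.overlay_rot_sigma_deg, 3))
        axis = Rotation.from_rotvec(rotvec).as_matrix() @ axis
    if config.overlay_trans_sigma_mm > 0:
        center = center + rng.normal(0.0, config.overlay_trans_sigma_mm, 3)
    postop_cup = CupPose(center, axis, "postop")
    return postop_mesh, postop_cup, disp


@dataclass(frozen=True)
class CaseTruth:
    """Ground-truth transforms and pose, retained for oracle checks only."""

    true_cup: CupPose                       # pre-op/model frame
    rater_transforms: tuple                 # rater frame -> pre-op frame
    postop_displacement: RigidTransform     # pre-op -> post-op


@dataclass(frozen=True)
class SyntheticCase:
    """One simulated surgery: observables plus (separable) ground truth."""

    config: SceneConfig
    pelvis: PelvisModel
    frame: PelvicFrame
    rater_points: tuple                     # PointSet per rater, rater frames
    cup_in_rater: tuple                     # CupPose per rater, rater frames
    postop_mesh: SurfaceMesh
    postop_cup: CupPose                     # post-op frame
    truth: CaseTruth | None

    def without_truth(self) -> "SyntheticCase":
        """Observable inputs only — what the analysis pipeline may read."""
        return replace(self, truth=None)


def simulate_case(config: SceneConfig) -> SyntheticCase:
    """Assemble a full study case from the per-stage generators."""
    pelvis = generate_pelvis(config)
    frame = pelvic_frame_for(pelvis, config.pelvic_tilt_deg)
    true_cup = implant_cup(pelvis, frame, config.cup_target(),
                           config.cup_depth_mm)

    root = np.random.SeedSequence((config.seed, 202))
    rater_seeds = root.spawn(config.n_raters)
    rater_points, cup_in_rater, rater_transforms = [], [], []
    for ss in rater_seeds:
        rng = np.random.default_rng(ss)
        model_pts = sample_registration_points(pelvis, config.region_counts,
                                               config.point_noise_sigma, rng)
        # rater/tracker world frame: the probed points and the physically
        # tracked cup are both expressed there; G maps rater -> model frame
        g = random_rigid_transform(rng, config.rater_rot_deg,
                                   config.rater_trans_mm)
        g_inv = g.invert()
        rater_points.append(model_pts.transformed(g_inv))
        cup_in_rater.append(CupPose(g_inv.apply(true_cup.center),
                                    g_inv.apply_vector(true_cup.axis), "rater"))
        rater_transforms.append(g)

    rng_post = np.random.default_rng(root.spawn(1)[0])
    postop_mesh, postop_cup, disp = simulate_postop(pelvis.mesh, true_cup,
                                                    config, rng_post)
    return SyntheticCase(
        config, pelvis, frame, tuple(rater_points), tuple(cup_in_rater),
        postop_mesh, postop_cup,
        CaseTruth(true_cup, tuple(rater_transforms), disp),
    )


# -- case directory IO -----------------------------------------------------

def write_case(case: SyntheticCase, out_dir) -> None:
    """Write a case directory (meshes, landmarks, points, poses, truth)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case.config.to_yaml(out / "config.yaml")
    case.pelvis.mesh.save(out / "preop.stl")
    case.postop_mesh.save(out / "postop.stl")
    case.pelvis.landmarks.to_csv(out / "landmarks.csv")
    with open(out / "regions.json", "w") as fh:
        json.dump({k: v.tolist() for k, v in
                   case.pelvis.region_centroids().items()}, fh, indent=2)
    for i, (pts, cup) in enumerate(zip(case.rater_points, case.cup_in_rater),
                                   start=1):
        import pandas as pd

        pd.DataFrame({"label": pts.labels, "x": pts.points[:, 0],
                      "y": pts.points[:, 1], "z": pts.points[:, 2]}).to_csv(
            out / f"rater_{i}_points.csv", index=False)
        cup.to_json(out / f"rater_{i}_cup.json")
    case.postop_cup.to_json(out / "postop_cup.json")
    truth = {
        "true_cup": case.truth.true_cup.to_dict(),
        "rater_transforms": [t.to_dict() for t in case.truth.rater_transforms],
        "postop_displacement": case.truth.postop_displacement.to_dict(),
        "acetabular_center": case.pelvis.acetabular_center.tolist(),
        "acetabular_radius": case.pelvis.acetabular_radius,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
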