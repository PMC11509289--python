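"""Post-op-to-pre-op assessment and navigation errors.

The assessment pipeline: register the post-op bone surface back to the
pre-op coordinate system (dense surface ICP on the segmented meshes — the
pelvis is rigid and alignment quality is scored by surface distance anyway),
transform the post-op cup pose into pre-op coordinates, and compare it with
the guide-tool readout. The navigation error of each quantity is defined as
*guide minus post-op* value: operative anteversion and inclination in
degrees, and the signed cup depth difference (along the guide cup axis,
positive = guide cup lateral/shallower) in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cup import CupAngles, CupPose, LEFT, OPERATIVE, operative_angles, \
    axis_from_operative_angles, signed_depth_difference
from .frames import PelvicFrame
from .mesh import SurfaceMesh
from .registration import (ICPRegistration, alignment_accuracy,
                           multistart_register, pca_coarse_candidates)
from .rigid import RigidTransform, random_rigid_transform


@dataclass(frozen=True)
class NavigationError:
    """Per-case guide-vs-post-op differences: degrees and mm, guide minus
    post-op; depth follows the lateral-positive convention."""

    d_anteversion: float
    d_inclination: float
    d_depth: float
    case_id: str = ""
    rater_id: str | None = None

    def __post_init__(self):
        for name in ("d_anteversion", "d_inclination", "d_depth"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")


@dataclass(frozen=True)
class PostopRegistration:
    transform: RigidTransform       # post-op frame -> pre-op frame
    accuracy_mm: float              # mean surface distance after alignment
    accuracy_warning: bool          # accuracy above the configured ceiling


def register_postop_to_preop(postop_mesh: SurfaceMesh, preop_mesh: SurfaceMesh,
                             sample_size: int = 1000,
                             accuracy_ceiling_mm: float = 1.0,
                             n_starts: int = 4,
                             perturb_rot_deg: float = 10.0,
                             perturb_trans_mm: float = 10.0,
                             tol: float = 1e-6, max_iter: int = 200,
                             seed=0) -> PostopRegistration:
    """Align the post-op scan to pre-op coordinates by dense surface ICP.

    A subsample of post-op vertices is registered to the pre-op surface. All
    four proper principal-axes coarse alignments are refined (the pelvis
    blade is nearly 180-degree symmetric, so the coarse sign ranking alone
    is unreliable), plus ``n_starts - 1`` perturbed restarts of the
    best-ranked one; the refined fit with the smallest RMS wins. Returns the
    transform and the alignment accuracy (mean surface distance of *all*
    transformed post-op vertices to the pre-op surface); accuracy above
    ``accuracy_ceiling_mm`` raises a warning flag, not an error.
    """
    rng = np.random.default_rng(seed)
    verts = postop_mesh.vertices
    if sample_size < len(verts):
        idx = rng.choice(len(verts), size=sample_size, replace=False)
        sample = verts[idx]
    else:
        sample = verts
    # coarse candidates from the FULL clouds: the blade's top two inertia
    # eigenvalues are nearly degenerate, so subsampled principal axes can
    # rotate arbitrarily in that subspace
    inits = pca_coarse_candidates(verts, preop_mesh.vertices)
    for _ in range(max(0, n_starts - 1)):
        perturb = random_rigid_transform(rng, perturb_rot_deg, perturb_trans_mm)
        inits.append(perturb.compose(inits[0]))
    # short-budget stage to separate basins, then refine the two best fully
    staged = []
    for init in inits:
        est = ICPRegistration(preop_mesh, init=init, tol=max(tol, 1e-4),
                              max_iter=min(max_iter, 30), polish=False
                              ).fit(sample)
        staged.append(est)
    staged.sort(key=lambda e: e.rms_residual_)
    best = None
    for est in staged[:2]:
        ref = ICPRegistration(preop_mesh, init=est.transform_, tol=tol,
                              max_iter=max_iter).fit(sample)
        if best is None or ref.rms_residual_ < best.rms_residual_:
            best = ref
    accuracy = alignment_accuracy(best.transform_.apply(verts), preop_mesh)
    return PostopRegistration(best.transform_, accuracy,
                              accuracy > accuracy_ceiling_mm)


def transform_cup_pose(t: RigidTransform, pose: CupPose,
                       frame_id: str = "preop",
                       expected_frame: str | None = None) -> CupPose:
    """Map a cup pose through a rigid transform: centre by the full
    transform, axis by rotation only (unit norm preserved)."""
    if expected_frame is not None and pose.frame_id != expected_frame:
        raise ValueError(
            f"pose is in frame {pose.frame_id!r}, expected {expected_frame!r}"
        )
    return CupPose(t.apply(pose.center), t.apply_vector(pose.axis), frame_id)


def navigation_error(guide: CupPose, postop_in_preop: CupPose,
                     frame: PelvicFrame, side: str = LEFT,
                     guide_angles: CupAngles | None = None,
                     case_id: str = "", rater_id: str | None = None,
                     ) -> NavigationError:
    """Guide-minus-post-op navigation error in the pre-op pelvic frame.

    ``guide_angles`` overrides the angles derived from ``guide`` (used when
    the displayed readout differs from the raw pose, e.g. an injected offset
    probe); the depth metric always projects on the guide cup axis.
    """
    if guide.frame_id != postop_in_preop.frame_id:
        raise ValueError(
            f"poses in different frames: {guide.frame_id!r} vs "
            f"{postop_in_preop.frame_id!r}"
        )
    ga = guide_angles if guide_angles is not None else \
        operative_angles(guide, frame, side)
    pa = operative_angles(postop_in_preop, frame, side)
    return NavigationError(
        ga.anteversion - pa.anteversion,
        ga.inclination - pa.inclination,
        signed_depth_difference(guide, postop_in_preop),
        case_id=case_id, rater_id=rater_id,
    )


# -- whole-case assessment -------------------------------------------------

@dataclass(frozen=True)
class AssessmentParams:
    """Analysis-side knobs (registration settings and validation probes)."""

    n_starts: int = 16
    perturb_rot_deg: float = 15.0
    perturb_trans_mm: float = 20.0
    icp_tol: float = 1e-6
    icp_max_iter: int = 200
    postop_sample_size: int = 1000
    postop_n_starts: int = 4
    accuracy_ceiling_mm: float = 1.0
    guide_anteversion_offset_deg: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class CaseAssessment:
    errors: tuple                   # NavigationError per rater
    guide_poses: tuple              # CupPose per rater, pre-op frame
    postop_in_preop: CupPose
    rater_rms_mm: tuple
    postop_accuracy_mm: float
    accuracy_warning: bool


def assess_case(case, params: AssessmentParams = AssessmentParams(),
                case_id: str = "") -> CaseAssessment:
    """Run the full analysis on one case's observables.

    Touches only observable inputs (meshes, landmarks, probed points, the
    tracked cup pose per rater frame, the post-op cup pose); any recorded
    ground truth on the case is ignored and may be absent.
    """
    pelvis = case.pelvis
    frame = case.frame
    side = pelvis.side
    regions = pelvis.region_centroids()

    postop_reg = register_postop_to_preop(
        case.postop_mesh, pelvis.mesh,
        sample_size=params.postop_sample_size,
        accuracy_ceiling_mm=params.accuracy_ceiling_mm,
        n_starts=params.postop_n_starts,
        tol=params.icp_tol, max_iter=params.icp_max_iter, seed=params.seed,
    )
    postop_pose = transform_cup_pose(postop_reg.transform, case.postop_cup,
                                     frame_id="preop")

    errors, guide_poses, rms = [], [], []
    for i, (pts, cup_rater) in enumerate(zip(case.rater_points,
                                             case.cup_in_rater), start=1):
        reg = multistart_register(
            pts, pelvis.mesh, model_regions=regions,
            n_starts=params.n_starts, seed=params.seed + i,
            perturb_rot_deg=params.perturb_rot_deg,
            perturb_trans_mm=params.perturb_trans_mm,
            tol=params.icp_tol, max_iter=params.icp_max_iter,
        )
        guide_pose = transform_cup_pose(reg.transform, cup_rater,
                                        frame_id="preop")
        ga = operative_angles(guide_pose, frame, side)
        if params.guide_anteversion_offset_deg != 0.0:
            ga = CupAngles(ga.anteversion + params.guide_anteversion_offset_deg,
                           ga.inclination, OPERATIVE)
            guide_pose = CupPose(
                guide_pose.center,
                axis_from_operative_angles(ga, frame, side), "preop",
            )
        errors.append(navigation_error(guide_pose, postop_pose, frame, side,
                                       guide_angles=ga, case_id=case_id,
                                       rater_id=f"rater_{i}"))
        guide_poses.append(guide_pose)
        rms.append(reg.rms_residual)

    return CaseAssessment(tuple(errors), tuple(guide_poses), postop_pose,
                          tuple(rms), postop_reg.accuracy_mm,
                          postop_reg.accuracy_warning)
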