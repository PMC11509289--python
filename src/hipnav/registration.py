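"""Sparse point-to-surface rigid registration ("patient alignment").

The intra-operative alignment step matches ~26 probed bone-surface points to
the pre-operative 3D pelvis model by minimizing the overall point-to-surface
distance. It is implemented as iterative closest point (ICP) with exact
closest-point-on-triangle correspondences and a Kabsch update, wrapped in a
seeded multi-start search around a coarse region-centroid alignment — a
reproducible stand-in for the proprietary global search of the clinical
system, optimizing the same objective.

Estimators follow scikit-learn conventions (``fit`` / ``transform`` /
``get_params``); fitted attributes carry a trailing underscore.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .mesh import SurfaceMesh
from .rigid import PointSet, RigidTransform, kabsch_align, random_rigid_transform

_MONOTONE_SLACK = 1e-9  # mm; ICP objective may not rise beyond this


class DivergenceError(RuntimeError):
    """ICP objective increased beyond tolerance (invariant breach)."""


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one registration run (points-frame -> model-frame)."""

    transform: RigidTransform
    rms_residual: float
    mean_residual: float
    iterations: int
    converged: bool
    per_point_residuals: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.per_point_residuals, float)
        if np.any(r < 0):
            raise ValueError("negative residuals")
        object.__setattr__(self, "per_point_residuals", r)


def _kabsch_rt(src: np.ndarray, dst: np.ndarray):
    """Lightweight Kabsch update for the ICP inner loop: (R, t) arrays only.

    Assumes validated, non-degenerate inputs (the correspondences of a
    well-posed ICP step); reflections are still guarded.
    """
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    U, _, Vt = np.linalg.svd((src - sc).T @ (dst - dc))
    if np.linalg.det(Vt.T @ U.T) < 0:
        Vt = Vt.copy()
        Vt[-1] *= -1.0
    R = Vt.T @ U.T
    return R, dc - R @ sc


def _check_points(X) -> np.ndarray:
    if isinstance(X, PointSet):
        X = X.points
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected (N, 3) points, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("points contain non-finite coordinates")
    return X


def _point_to_plane_polish(X, mesh, R, t, rms, dists, max_steps=12):
    """Gauss-Newton point-to-plane refinement of a converged ICP pose.

    Point-to-point ICP creeps along the surface near the optimum (linear
    convergence in the sliding directions); a few linearized point-to-plane
    steps remove that floor. Steps are accepted only while the point-to-
    surface RMS does not increase, so the reported objective stays monotone.
    """
    normals = mesh.face_normals()
    for _ in range(max_steps):
        moved = X @ R.T + t
        cp, d, fid = mesh.nearest(moved)
        n = normals[fid]
        r = np.einsum("ij,ij->i", moved - cp, n)
        J = np.hstack([np.cross(moved, n), n])  # d r_i / d (rotvec, dt)
        A = J.T @ J
        try:
            delta = np.linalg.solve(A + 1e-12 * np.trace(A) / 6 * np.eye(6),
                                    -(J.T @ r))
        except np.linalg.LinAlgError:
            break
        Rw = Rotation.from_rotvec(delta[:3]).as_matrix()
        R_new = Rw @ R
        t_new = Rw @ t + delta[3:]
        _, d_new, _ = mesh.nearest(X @ R_new.T + t_new)
        rms_new = float(np.sqrt(np.mean(d_new**2)))
        if rms_new > rms + _MONOTONE_SLACK:
            break
        R, t, rms, dists = R_new, t_new, rms_new, d_new
        if np.abs(delta).max() < 1e-14:
            break
    return R, t, rms, dists


class ICPRegistration(BaseEstimator, TransformerMixin):
    """Point-to-surface ICP against a fixed triangle mesh.

    Alternates exact closest-point correspondence with a Kabsch least-squares
    update until the RMS point-to-surface residual changes by less than
    ``tol`` (mm) or ``max_iter`` is reached, then applies a short point-to-
    plane Gauss-Newton polish (``polish=False`` disables it). The RMS
    objective is asserted non-increasing at every iteration.

    Parameters
    ----------
    mesh : SurfaceMesh
        Target surface (model frame).
    init : RigidTransform, optional
        Initial points-frame -> model-frame guess (identity if omitted).
    tol : float
        Convergence threshold on the RMS change, mm.
    max_iter : int
        Iteration cap.

    Attributes
    ----------
    transform_ : RigidTransform
        Estimated points-frame -> model-frame transform.
    rms_residual_, mean_residual_ : float
        Final point-to-surface residuals, mm.
    n_iter_ : int
    converged_ : bool
    per_point_residuals_ : ndarray
    result_ : RegistrationResult
    """

    def __init__(self, mesh: SurfaceMesh = None, init: RigidTransform = None,
                 tol: float = 1e-6, max_iter: int = 200, polish: bool = True):
        self.mesh = mesh
        self.init = init
        self.tol = tol
        self.max_iter = max_iter
        self.polish = polish

    def fit(self, X, y=None):
        if self.mesh is None:
            raise ValueError("a target SurfaceMesh is required")
        X = _check_points(X)
        if len(X) < 6:
            raise ValueError(f"need at least 6 registration points, got {len(X)}")
        T0 = self.init if self.init is not None else RigidTransform.identity()
        R, t = T0.rotation, T0.translation

        prev_rms = np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            moved = X @ R.T + t
            closest, dists, _ = self.mesh.nearest(moved)
            rms = float(np.sqrt(np.mean(dists**2)))
            if rms > prev_rms + _MONOTONE_SLACK:
                raise DivergenceError(
                    f"ICP objective increased at iteration {it}: "
                    f"{prev_rms:.6g} -> {rms:.6g} mm"
                )
            if abs(prev_rms - rms) < self.tol:
                converged = True
                break
            prev_rms = rms
            Rs, ts = _kabsch_rt(moved, closest)
            R = Rs @ R
            t = Rs @ t + ts
        if not converged:
            # (R, t) were updated after the last evaluation: re-measure
            _, dists, _ = self.mesh.nearest(X @ R.T + t)
            rms = float(np.sqrt(np.mean(dists**2)))
        if self.polish:
            R, t, rms, dists = _point_to_plane_polish(X, self.mesh, R, t,
                                                      rms, dists)
        T = RigidTransform(R, t)

        self.transform_ = T
        self.rms_residual_ = rms
        self.mean_residual_ = float(np.mean(dists))
        self.per_point_residuals_ = np.asarray(dists, float)
        self.n_iter_ = it
        self.converged_ = converged
        self.result_ = RegistrationResult(
            T, self.rms_residual_, self.mean_residual_, it, converged,
            self.per_point_residuals_,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "transform_")
        return self.transform_.apply(_check_points(X))


class MultiStartICP(BaseEstimator, TransformerMixin):
    """Seeded multi-start ICP around a coarse landmark-region prior.

    The coarse alignment is a Kabsch fit of per-region point centroids onto
    the model's region centroids (``model_regions``); the remaining starts
    perturb it by random rotations up to ``perturb_rot_deg`` and translations
    up to ``perturb_trans_mm``. The start with the smallest RMS residual
    wins. Deterministic given ``random_state``.

    ``fit(X, labels=...)`` takes per-point region labels; a :class:`PointSet`
    with labels may be passed directly as ``X``.
    """

    def __init__(self, mesh: SurfaceMesh = None,
                 model_regions: Mapping[str, np.ndarray] = None,
                 init: RigidTransform = None, n_starts: int = 16,
                 perturb_rot_deg: float = 15.0, perturb_trans_mm: float = 20.0,
                 tol: float = 1e-6, max_iter: int = 200, random_state=None):
        self.mesh = mesh
        self.model_regions = model_regions
        self.init = init
        self.n_starts = n_starts
        self.perturb_rot_deg = perturb_rot_deg
        self.perturb_trans_mm = perturb_trans_mm
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _coarse_init(self, X: np.ndarray, labels) -> RigidTransform:
        if self.init is not None:
            return self.init
        if self.model_regions and labels is not None:
            src, dst = [], []
            for name, centroid in self.model_regions.items():
                mask = np.asarray([lb == name for lb in labels])
                if mask.any():
                    src.append(X[mask].mean(axis=0))
                    dst.append(np.asarray(centroid, float))
            if len(src) >= 3:
                try:
                    return kabsch_align(np.asarray(src), np.asarray(dst))
                except ValueError:
                    pass  # collinear centroids: fall through to translation
            if src:
                return RigidTransform(
                    np.eye(3),
                    np.mean(np.asarray(dst), axis=0) - np.mean(np.asarray(src), axis=0),
                )
        # translation-only fallback: match point centroid to mesh centroid
        return RigidTransform(np.eye(3),
                              self.mesh.vertices.mean(axis=0) - X.mean(axis=0))

    def fit(self, X, y=None, labels=None):
        if isinstance(X, PointSet) and labels is None:
            labels = X.labels
        X = _check_points(X)
        if self.mesh is None:
            raise ValueError("a target SurfaceMesh is required")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        rng = np.random.default_rng(self.random_state)
        coarse = self._coarse_init(X, labels)

        inits = [coarse]
        for _ in range(self.n_starts - 1):
            perturb = random_rigid_transform(rng, self.perturb_rot_deg,
                                             self.perturb_trans_mm)
            inits.append(perturb.compose(coarse))

        # stage 1: a short ICP budget per start separates the basins; the
        # unperturbed coarse start plus the best stage-1 candidates are then
        # refined to full tolerance (ICP is memoryless, so continuing a
        # truncated run reproduces the uninterrupted trajectory)
        stage_tol = max(self.tol, 1e-4)
        stage_iter = min(self.max_iter, 30)
        staged, failures = [], []
        for i, init in enumerate(inits):
            try:
                icp = ICPRegistration(self.mesh, init=init, tol=stage_tol,
                                      max_iter=stage_iter, polish=False).fit(X)
                staged.append((i, icp.result_))
            except DivergenceError as exc:
                failures.append((i, str(exc)))
        if not staged:
            raise DivergenceError(
                "all starts diverged: " + "; ".join(f"start {i}: {m}"
                                                    for i, m in failures)
            )
        order = sorted(range(len(staged)),
                       key=lambda k: staged[k][1].rms_residual)
        finalists = {k for k in order[:3]}
        finalists |= {k for k, (i, _) in enumerate(staged) if i == 0}

        results = []
        for k, (i, stage_res) in enumerate(staged):
            if k not in finalists:
                results.append(stage_res)
                continue
            try:
                icp = ICPRegistration(self.mesh, init=stage_res.transform,
                                      tol=self.tol,
                                      max_iter=self.max_iter).fit(X)
                results.append(icp.result_)
            except DivergenceError as exc:
                failures.append((i, str(exc)))
                results.append(stage_res)
        best = int(np.argmin([r.rms_residual for r in results]))
        self.results_ = results
        self.best_index_ = best
        self.result_ = results[best]
        self.transform_ = self.result_.transform
        self.rms_residual_ = self.result_.rms_residual
        self.mean_residual_ = self.result_.mean_residual
        self.n_iter_ = self.result_.iterations
        self.converged_ = self.result_.converged
        self.per_point_residuals_ = self.result_.per_point_residuals
        return self

    def transform(self, X):
        check_is_fitted(self, "transform_")
        return self.transform_.apply(_check_points(X))


# -- thin functional wrappers ---------------------------------------------

def icp_point_to_surface(points, mesh: SurfaceMesh,
                         init: RigidTransform = None, tol: float = 1e-6,
                         max_iter: int = 200) -> RegistrationResult:
    """Single-start point-to-surface ICP; see :class:`ICPRegistration`."""
    return ICPRegistration(mesh, init=init, tol=tol, max_iter=max_iter).fit(
        points).result_


def multistart_register(points, mesh: SurfaceMesh,
                        model_regions: Mapping[str, np.ndarray] = None,
                        n_starts: int = 16, seed=None,
                        **kwargs) -> RegistrationResult:
    """Multi-start registration; see :class:`MultiStartICP`."""
    est = MultiStartICP(mesh, model_regions=model_regions, n_starts=n_starts,
                        random_state=seed, **kwargs)
    return est.fit(points).result_


@dataclass(frozen=True)
class ScrewCheck:
    passed: bool
    residual_mm: float


def control_screw_check(measured, model_point, t: RigidTransform,
                        tol_mm: float = 1.0) -> ScrewCheck:
    """Validate an alignment with a re-probed control screw.

    ``residual = || t(measured) - model_point ||``; passes (inclusively) when
    the residual is within ``tol_mm``.
    """
    if tol_mm <= 0:
        raise ValueError("tol_mm must be positive")
    residual = float(np.linalg.norm(t.apply(np.asarray(measured, float))
                                    - np.asarray(model_point, float)))
    return ScrewCheck(residual <= tol_mm, residual)


def alignment_accuracy(points_a, mesh_b: SurfaceMesh) -> float:
    """Mean point-to-surface distance (mm) from points (or a mesh's vertices)
    to a surface — the study's alignment-accuracy readout.

    Note the metric is asymmetric: ``accuracy(A -> B) != accuracy(B -> A)``
    in general; report both when comparing two meshes.
    """
    if isinstance(points_a, SurfaceMesh):
        points_a = points_a.vertices
    pts = _check_points(points_a)
    if len(pts) == 0:
        raise ValueError("empty point set")
    _, d, _ = mesh_b.nearest(pts)
    return float(np.mean(d))


def pca_coarse_candidates(src_points, dst_points) -> list:
    """Coarse alignments of two clouds of the same rigid object.

    Matches centroids and principal axes; the 4 proper axis-sign combinations
    are all returned, ordered by nearest-neighbour RMS (best first). Nearly
    symmetric shapes make the sign disambiguation marginal, so callers should
    refine every candidate rather than trusting the ranking.
    """
    from scipy.spatial import cKDTree

    src = _check_points(src_points)
    dst = _check_points(dst_points)
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    _, _, Vs = np.linalg.svd(src - sc, full_matrices=False)
    _, _, Vd = np.linalg.svd(dst - dc, full_matrices=False)
    tree = cKDTree(dst)
    scored = []
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = Vd.T @ np.diag(signs) @ Vs
        if np.linalg.det(R) < 0:  # guard: flip last axis to stay proper
            R = Vd.T @ np.diag(signs) @ np.diag([1, 1, -1]) @ Vs
        T = RigidTransform(R, dc - R @ sc)
        d, _ = tree.query(T.apply(src[:: max(1, len(src) // 500)]))
        scored.append((float(np.sqrt(np.mean(d**2))), T))
    scored.sort(key=lambda item: item[0])
    return [t for _, t in scored]


def pca_coarse_align(src_points, dst_points) -> RigidTransform:
    """Best-scoring principal-axes coarse alignment (see
    :func:`pca_coarse_candidates`)."""
    return pca_coarse_candidates(src_points, dst_points)[0]
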