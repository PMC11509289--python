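import numpy as np
import pytest
from sklearn.base import clone

from hipnav import (DivergenceError, ICPRegistration, MultiStartICP,
                    RigidTransform, alignment_accuracy, compose,
                    control_screw_check, icp_point_to_surface, invert,
                    multistart_register, pca_coarse_align,
                    random_rigid_transform, rotation_angle_deg)
from hipnav.synthetic import SceneConfig, sample_registration_points
import trimesh

from hipnav.mesh import SurfaceMesh


def surface_samples(pelvis, sigma, seed, counts=None):
    rng = np.random.default_rng(seed)
    counts = counts or {"iliac_crest": 8, "anterior_wall": 6,
                        "posterior_wall": 6, "acetabular_rim": 6}
    return sample_registration_points(pelvis, counts, sigma, rng)


class TestICP:
    def test_exact_points_identity_init(self, pelvis):
        pts = surface_samples(pelvis, 0.0, 0)
        res = icp_point_to_surface(pts, pelvis.mesh)
        assert res.rms_residual < 1e-9
        assert rotation_angle_deg(res.transform) < 1e-9
        assert np.linalg.norm(res.transform.translation) < 1e-9
        assert res.converged

    def test_recovers_known_displacement(self, pelvis):
        pts = surface_samples(pelvis, 0.0, 1)
        t = random_rigid_transform(np.random.default_rng(2), 8.0, 10.0)
        displaced = pts.transformed(t.invert())
        res = icp_point_to_surface(displaced, pelvis.mesh, tol=1e-10,
                                   max_iter=500)
        err = compose(res.transform, invert(t))
        assert rotation_angle_deg(err) < 0.1
        assert np.linalg.norm(err.translation) < 0.1

    def test_monotone_objective_flagged(self, pelvis):
        """Divergence raises; normal runs report convergence and residuals."""
        pts = surface_samples(pelvis, 0.5, 3)
        est = ICPRegistration(pelvis.mesh).fit(pts.points)
        assert est.converged_
        assert est.mean_residual_ <= est.per_point_residuals_.max()
        assert est.per_point_residuals_.min() >= 0

    def test_sklearn_estimator_contract(self, pelvis):
        est = ICPRegistration(pelvis.mesh, tol=1e-5, max_iter=50)
        params = est.get_params()
        assert params["tol"] == 1e-5
        cloned = clone(est)
        pts = surface_samples(pelvis, 0.2, 4)
        cloned.fit(pts.points)
        moved = cloned.transform(pts.points)
        assert moved.shape == pts.points.shape
        with pytest.raises(Exception):
            ICPRegistration(pelvis.mesh).transform(pts.points)  # not fitted

    def test_too_few_points_rejected(self, pelvis):
        with pytest.raises(ValueError, match="6"):
            ICPRegistration(pelvis.mesh).fit(pelvis.mesh.vertices[:5])

    def test_equivariance_under_world_motion(self, pelvis):
        """Moving mesh and points by G conjugates the recovered transform."""
        pts = surface_samples(pelvis, 0.3, 5)
        t = random_rigid_transform(np.random.default_rng(6), 5.0, 5.0)
        displaced = pts.transformed(t)
        res0 = icp_point_to_surface(displaced, pelvis.mesh, tol=1e-9)
        g = random_rigid_transform(np.random.default_rng(7), 180.0, 80.0)
        # identity init conjugates to identity, so both runs are comparable
        res1 = icp_point_to_surface(
            displaced.transformed(g), pelvis.mesh.transformed(g), tol=1e-9)
        conj = compose(g, compose(res0.transform, invert(g)))
        delta = compose(res1.transform, invert(conj))
        assert rotation_angle_deg(delta) < 1e-6
        assert np.linalg.norm(delta.translation) < 1e-6


class TestMultiStart:
    def test_correct_prior_matches_single_icp(self, pelvis):
        pts = surface_samples(pelvis, 0.2, 8)
        single = icp_point_to_surface(pts, pelvis.mesh)
        multi = multistart_register(pts, pelvis.mesh,
                                    model_regions=pelvis.region_centroids(),
                                    n_starts=8, seed=0)
        assert multi.rms_residual <= single.rms_residual + 1e-9

    def test_deterministic_given_seed(self, pelvis):
        pts = surface_samples(pelvis, 0.4, 9)
        a = multistart_register(pts, pelvis.mesh, n_starts=6, seed=123)
        b = multistart_register(pts, pelvis.mesh, n_starts=6, seed=123)
        assert np.array_equal(a.transform.rotation, b.transform.rotation)
        assert a.rms_residual == b.rms_residual

    def test_region_prior_recovers_arbitrary_rater_pose(self, pelvis):
        pts = surface_samples(pelvis, 0.3, 10)
        g = random_rigid_transform(np.random.default_rng(11), 170.0, 150.0)
        obs = pts.transformed(g.invert())
        res = multistart_register(obs, pelvis.mesh,
                                  model_regions=pelvis.region_centroids(),
                                  n_starts=16, seed=5)
        err = compose(res.transform, invert(g))
        assert rotation_angle_deg(err) < 1.0
        assert np.linalg.norm(err.translation) < 1.0

    def test_best_of_starts_is_minimum(self, pelvis):
        pts = surface_samples(pelvis, 0.4, 12)
        est = MultiStartICP(pelvis.mesh,
                            model_regions=pelvis.region_centroids(),
                            n_starts=8, random_state=3).fit(pts)
        assert est.rms_residual_ == min(r.rms_residual for r in est.results_)
        assert est.results_[est.best_index_].rms_residual == est.rms_residual_


class TestControlScrew:
    def test_exact_point_passes(self):
        t = random_rigid_transform(np.random.default_rng(13), 30, 30)
        model = np.array([40.0, -10.0, 25.0])
        check = control_screw_check(t.invert().apply(model), model, t)
        assert check.passed and check.residual_mm < 1e-9

    def test_boundary_inclusive(self):
        t = RigidTransform.identity()
        check = control_screw_check([1.0, 0, 0], [0.0, 0, 0], t, tol_mm=1.0)
        assert check.passed and check.residual_mm == pytest.approx(1.0)

    def test_rotation_error_chord_length(self):
        """2 deg rotation error, screw 100 mm from center -> ~3.5 mm chord."""
        t = RigidTransform.from_rotvec_deg([0, 0, 2.0])
        measured = np.array([100.0, 0.0, 0.0])
        check = control_screw_check(measured, measured, t, tol_mm=1.0)
        chord = 2 * 100.0 * np.sin(np.radians(1.0))
        assert check.residual_mm == pytest.approx(chord, abs=1e-9)
        assert check.residual_mm == pytest.approx(3.49, abs=0.01)
        assert not check.passed

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            control_screw_check([0, 0, 0], [0, 0, 0],
                                RigidTransform.identity(), tol_mm=0.0)


class TestAlignmentAccuracy:
    def test_self_comparison_zero(self, pelvis):
        assert alignment_accuracy(pelvis.mesh, pelvis.mesh) == \
            pytest.approx(0.0, abs=1e-12)

    def test_normal_offset_sphere(self):
        """Sphere offset 0.2 mm along exact normals -> accuracy ~0.2 mm."""
        tm = trimesh.creation.icosphere(subdivisions=3, radius=30.0)
        sphere = SurfaceMesh.from_trimesh(tm)
        normals = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1,
                                                   keepdims=True)
        offset = SurfaceMesh(sphere.vertices + 0.2 * normals, sphere.faces)
        acc = alignment_accuracy(offset, sphere)
        assert acc == pytest.approx(0.2, abs=0.02)

    def test_asymmetry_acknowledged(self, pelvis):
        """accuracy(A->B) != accuracy(B->A) in general; both are defined."""
        sub = SurfaceMesh(pelvis.mesh.vertices,
                          pelvis.mesh.faces[:len(pelvis.mesh.faces) // 2])
        ab = alignment_accuracy(pelvis.mesh, sub)
        ba = alignment_accuracy(sub, pelvis.mesh)
        assert ab >= 0 and ba >= 0
        assert ab != pytest.approx(ba, abs=1e-6)

    def test_monotone_in_vertex_noise(self, pelvis):
        """Accuracy grows with injected vertex noise (Spearman rho > 0.95)."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(20)
        sigmas = [0.05, 0.1, 0.2, 0.4, 0.8]
        accs = []
        for s in sigmas:
            noisy = pelvis.mesh.vertices + rng.normal(0, s,
                                                      pelvis.mesh.vertices.shape)
            accs.append(alignment_accuracy(noisy, pelvis.mesh))
        rho = spearmanr(sigmas, accs).statistic
        assert rho > 0.95


class TestPCACoarse:
    def test_recovers_large_displacement(self, pelvis):
        g = random_rigid_transform(np.random.default_rng(21), 120.0, 100.0)
        moved = pelvis.mesh.transformed(g)
        t = pca_coarse_align(moved.vertices, pelvis.mesh.vertices)
        err = compose(t, g)
        # coarse only: within the ICP capture basin
        assert rotation_angle_deg(err) < 10.0
        assert np.linalg.norm(err.translation) < 10.0
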