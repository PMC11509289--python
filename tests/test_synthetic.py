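import numpy as np
import pytest

from hipnav import (CupAngles, SceneConfig, generate_pelvis, implant_cup,
                    operative_angles, pelvic_frame_for,
                    sample_registration_points, signed_depth_difference,
                    simulate_case, simulate_postop, write_case)
from hipnav.synthetic import _scale_region_counts

import oracles


class TestGeneratePelvis:
    def test_same_seed_identical(self):
        a = generate_pelvis(SceneConfig(seed=5))
        b = generate_pelvis(SceneConfig(seed=5))
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mesh.faces, b.mesh.faces)

    def test_different_seed_different_shape(self):
        a = generate_pelvis(SceneConfig(seed=5))
        b = generate_pelvis(SceneConfig(seed=6))
        assert not np.array_equal(a.mesh.vertices, b.mesh.vertices)

    def test_acetabular_cavity_radius(self, pelvis):
        """Cavity vertices sit exactly on the construction sphere, and every
        point of the spherical cavity faces is within 2% of the radius from
        the acetabular centre (chordal flattening only)."""
        cav = pelvis.mesh.vertices[pelvis.cavity_vertex_mask]
        r = np.linalg.norm(cav - pelvis.acetabular_center, axis=1)
        assert np.abs(r - pelvis.acetabular_radius).max() < 1e-9
        faces = pelvis.mesh.faces
        cavity_faces = faces[pelvis.cavity_vertex_mask[faces].all(axis=1)]
        assert len(cavity_faces) > 0
        v = pelvis.mesh.vertices
        for f in cavity_faces:
            cp = oracles.closest_point_plane_method(
                pelvis.acetabular_center, v[f[0]], v[f[1]], v[f[2]])
            d = np.linalg.norm(cp - pelvis.acetabular_center)
            assert abs(d - pelvis.acetabular_radius) < \
                0.02 * pelvis.acetabular_radius

    def test_custom_radius(self):
        p = generate_pelvis(SceneConfig(seed=2, acetabular_radius_mm=26.0))
        cav = p.mesh.vertices[p.cavity_vertex_mask]
        r = np.linalg.norm(cav - p.acetabular_center, axis=1)
        assert np.abs(r - 26.0).max() < 1e-9

    def test_left_right_mirror_images(self):
        left = generate_pelvis(SceneConfig(seed=3, side="left"))
        right = generate_pelvis(SceneConfig(seed=3, side="right"))
        mirrored = left.mesh.vertices * np.array([-1.0, 1, 1])
        assert np.abs(right.mesh.vertices - mirrored).max() < 1e-9
        assert np.allclose(right.acetabular_center,
                           left.acetabular_center * np.array([-1.0, 1, 1]))
        assert np.allclose(right.landmarks.asis_left,
                           left.landmarks.asis_right * np.array([-1.0, 1, 1]))

    def test_regions_nonempty(self, pelvis):
        for name, fidx in pelvis.regions.items():
            assert len(fidx) > 0, name


class TestImplantCup:
    def test_target_angles_roundtrip(self, pelvis):
        frame = pelvic_frame_for(pelvis)
        cup = implant_cup(pelvis, frame, CupAngles(15.0, 40.0))
        got = operative_angles(cup, frame, side=pelvis.side)
        assert got.anteversion == pytest.approx(15.0, abs=1e-9)
        assert got.inclination == pytest.approx(40.0, abs=1e-9)

    def test_zero_depth_at_acetabular_center(self, pelvis):
        frame = pelvic_frame_for(pelvis)
        cup = implant_cup(pelvis, frame, CupAngles(15.0, 40.0), depth_mm=0.0)
        assert np.allclose(cup.center, pelvis.acetabular_center, atol=0)

    def test_depth_offset_consistent_with_depth_metric(self, pelvis):
        frame = pelvic_frame_for(pelvis)
        flush = implant_cup(pelvis, frame, CupAngles(15.0, 40.0), 0.0)
        proud = implant_cup(pelvis, frame, CupAngles(15.0, 40.0), 2.0)
        assert signed_depth_difference(proud, flush) == pytest.approx(2.0,
                                                                      abs=1e-9)


class TestSampleRegistrationPoints:
    def test_noiseless_points_on_surface(self, pelvis):
        pts = sample_registration_points(
            pelvis, {"iliac_crest": 10, "acetabular_rim": 10}, 0.0,
            np.random.default_rng(0))
        _, d, _ = pelvis.mesh.nearest(pts.points)
        assert d.max() < 1e-9

    def test_default_region_split_sums_to_26(self):
        counts = _scale_region_counts(26)
        assert counts == {"iliac_crest": 8, "anterior_wall": 6,
                          "posterior_wall": 6, "acetabular_rim": 6}
        assert sum(_scale_region_counts(12).values()) == 12

    def test_noise_magnitude_folded_normal(self, pelvis):
        """Mean point-to-surface distance of sigma-noised samples matches the
        folded-normal expectation (locally planar surface) within 5%."""
        sigma = 0.5
        pts = sample_registration_points(
            pelvis, {"iliac_crest": 4000, "anterior_wall": 3000,
                     "posterior_wall": 3000}, sigma,
            np.random.default_rng(1))
        _, d, _ = pelvis.mesh.nearest(pts.points)
        expected = oracles.folded_normal_mean(sigma)
        assert np.mean(d) == pytest.approx(expected, rel=0.05)

    def test_labels_recorded(self, pelvis):
        pts = sample_registration_points(pelvis, {"iliac_crest": 3,
                                                  "acetabular_rim": 2},
                                         0.1, np.random.default_rng(2))
        assert pts.labels == ("iliac_crest",) * 3 + ("acetabular_rim",) * 2


class TestSimulatePostop:
    def test_zero_noise_zero_displacement(self, pelvis):
        cfg = SceneConfig(seed=0, postop_rot_deg=0.0, postop_trans_mm=0.0,
                          postop_vertex_noise_sigma=0.0)
        frame = pelvic_frame_for(pelvis)
        cup = implant_cup(pelvis, frame, CupAngles(15.0, 40.0))
        mesh, pcup, disp = simulate_postop(pelvis.mesh, cup, cfg,
                                           np.random.default_rng(0))
        assert np.array_equal(mesh.vertices, pelvis.mesh.vertices)
        assert np.allclose(pcup.center, cup.center, atol=0)
        assert disp.rotation_angle_deg() == 0.0

    def test_displacement_equivariance(self, pelvis):
        """Cup angles in the displaced frame equal the originals."""
        from hipnav.frames import PelvicFrame

        cfg = SceneConfig(seed=0, postop_vertex_noise_sigma=0.0)
        frame = pelvic_frame_for(pelvis)
        cup = implant_cup(pelvis, frame, CupAngles(15.0, 40.0))
        _, pcup, disp = simulate_postop(pelvis.mesh, cup, cfg,
                                        np.random.default_rng(3))
        moved_frame = PelvicFrame(
            disp.apply(frame.origin), disp.apply_vector(frame.lateral_axis),
            disp.apply_vector(frame.anterior_axis),
            disp.apply_vector(frame.superior_axis))
        got = operative_angles(pcup, moved_frame, side=pelvis.side)
        assert got.anteversion == pytest.approx(15.0, abs=1e-9)
        assert got.inclination == pytest.approx(40.0, abs=1e-9)

    def test_overlay_noise_angle_spread(self, pelvis):
        """Overlay noise (sigma = 0.5 deg rotation-vector components)
        propagates to anteversion with the small-angle factor 1/cos(I):
        SD(d_av) ~ sigma / cos(40 deg) over 500 draws."""
        sigma = 0.5
        cfg = SceneConfig(seed=0, postop_rot_deg=0.0, postop_trans_mm=0.0,
                          postop_vertex_noise_sigma=0.0,
                          overlay_rot_sigma_deg=sigma)
        frame = pelvic_frame_for(pelvis)
        cup = implant_cup(pelvis, frame, CupAngles(15.0, 40.0))
        rng = np.random.default_rng(4)
        avs = []
        for _ in range(500):
            _, pcup, _ = simulate_postop(pelvis.mesh, cup, cfg, rng)
            avs.append(operative_angles(pcup, frame, side=pelvis.side).anteversion)
        expected = sigma / np.cos(np.radians(40.0))
        assert np.std(avs, ddof=1) == pytest.approx(expected, rel=0.1)


class TestSimulateCase:
    def test_structure_and_rater_count(self, default_case):
        assert len(default_case.rater_points) == 3
        assert len(default_case.cup_in_rater) == 3
        assert len(default_case.truth.rater_transforms) == 3
        # raters share one ground truth but see distinct point sets
        assert not np.allclose(default_case.rater_points[0].points,
                               default_case.rater_points[1].points)

    def test_rater_frames_consistent_with_truth(self, default_case):
        """Mapping rater observables by the true transform recovers the
        model-frame cup pose."""
        truth = default_case.truth
        for g, cup_r in zip(truth.rater_transforms, default_case.cup_in_rater):
            assert np.allclose(g.apply(cup_r.center), truth.true_cup.center,
                               atol=1e-9)
            assert np.allclose(g.apply_vector(cup_r.axis), truth.true_cup.axis,
                               atol=1e-12)

    def test_postop_consistent_with_displacement(self, default_case):
        truth = default_case.truth
        disp = truth.postop_displacement
        # vertex noise is bounded: displaced pre-op mesh ~ post-op mesh
        moved = disp.apply(default_case.pelvis.mesh.vertices)
        resid = np.linalg.norm(moved - default_case.postop_mesh.vertices, axis=1)
        sigma = default_case.config.postop_vertex_noise_sigma
        assert np.median(resid) < 4 * sigma

    def test_deterministic_bit_for_bit(self, tmp_path):
        cfg = SceneConfig(seed=77, n_raters=2)
        for d in ("a", "b"):
            write_case(simulate_case(cfg), tmp_path / d)
        for name in ("preop.stl", "postop.stl", "landmarks.csv", "truth.json",
                     "rater_1_points.csv", "rater_2_points.csv",
                     "postop_cup.json", "config.yaml", "regions.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name

    def test_without_truth_strips_ground_truth(self, default_case):
        assert default_case.without_truth().truth is None


class TestSceneConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"point_noise_sigma": -0.1}, {"n_points": 5}, {"n_raters": 0},
        {"side": "up"}, {"region_counts": {"iliac_crest": 26}, "n_points": 25},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SceneConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SceneConfig(seed=9, point_noise_sigma=0.25, n_raters=2)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SceneConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
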