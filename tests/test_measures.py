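"""Measurement suite: body frame, intrinsic and pose-dependent measures."""

import numpy as np
import pytest
import trimesh

import torsometry as tm
from torsometry.atlas import LandmarkSet
from torsometry.measures import MeasureError


@pytest.fixture(scope="module")
def flat_reg(flat_torso):
    spec, mesh, lms, truth = flat_torso
    return tm.as_registered(mesh, spec), lms, truth


@pytest.fixture(scope="module")
def flat_frame(flat_reg):
    _, lms, _ = flat_reg
    return tm.build_body_frame(lms)


def registered(spec):
    mesh, lms, truth = tm.generate_torso(spec)
    return tm.as_registered(mesh, spec), lms, truth


class TestBodyFrame:
    def test_longitudinal_axis_matches_generator(self, flat_frame):
        assert np.degrees(np.arccos(abs(flat_frame.longitudinal_w @
                                        [0, 0, 1]))) < 0.5

    def test_right_handed_anterior(self, flat_frame):
        f = flat_frame
        assert np.allclose(np.cross(f.lateral_u, f.anterior_v), f.longitudinal_w,
                           atol=1e-12)
        assert f.anterior_v @ [0, 1, 0] > 0.99

    def test_mirrored_landmarks_flip_lateral_keep_anterior(self, flat_reg):
        _, lms, _ = flat_reg
        pts = {}
        for k, v in lms.points.items():
            side = ("_L", "_R")
            if k.endswith(side[0]):
                k2 = k[:-2] + side[1]
            elif k.endswith(side[1]):
                k2 = k[:-2] + side[0]
            else:
                k2 = k
            pts[k2] = v * np.array([-1.0, 1.0, 1.0])
        f0 = tm.build_body_frame(lms)
        f1 = tm.build_body_frame(LandmarkSet(pts))
        assert np.allclose(f1.lateral_u, -f0.lateral_u * np.array([-1, 1, 1]))
        assert np.allclose(f1.anterior_v, f0.anterior_v, atol=1e-12)

    def test_missing_landmark_rejected(self, flat_reg):
        _, lms, _ = flat_reg
        pts = dict(lms.points)
        del pts["SP_C7"]
        with pytest.raises(ValueError, match="missing"):
            LandmarkSet(pts)

    def test_level_planes(self, flat_frame):
        p0 = tm.level_plane(flat_frame, 0.0)
        p1 = tm.level_plane(flat_frame, 1.0)
        pm = tm.level_plane(flat_frame, 0.5)
        assert np.allclose(p0.point, flat_frame.origin)
        d0 = np.linalg.norm(pm.point - p0.point)
        d1 = np.linalg.norm(p1.point - pm.point)
        assert abs(d0 - d1) < 1e-9
        with pytest.raises(ValueError):
            tm.level_plane(flat_frame, 1.2)


class TestIntrinsicMeasures:
    def test_spine_length_matches_truth(self, flat_reg):
        reg, _, truth = flat_reg
        assert tm.spine_length(reg) == pytest.approx(truth.spine_length_mm / 10,
                                                     abs=0.5)
        assert tm.spine_length(reg) == pytest.approx(48.0, abs=0.5)

    def test_spine_length_scales_linearly(self, flat_torso):
        spec, mesh, lms, _ = flat_torso
        reg = tm.as_registered(mesh, spec)
        big = mesh.copy()
        big.apply_scale(2.0)
        reg2 = tm.as_registered(big, spec)
        assert tm.spine_length(reg2) == pytest.approx(2 * tm.spine_length(reg),
                                                      rel=1e-12)

    def test_back_area_halves_and_sum(self, flat_reg, flat_frame):
        reg, _, truth = flat_reg
        total, left, right = tm.back_area(reg, flat_frame)
        assert left == pytest.approx(right, rel=5e-3)
        assert total == left + right
        assert total == pytest.approx(truth.dorsal_area_mm2 * 1e-4, rel=5e-3)

    def test_xsa_elliptic_closed_form(self):
        spec = tm.TorsoSpec(profile="ellipse", a=150.0, b=100.0, bow_mm=0,
                            theta_deg=0, hump_mm=0, n_around=128)
        reg, lms, _ = registered(spec)
        frame = tm.build_body_frame(lms)
        area = tm.cross_section_area(reg, frame, "L2")
        assert area == pytest.approx(np.pi * 1.5 * 1.0, rel=5e-3)

    def test_xsa_invariant_to_axial_rotation(self):
        a = tm.TorsoSpec(profile="ellipse", a=150.0, b=100.0, bow_mm=0,
                         theta_deg=0, hump_mm=0)
        b = tm.TorsoSpec(profile="ellipse", a=150.0, b=100.0, bow_mm=0,
                         theta_deg=12, hump_mm=0)
        ra, la, _ = registered(a)
        rb, lb, _ = registered(b)
        xa = tm.cross_section_area(ra, tm.build_body_frame(la), "T8")
        xb = tm.cross_section_area(rb, tm.build_body_frame(lb), "T8")
        assert xa == pytest.approx(xb, rel=1e-3)

    def test_section_volumes_match_quadrature(self, flat_reg, flat_frame):
        reg, _, truth = flat_reg
        vols = tm.section_volumes(reg, flat_frame)
        assert vols["L2-T8"] == pytest.approx(truth.xsv_mm3(0.25, 0.55) * 1e-6,
                                              rel=5e-3)
        assert vols["PSIS-JN"] == pytest.approx(truth.xsv_mm3(0.0, 0.95) * 1e-6,
                                                rel=5e-3)
        assert vols["PSIS-JN"] >= vols["L2-T8"]

    def test_nested_volume_additivity(self, flat_reg, flat_frame):
        reg, lms, _ = flat_reg
        from torsometry.geometry import Plane
        w = flat_frame.longitudinal_w
        p_psis = tm.level_plane(flat_frame, 0.0)
        p_l2 = Plane(lms["SP_L2"], w)
        p_jn = Plane(lms["JN"], w)
        whole = tm.section_volume(reg.mesh, p_psis, p_jn)
        parts = (tm.section_volume(reg.mesh, p_psis, p_l2) +
                 tm.section_volume(reg.mesh, p_l2, p_jn))
        assert abs(whole - parts) / whole < 1e-9

    def test_inverted_landmark_order_rejected(self, flat_reg, flat_frame):
        reg, _, _ = flat_reg
        upside = reg.mesh.copy()
        upside.apply_transform(trimesh.transformations.rotation_matrix(
            np.pi, [1, 0, 0]))
        reg2 = tm.RegisteredTorso(mesh=upside, atlas=reg.atlas, residual_rms=0)
        with pytest.raises(MeasureError, match="inverted landmark order"):
            tm.section_volumes(reg2, flat_frame)


class TestBsr:
    def test_symmetric_section_is_flat(self, flat_reg, flat_frame):
        reg, _, _ = flat_reg
        assert abs(tm.bsr_at(reg, flat_frame, 0.5)) < 0.2

    def test_recovers_injected_rotation(self):
        spec = tm.TorsoSpec(theta_deg=10, bow_mm=0, hump_mm=0)
        reg, lms, _ = registered(spec)
        frame = tm.build_body_frame(lms)
        assert tm.bsr_at(reg, frame, 0.5) == pytest.approx(10.0, abs=1.0)

    def test_mirror_flips_sign(self):
        spec = tm.TorsoSpec(theta_deg=12, bow_mm=0, hump_mm=6)
        ra, la, _ = registered(spec)
        rb, lb, _ = registered(spec.mirrored())
        va = tm.bsr_at(ra, tm.build_body_frame(la), 0.5)
        vb = tm.bsr_at(rb, tm.build_body_frame(lb), 0.5)
        assert va == pytest.approx(-vb, abs=0.2)
        assert abs(va) > 5

    def test_profile_max_and_grid_consistency(self):
        spec = tm.TorsoSpec(theta_deg=15, bow_mm=0, hump_mm=0)
        reg, lms, _ = registered(spec)
        frame = tm.build_body_frame(lms)
        ts, vals, bsr_max = tm.bsr_profile(reg, frame, n_levels=41)
        assert bsr_max == pytest.approx(15.0, abs=1.5)
        assert ts[np.argmax(np.abs(vals))] == pytest.approx(0.5, abs=0.1)
        assert vals[10] == tm.bsr_at(reg, frame, ts[10])


class TestCentroidAndAxis:
    def test_straight_torso_zero_deviation(self, flat_reg, flat_frame):
        reg, _, _ = flat_reg
        assert abs(tm.centroid_deviation(reg, flat_frame, n_levels=41)) < 0.5

    def test_recovers_injected_bow(self):
        spec = tm.TorsoSpec(theta_deg=0, bow_mm=20, hump_mm=0)
        reg, lms, _ = registered(spec)
        frame = tm.build_body_frame(lms)
        assert tm.centroid_deviation(reg, frame, n_levels=41) == \
            pytest.approx(20.0, abs=1.0)

    def test_translation_invariance(self):
        spec = tm.TorsoSpec(theta_deg=0, bow_mm=20, hump_mm=0)
        reg, lms, _ = registered(spec)
        d0 = tm.centroid_deviation(reg, tm.build_body_frame(lms), n_levels=21)
        moved = reg.mesh.copy()
        moved.apply_translation([55.0, -20.0, 10.0])
        reg2 = tm.RegisteredTorso(mesh=moved, atlas=reg.atlas, residual_rms=0)
        lm2 = lms.transformed(np.block([[np.eye(3), np.array([[55.0], [-20.0], [10.0]])],
                                        [np.zeros((1, 3)), np.ones((1, 1))]]))
        d1 = tm.centroid_deviation(reg2, tm.build_body_frame(lm2), n_levels=21)
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_axis_zero_then_recovers_rotation(self, flat_reg, flat_frame):
        reg, _, _ = flat_reg
        assert abs(tm.trunk_axis(reg, flat_frame, n_levels=21)) < 0.2
        spec = tm.TorsoSpec(theta_deg=12, bow_mm=0, hump_mm=0)
        reg2, lms, _ = registered(spec)
        assert tm.trunk_axis(reg2, tm.build_body_frame(lms), n_levels=41) == \
            pytest.approx(12.0, abs=1.0)

    def test_circular_sections_have_no_axis(self):
        # exactly transverse frame so every slice is a true circle
        spec = tm.TorsoSpec(profile="ellipse", a=100.0, b=100.0, bow_mm=0,
                            theta_deg=0, hump_mm=0)
        reg, lms, _ = registered(spec)
        frame = tm.BodyFrame(origin=np.array([0.0, 0.0, 0.0]),
                             lateral_u=np.array([1.0, 0.0, 0.0]),
                             anterior_v=np.array([0.0, 1.0, 0.0]),
                             longitudinal_w=np.array([0.0, 0.0, 1.0]),
                             trunk_height=spec.height, pose="EOS",
                             reference_mode="coronal")
        with pytest.raises(MeasureError, match="isotropic"):
            tm.trunk_axis(reg, frame, n_levels=21)


class TestSymmetryLineAndQangle:
    def test_symmetric_line_stays_sagittal(self, flat_reg):
        reg, _, _ = flat_reg
        line = tm.symmetry_line(reg)
        assert len(line) == 201
        assert np.max(np.abs(line[:, 0])) < 0.5

    def test_bowed_line_extent_matches_amplitude(self):
        spec = tm.TorsoSpec(theta_deg=0, bow_mm=25, hump_mm=0)
        reg, _, _ = registered(spec)
        line = tm.symmetry_line(reg)
        assert np.ptp(line[:, 0]) == pytest.approx(25.0, abs=1.0)

    def test_harmonic_fit_recovers_known_coefficients(self, flat_frame):
        t = np.linspace(0, 1, 201)
        a = np.array([3.0, -2.0, 0.5, 1.0])
        b = np.array([10.0, 4.0, -1.5, 0.25])
        x_left = 2.0 + sum(a[k] * np.cos(2 * np.pi * (k + 1) * t) +
                           b[k] * np.sin(2 * np.pi * (k + 1) * t)
                           for k in range(4))
        f = flat_frame
        pts = (f.origin[None, :] - x_left[:, None] * f.lateral_u[None, :]
               + t[:, None] * f.trunk_height * f.longitudinal_w[None, :])
        fit = tm.fit_harmonic(pts, f)
        assert fit.a0 == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(fit.a, a, atol=1e-8)
        assert np.allclose(fit.b, b, atol=1e-8)
        assert fit.residual_rms < 1e-9

    def test_constant_line_fit(self, flat_frame):
        t = np.linspace(0, 1, 201)
        f = flat_frame
        pts = (f.origin[None, :] - 7.0 * f.lateral_u[None, :]
               + t[:, None] * f.trunk_height * f.longitudinal_w[None, :])
        fit = tm.fit_harmonic(pts, f)
        assert fit.a0 == pytest.approx(7.0, abs=1e-10)
        assert np.max(np.abs(np.concatenate([fit.a, fit.b]))) < 1e-8

    def test_qangle_straight_line_flags_no_curve(self):
        fit = tm.HarmonicFit(a0=5.0, a=np.zeros(4), b=np.zeros(4))
        res = tm.qangle(fit, 450.0)
        assert res.angle_deg == 0.0 and not res.has_curve

    def test_qangle_single_harmonic_closed_form(self):
        fit = tm.HarmonicFit(a0=0.0, a=np.zeros(4),
                             b=np.array([25.0, 0, 0, 0.0]))
        res = tm.qangle(fit, 450.0)
        expected = np.degrees(2 * np.arctan(2 * np.pi * 25 / 450))
        assert abs(res.angle_deg) == pytest.approx(expected, abs=0.2)
        assert res.angle_deg > 0  # apex toward patient left
        flipped = tm.qangle(tm.HarmonicFit(a0=0.0, a=np.zeros(4),
                                           b=np.array([-25.0, 0, 0, 0.0])), 450.0)
        assert flipped.angle_deg == pytest.approx(-res.angle_deg, abs=1e-9)


class TestMeasureAll:
    def test_symmetric_torso_suite(self, flat_reg):
        reg, lms, _ = flat_reg
        suite = tm.measure_all(reg, landmarks=lms, n_levels=41)
        assert suite.spine_length_cm > 0
        assert suite.back_area_dm2 > 0
        assert all(v > 0 for v in suite.xsa_dm2.values())
        assert all(v > 0 for v in suite.xsv_l.values())
        assert abs(suite.bsr_deg["max"]) < 0.2
        assert abs(suite.centroid_dev_mm) < 0.5

    def test_adam_pose_suppresses_upright_only_measures(self, flat_torso):
        spec, mesh, lms, _ = flat_torso
        bent, lms_b = tm.adam_pose(mesh, lms)
        reg = tm.as_registered(bent, spec)
        suite = tm.measure_all(reg, landmarks=lms_b, pose="Adam", n_levels=41)
        assert suite.xsa_dm2 is None and suite.xsv_l is None
        assert suite.centroid_dev_mm is None and suite.qangle_deg is None
        assert set(suite.suppressed) == {"xsa", "xsv", "centroid_dev", "axis",
                                         "qangle"}
        assert suite.spine_length_cm > 0 and suite.back_area_dm2 > 0
        assert np.isfinite(suite.bsr_deg["max"])

    def test_rigid_motion_leaves_intrinsic_identical(self, deformed_torso):
        spec, mesh, lms, _ = deformed_torso
        reg = tm.as_registered(mesh, spec)
        s0 = tm.measure_all(reg, landmarks=lms, n_levels=21)
        M = trimesh.transformations.euler_matrix(0.3, 0.6, -0.4)
        M[:3, 3] = [100, 50, -70]
        moved = mesh.copy()
        moved.apply_transform(M)
        reg2 = tm.as_registered(moved, spec)
        s1 = tm.measure_all(reg2, landmarks=lms.transformed(M), n_levels=21)
        assert s1.spine_length_cm == pytest.approx(s0.spine_length_cm, rel=1e-6)
        assert s1.back_area_dm2 == pytest.approx(s0.back_area_dm2, rel=1e-6)
        for k in s0.xsa_dm2:
            assert s1.xsa_dm2[k] == pytest.approx(s0.xsa_dm2[k], rel=1e-6)
        for k in s0.xsv_l:
            assert s1.xsv_l[k] == pytest.approx(s0.xsv_l[k], rel=1e-6)

    def test_repeat_run_is_bit_identical(self, deformed_torso):
        spec, _, _, _ = deformed_torso
        outs = []
        for _ in range(2):
            mesh, lms, _ = tm.generate_torso(spec)
            reg = tm.as_registered(mesh, spec)
            outs.append(tm.measure_all(reg, landmarks=lms, n_levels=21).to_json())
        assert outs[0] == outs[1]
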