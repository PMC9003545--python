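"""Anatomical angles, hand metrics, displacements, PAU/PANU."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from reachval.kinematics import (
    KinematicsError,
    compute_panu,
    compute_pau,
    displacement_deltas,
    elbow_angle,
    hand_metrics,
    retained_angle,
    shoulder_angles,
    summarize_reach,
    trunk_angles,
)
from reachval.segmentation import ReachSegment, detect_reach_bounds
from reachval.synthetic import minimum_jerk_profile, simulate_truth_trial, SyntheticConfig

from conftest import make_recording


class TestRetainedAngle:
    @pytest.mark.parametrize("a0,a1,expected", [(90, 150, 60), (45, 45, 0), (30, 10, -20)])
    def test_end_minus_onset(self, a0, a1, expected):
        series = np.linspace(a0, a1, 20)
        assert retained_angle(series, 0, 19) == pytest.approx(expected)


class TestElbowAngle:
    def test_collinear_is_full_extension(self):
        a = elbow_angle([0, 0, 0], [1, 0, 0], [2, 0, 0])
        assert a[0] == pytest.approx(180.0)

    def test_perpendicular_segments(self):
        a = elbow_angle([0, 0, 1.0], [0, 0, 0], [1.0, 0, 0])
        assert a[0] == pytest.approx(90.0)

    def test_arccos_of_half_is_sixty(self):
        # unit vectors with dot product 0.5
        a = elbow_angle([1.0, 0, 0], [0, 0, 0], [0.5, np.sqrt(3) / 2, 0])
        assert a[0] == pytest.approx(60.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(KinematicsError, match="degenerate"):
            elbow_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


UP = {
    "trunk": np.array([[0.0, 0.0, 450.0]]),
    "hip_left": np.array([[0.0, 110.0, 0.0]]),
    "hip_right": np.array([[0.0, -110.0, 0.0]]),
    "sh_l": np.array([[0.0, 190.0, 430.0]]),
    "sh_r": np.array([[0.0, -190.0, 430.0]]),
}


class TestTrunkAngles:
    def test_upright_still_trunk_is_zero(self):
        flex, rot = trunk_angles(UP["trunk"], UP["hip_left"], UP["hip_right"],
                                 UP["sh_l"], UP["sh_r"])
        np.testing.assert_allclose(flex, 0.0, atol=1e-9)
        np.testing.assert_allclose(rot, 0.0, atol=1e-9)

    def test_ten_degree_forward_tilt(self):
        h = 450.0
        trunk = np.array([[h * np.sin(np.radians(10)), 0.0, h * np.cos(np.radians(10))]])
        flex, _ = trunk_angles(trunk, UP["hip_left"], UP["hip_right"],
                               UP["sh_l"], UP["sh_r"])
        assert flex[0] == pytest.approx(10.0, abs=1e-9)

    def test_fifteen_degree_rotation_assessed_forward_positive(self):
        # +15 deg about +Z advances the right (-Y) shoulder toward +X
        R = Rotation.from_euler("z", 15, degrees=True).as_matrix()
        sh_l = np.vstack([UP["sh_l"], UP["sh_l"][0] @ R.T])
        sh_r = np.vstack([UP["sh_r"], UP["sh_r"][0] @ R.T])
        trunk = np.repeat(UP["trunk"], 2, axis=0)
        hl = np.repeat(UP["hip_left"], 2, axis=0)
        hr = np.repeat(UP["hip_right"], 2, axis=0)
        _, rot = trunk_angles(trunk, hl, hr, sh_l, sh_r, assessed_side="right")
        assert rot[1] == pytest.approx(15.0, abs=1e-9)
        _, rot_left = trunk_angles(trunk, hl, hr, sh_l, sh_r, assessed_side="left")
        assert rot_left[1] == pytest.approx(-15.0, abs=1e-9)


class TestShoulderAngles:
    shoulder = np.array([[0.0, -190.0, 430.0]])

    def run(self, elbow):
        return shoulder_angles(self.shoulder, np.asarray(elbow),
                               UP["trunk"], UP["hip_left"], UP["hip_right"],
                               assessed_side="right")

    def test_arm_hanging_is_zero_zero(self):
        flex, abd = self.run([[0.0, -190.0, 130.0]])
        assert flex[0] == pytest.approx(0.0, abs=1e-9)
        assert abd[0] == pytest.approx(0.0, abs=1e-9)

    def test_horizontal_anterior_is_pure_flexion(self):
        flex, abd = self.run([[300.0, -190.0, 430.0]])
        assert flex[0] == pytest.approx(90.0, abs=1e-9)
        assert abd[0] == pytest.approx(0.0, abs=1e-9)

    def test_horizontal_lateral_is_pure_abduction(self):
        flex, abd = self.run([[0.0, -490.0, 430.0]])
        assert abd[0] == pytest.approx(90.0, abs=1e-9)
        assert flex[0] == pytest.approx(0.0, abs=1e-9)


class TestHandMetrics:
    fs = 100.0

    def segment_for(self, hand, target):
        t = np.arange(hand.shape[0]) / self.fs
        return detect_reach_bounds(hand, target, t, self.fs)

    def test_minimum_jerk_closed_form(self):
        D, T = 300.0, 1.0
        t = np.arange(0.0, 2.0, 1 / self.fs)
        prof = np.where(t < 0.5, 0.0,
                        np.where(t < 1.5, minimum_jerk_profile((t - 0.5) / T), 1.0))
        hand = np.zeros((t.size, 3))
        hand[:, 0] = D * prof
        seg = self.segment_for(hand, np.array([300.0, 0.0, 0.0]))
        m = hand_metrics(hand, seg, self.fs)
        assert m["movement_time"] == pytest.approx(T, rel=0.02)
        assert m["peak_velocity"] == pytest.approx(15 * D / (8 * T), rel=0.02)
        assert m["time_to_peak_velocity"] == pytest.approx(0.5, abs=0.03)
        assert m["mean_velocity"] == pytest.approx(D / T, rel=0.02)
        assert m["path_length_ratio"] == pytest.approx(1.0, abs=0.01)
        assert m["n_velocity_peaks"] == 1

    def test_semicircular_path_ratio_is_half_pi(self):
        # semicircle between (0,0,0) and (200,0,0) at constant speed
        theta = np.linspace(np.pi, 0.0, 400)
        hand = np.column_stack([100 + 100 * np.cos(theta),
                                100 * np.sin(theta),
                                np.zeros_like(theta)])
        seg = ReachSegment(t0=0.0, t_peak=0.01, t_final=(theta.size - 1) / self.fs,
                           i0=0, i_peak=1, i_final=theta.size - 1,
                           d0=200.0, d_final=0.0)
        m = hand_metrics(hand, seg, self.fs)
        assert m["path_length_ratio"] == pytest.approx(np.pi / 2, rel=1e-3)

    def test_constant_velocity_line(self):
        t = np.arange(0, 1, 1 / self.fs)
        hand = np.column_stack([300.0 * t, np.zeros_like(t), np.zeros_like(t)])
        seg = ReachSegment(t0=0.0, t_peak=0.5, t_final=t[-1],
                           i0=0, i_peak=50, i_final=t.size - 1,
                           d0=300.0, d_final=0.0)
        m = hand_metrics(hand, seg, self.fs)
        assert m["path_length_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert m["n_velocity_peaks"] == 1
        assert m["mean_velocity"] == pytest.approx(m["peak_velocity"], rel=0.01)

    def test_zero_displacement_rejected(self):
        hand = np.zeros((100, 3))
        seg = ReachSegment(0.0, 0.5, 0.99, 0, 50, 99, 1.0, 0.0)
        with pytest.raises(KinematicsError, match="PLR undefined"):
            hand_metrics(hand, seg, self.fs)

    def test_time_rescaling_scales_velocities_not_plr(self):
        D, T = 300.0, 1.0
        t = np.arange(0.0, 2.0, 1 / self.fs)
        prof = np.where(t < 0.5, 0.0,
                        np.where(t < 1.5, minimum_jerk_profile((t - 0.5) / T), 1.0))
        hand = np.zeros((t.size, 3))
        hand[:, 0] = D * prof
        seg = self.segment_for(hand, np.array([300.0, 0.0, 0.0]))
        m1 = hand_metrics(hand, seg, self.fs)
        # same samples at half the rate = uniform time dilation a = 2
        seg2 = detect_reach_bounds(hand, np.array([300.0, 0.0, 0.0]),
                                   np.arange(t.size) / 50.0, 50.0)
        m2 = hand_metrics(hand, seg2, 50.0)
        assert m2["movement_time"] == pytest.approx(2 * m1["movement_time"], rel=1e-6)
        assert m2["peak_velocity"] == pytest.approx(m1["peak_velocity"] / 2, rel=1e-6)
        assert m2["path_length_ratio"] == pytest.approx(m1["path_length_ratio"], rel=1e-9)
        assert m2["n_velocity_peaks"] == m1["n_velocity_peaks"]


class TestDeltas:
    def test_net_not_path(self):
        markers = {name: np.zeros((100, 3)) for name in
                   ("hand", "elbow", "shoulder", "trunk")}
        markers["hand"][:, 0] = 100.0 * np.sin(np.linspace(0, np.pi, 100))  # out & back
        markers["elbow"][:, 0] = np.linspace(0, 300.0, 100)
        seg = ReachSegment(0.0, 0.5, 0.99, 0, 50, 99, 1.0, 0.0)
        d = displacement_deltas(markers, seg)
        assert d["delta_hand"] == pytest.approx(0.0, abs=1e-6)
        assert d["delta_elbow"] == pytest.approx(300.0)
        assert d["delta_trunk"] == 0.0


class TestPauPanu:
    @pytest.mark.parametrize("dh,dt,expected", [(400, 0, 100.0), (400, 400, 0.0),
                                                (400, 100, 75.0)])
    def test_pau_formula(self, dh, dt, expected):
        assert compute_pau(dh, dt) == pytest.approx(expected)

    def test_pau_undefined_for_zero_hand(self):
        with pytest.raises(KinematicsError, match="PAU undefined"):
            compute_pau(0.0, 10.0)

    @pytest.mark.parametrize("pr,ps,val,flag", [(80, 80, 0, False),
                                                (90, 70, 20, True),
                                                (70, 68, 2, False)])
    def test_panu_and_nonuse_flag(self, pr, ps, val, flag):
        panu, fired = compute_panu(pr, ps)
        assert panu == pytest.approx(val)
        assert fired is flag

    def test_pau_strictly_decreases_with_trunk_gain(self):
        cfg = SyntheticConfig(reaches_per_condition=1, trunk_gain_jitter_sd=0.0)
        paus = [simulate_truth_trial(cfg, "s", "spontaneous", trunk_gain=g).pau
                for g in (0.0, 0.1, 0.2, 0.3)]
        assert all(a > b for a, b in zip(paus, paus[1:]))
        assert paus[0] == pytest.approx(100.0)


class TestSummarize:
    def test_angles_invariant_under_global_rigid_motion(self):
        cfg = SyntheticConfig(reaches_per_condition=1, trunk_gain_jitter_sd=0.0)
        rec = simulate_truth_trial(cfg, "s", "spontaneous", trunk_gain=0.2).recording
        t = np.arange(rec.n_samples) / 100.0
        seg = detect_reach_bounds(rec.markers["hand"], rec.target, rec.times,
                                  rec.sample_rate)
        base = summarize_reach(rec, seg)
        R = Rotation.from_euler("xyz", [15, -25, 40], degrees=True).as_matrix()
        shift = np.array([300.0, -100.0, 50.0])
        moved = rec.with_markers(
            {k: v @ R.T + shift for k, v in rec.markers.items()},
            target=R @ rec.target + shift,
        )
        seg2 = detect_reach_bounds(moved.markers["hand"], moved.target,
                                   moved.times, moved.sample_rate)
        out = summarize_reach(moved, seg2)
        for name in ("elbow_extension", "shoulder_abduction", "shoulder_flexion"):
            assert getattr(out, name) == pytest.approx(getattr(base, name), abs=1e-6)
        # lab-frame trunk angles are defined w.r.t. gravity and the lab axes,
        # so only the rigid-motion-free metrics must match here
        for name in ("path_length_ratio", "peak_velocity", "delta_hand", "delta_trunk"):
            assert getattr(out, name) == pytest.approx(getattr(base, name), rel=1e-6)

    def test_deterministic(self, rng):
        cfg = SyntheticConfig(reaches_per_condition=1, trunk_gain_jitter_sd=0.0)
        rec = simulate_truth_trial(cfg, "s", "spontaneous", trunk_gain=0.2).recording
        seg = detect_reach_bounds(rec.markers["hand"], rec.target, rec.times,
                                  rec.sample_rate)
        a = summarize_reach(rec, seg)
        b = summarize_reach(rec, seg)
        assert a == b
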