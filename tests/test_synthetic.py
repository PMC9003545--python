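"""Synthetic-data generator: ground truth, sensor models, reproducibility."""

import numpy as np
import pytest

from reachval.preprocessing import band_power_fraction
from reachval.synthetic import (
    SyntheticConfig,
    apply_sensor_model,
    frame_transform,
    minimum_jerk_trajectory,
    simulate_dataset,
    simulate_truth_trial,
)
from reachval.trajectory_io import resample_to


class TestMinimumJerk:
    def test_midpoint_symmetry(self):
        p0, p1 = np.zeros(3), np.array([300.0, 0, 0])
        t, pos = minimum_jerk_trajectory(p0, p1, 1.0, 100.0)
        mid = pos[np.argmin(np.abs(t - 0.5))]
        np.testing.assert_allclose(mid, (p0 + p1) / 2, atol=1e-9)

    def test_endpoint_speeds_vanish(self):
        t, pos = minimum_jerk_trajectory(np.zeros(3), np.array([300.0, 0, 0]),
                                         1.0, 1000.0)
        spd = np.linalg.norm(np.gradient(pos, 1e-3, axis=0), axis=1)
        assert spd[0] < 1.0 and spd[-1] < 1.0

    def test_peak_speed_at_midmovement(self):
        D, T = 300.0, 1.0
        t, pos = minimum_jerk_trajectory(np.zeros(3), np.array([D, 0, 0]), T, 1000.0)
        spd = np.linalg.norm(np.gradient(pos, 1e-3, axis=0), axis=1)
        assert spd.max() == pytest.approx(15 * D / (8 * T), rel=1e-4)
        assert t[np.argmax(spd)] == pytest.approx(T / 2, abs=2e-3)


class TestTruthTrial:
    def test_zero_gain_is_pure_arm_reach(self):
        cfg = SyntheticConfig(trunk_gain_jitter_sd=0.0)
        tt = simulate_truth_trial(cfg, "s", "spontaneous", trunk_gain=0.0)
        assert tt.pau == pytest.approx(100.0)
        assert tt.reaches[0].delta_trunk == 0.0

    def test_quarter_gain_geometry(self):
        cfg = SyntheticConfig(reach_distance=300.0, trunk_gain_jitter_sd=0.0)
        tt = simulate_truth_trial(cfg, "s", "spontaneous", trunk_gain=0.25)
        assert tt.reaches[0].delta_trunk == pytest.approx(75.0)
        assert tt.pau == pytest.approx(75.0)

    def test_condition_gains_give_constructed_panu(self):
        cfg = SyntheticConfig(trunk_gain_spontaneous=0.25,
                              trunk_gain_restrained=0.05,
                              trunk_gain_jitter_sd=0.0)
        sp = simulate_truth_trial(cfg, "s", "spontaneous")
        re = simulate_truth_trial(cfg, "s", "restrained")
        assert re.pau - sp.pau == pytest.approx(20.0)

    def test_hand_ends_at_target_each_reach(self):
        cfg = SyntheticConfig(trunk_gain_jitter_sd=0.0)
        tt = simulate_truth_trial(cfg, "s", "spontaneous")
        rec = tt.recording
        d = np.linalg.norm(rec.markers["hand"] - rec.target, axis=1)
        assert d.min() == pytest.approx(0.0, abs=1e-9)
        assert d[0] == pytest.approx(cfg.reach_distance, rel=1e-9)

    def test_noiseless_trajectories_meet_spectral_criterion(self):
        cfg = SyntheticConfig(trunk_gain_jitter_sd=0.0,
                              submovement_prob=0.0, path_bow_max=0.0)
        rec = simulate_truth_trial(cfg, "s", "spontaneous").recording
        for axis in (0, 2):  # axes carrying hand motion
            frac = band_power_fraction(rec.markers["hand"][:, axis],
                                       rec.sample_rate)
            assert frac >= 0.95


class TestSensorModel:
    cfg = SyntheticConfig(trunk_gain_jitter_sd=0.0)

    def test_degenerate_sensor_equals_resampled_truth(self):
        cfg = SyntheticConfig(gold_noise_sd=0.0, markerless_noise_sd=0.0,
                              artifact_rate=0.0, frame_rotation=0.0,
                              frame_translation=(0.0, 0.0, 0.0),
                              trunk_gain_jitter_sd=0.0)
        truth = simulate_truth_trial(cfg, "s", "spontaneous").recording
        rng = np.random.default_rng(0)
        ml = apply_sensor_model(truth, "markerless", cfg, rng)
        assert ml.sample_rate == pytest.approx(30.0, rel=0.01)
        ref = resample_to(truth, ml.times)
        for name in truth.markers:
            np.testing.assert_allclose(ml.markers[name], ref.markers[name],
                                       atol=1e-9)

    def test_fixed_seed_reproducible(self):
        truth = simulate_truth_trial(self.cfg, "s", "spontaneous").recording
        a = apply_sensor_model(truth, "markerless", self.cfg,
                               np.random.default_rng(42))
        b = apply_sensor_model(truth, "markerless", self.cfg,
                               np.random.default_rng(42))
        for name in a.markers:
            np.testing.assert_array_equal(a.markers[name], b.markers[name])

    def test_markerless_frame_is_oblique(self):
        truth = simulate_truth_trial(self.cfg, "s", "spontaneous").recording
        ml = apply_sensor_model(truth, "markerless", self.cfg,
                                np.random.default_rng(1))
        # mapping back through the device-to-lab transform recovers truth frame
        back = frame_transform(self.cfg).apply_points(ml.markers["hip_left"])
        resid = np.linalg.norm(
            back - resample_to(truth, ml.times).markers["hip_left"], axis=1)
        assert np.median(resid) < 15.0  # noise only, no frame offset left
        raw_resid = np.linalg.norm(
            ml.markers["hip_left"] - resample_to(truth, ml.times).markers["hip_left"],
            axis=1)
        assert np.median(raw_resid) > 50.0  # frame offset dominates

    def test_artifacts_inflate_velocity_peak_count(self):
        """Armrest-capture artifacts add spurious speed peaks on the
        markerless stream for the same trial, in at least 80% of trials."""
        from reachval.pipeline import process_trial_pair, PipelineOptions

        cfg = SyntheticConfig(n_subjects=1, trunk_gain_jitter_sd=0.0)
        wins = 0
        total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            truth = simulate_truth_trial(cfg, "s", "spontaneous",
                                         rng=np.random.default_rng(1000 + seed))
            gold = apply_sensor_model(truth.recording, "gold", cfg, rng)
            ml = apply_sensor_model(truth.recording, "markerless", cfg, rng)
            res = process_trial_pair(gold, ml, PipelineOptions())
            sg, sm = res.summaries["gold"], res.summaries["markerless"]
            if not sg or not sm:
                continue
            total += 1
            if np.mean([s.n_velocity_peaks for s in sm]) >= np.mean(
                    [s.n_velocity_peaks for s in sg]):
                wins += 1
        assert total >= 45
        assert wins / total >= 0.8


class TestDataset:
    def test_counts(self):
        cfg = SyntheticConfig(n_subjects=2, seed=9)
        ds = simulate_dataset(cfg)
        assert len(ds.pairs) == 4  # 2 subjects x 2 conditions
        assert len(ds.manifest) == 20  # x 5 reaches
        sensors = {p.gold.sensor for p in ds.pairs} | {p.markerless.sensor for p in ds.pairs}
        assert sensors == {"gold", "markerless"}

    def test_same_seed_identical_manifest(self, tmp_path):
        cfg = SyntheticConfig(n_subjects=2, seed=11)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        a.manifest.to_csv(tmp_path / "a.csv", index=False)
        b.manifest.to_csv(tmp_path / "b.csv", index=False)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_duration_heterogeneity_spans_configured_range(self):
        cfg = SyntheticConfig(n_subjects=30, seed=2)
        ds = simulate_dataset(cfg)
        durs = ds.manifest.groupby("subject_id")["reach_duration"].first()
        lo = cfg.reach_duration - cfg.reach_duration_jitter
        hi = cfg.reach_duration + cfg.reach_duration_jitter
        assert durs.min() >= lo and durs.max() <= hi
        assert durs.max() - durs.min() > 0.25  # spans most of the range

    def test_written_dataset_round_trips(self, tmp_path):
        from reachval.trajectory_io import read_trial

        cfg = SyntheticConfig(n_subjects=1, seed=3)
        ds = simulate_dataset(cfg)
        out = ds.write(tmp_path / "data")
        files = sorted((out / "recordings").glob("*.csv"))
        assert len(files) == 4
        rec = read_trial(files[0])
        orig = ds.pair(rec.subject_id, rec.condition)
        src = orig.gold if rec.sensor == "gold" else orig.markerless
        np.testing.assert_allclose(rec.markers["hand"], src.markers["hand"],
                                   atol=1e-9)

    def test_noise_degrades_peak_velocity_icc_monotonically(self):
        from reachval.pipeline import run_validation

        # artifacts off so the broadband-noise level is the only factor
        med = []
        for sd in (0.5, 3.0, 12.0):
            iccs = []
            for seed in (21, 22, 23):
                cfg = SyntheticConfig(n_subjects=6, seed=seed,
                                      markerless_noise_sd=sd,
                                      artifact_rate=0.0)
                res = run_validation(simulate_dataset(cfg))
                iccs.append(res.report.row("peak_velocity").icc)
            med.append(float(np.median(iccs)))
        assert med[0] > med[1] > med[2]
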