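"""Synthetic paired-sensor recordings of seated reaching with known ground truth.

The generator emulates the validation protocol: each subject performs 5
reach-and-return cycles toward a fixed target in two trunk-use conditions
(spontaneous vs restrained), recorded simultaneously by a near-noise-free
gold-standard system at 100 Hz and a markerless depth sensor at 30 Hz.

Hand paths follow the minimum-jerk model of point-to-point reaching, whose
movement time, peak speed (15 D / 8 T at mid-movement), time to peak,
path-length ratio and velocity-peak count are closed-form — every pipeline
stage therefore has an analytic oracle.  Trunk compensation is modelled as
a forward translation of the trunk marker and both shoulders by a
condition-dependent fraction (``trunk_gain``) of the hand displacement, so
the ground-truth proximal arm use is PAU = 100 (1 - gain) exactly.  The
elbow is placed by a two-segment arm model (inverse kinematics between the
moving shoulder and the hand).

The markerless sensor model reproduces the documented failure modes of
depth-camera skeleton tracking: an oblique mounting frame (rigid rotation
plus translation), a lower sampling rate, broadband position noise, and
transient "armrest confusion" artifacts in which the hand or elbow is
captured toward a fixed distractor point and released with exponential
recovery (elbow events twice as frequent, mimicking elbow occlusion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import RigidTransform
from .kinematics import (
    KinematicSummary,
    compute_pau,
    elbow_angle,
    shoulder_angles,
    trunk_angles,
)
from .trajectory_io import TrialRecording, resample_to, write_trial


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and sensor-model parameters of the generator.

    Defaults encode the emulated protocol: 5 reaches of 300 mm per
    condition, natural-pace durations around 1.1 s, trunk gains 0.25
    (spontaneous) vs 0.05 (restrained), a 100 Hz gold sensor with 0.2 mm
    noise and a 30 Hz markerless sensor with 3 mm noise, a 10 degree
    oblique mounting, and armrest-confusion artifacts of 60 mm with a
    0.1 s recovery at 0.5 events/s on the hand (double on the elbow).
    """

    n_subjects: int = 10
    reaches_per_condition: int = 5
    reach_distance: float = 300.0  # mm
    reach_duration: float = 1.1  # s, per-subject mean
    reach_duration_jitter: float = 0.2  # s, uniform half-width across subjects
    trunk_gain_spontaneous: float = 0.25
    trunk_gain_restrained: float = 0.05
    trunk_gain_jitter_sd: float = 0.04  # per subject x condition
    submovement_prob: float = 0.4  # chance a reach undershoots and corrects
    submovement_undershoot: tuple = (25.0, 50.0)  # mm, uniform range
    submovement_duration: float = 0.45  # s, corrective movement time
    path_bow_max: float = 35.0  # mm, per-subject lateral path curvature
    load_condition: bool = False  # x1.3 duration, x2 trunk gain
    gold_noise_sd: float = 0.2  # mm
    markerless_noise_sd: float = 3.0  # mm
    artifact_rate: float = 0.5  # hand events per second; elbow rate is double
    artifact_magnitude: float = 60.0  # mm
    artifact_decay: float = 0.1  # s
    frame_rotation: float = 10.0  # deg about the medio-lateral (Y) axis
    frame_translation: tuple = (200.0, 100.0, -150.0)  # mm
    gold_rate: float = 100.0  # Hz
    markerless_rate: float = 30.0  # Hz
    assessed_side: str = "right"
    hold_duration: float = 1.0  # s at the target
    rest_duration: float = 0.8  # s between cycles (and before the first)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gold_rate <= 0 or self.markerless_rate <= 0:
            raise SimulationError("sampling rates must be positive")
        for g in (self.trunk_gain_spontaneous, self.trunk_gain_restrained):
            if not 0.0 <= g < 1.0:
                raise SimulationError("trunk_gain must lie in [0, 1)")
        for sd in (self.gold_noise_sd, self.markerless_noise_sd,
                   self.trunk_gain_jitter_sd):
            if sd < 0:
                raise SimulationError("noise SDs must be non-negative")

    def trunk_gain(self, condition: str) -> float:
        g = (self.trunk_gain_spontaneous if condition == "spontaneous"
             else self.trunk_gain_restrained)
        if self.load_condition:
            g = min(2.0 * g, 0.9)
        return g

    def duration(self) -> float:
        return self.reach_duration * (1.3 if self.load_condition else 1.0)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        d = json.loads(Path(path).read_text())
        d["frame_translation"] = tuple(d.get("frame_translation", (0, 0, 0)))
        return cls(**d)


# ----------------------------------------------------------------------
# body geometry (mm, lab frame: +X anterior, +Y left, +Z up, mid-hip origin)
# ----------------------------------------------------------------------

_UPPER_ARM = 300.0
_FOREARM = 380.0


def _static_posture(side: str) -> dict[str, np.ndarray]:
    s = 1.0 if side == "left" else -1.0  # y sign of the assessed side
    return {
        "hip_left": np.array([0.0, 110.0, 0.0]),
        "hip_right": np.array([0.0, -110.0, 0.0]),
        "trunk": np.array([20.0, 0.0, 450.0]),
        "shoulder": np.array([0.0, s * 190.0, 430.0]),
        "shoulder_contra": np.array([0.0, -s * 190.0, 430.0]),
        "hand": np.array([250.0, s * 190.0, 60.0]),
    }


def _reach_direction(side: str) -> np.ndarray:
    s = 1.0 if side == "left" else -1.0
    u = np.array([290.0, -s * 30.0, 80.0])  # forward, toward midline, upward
    return u / np.linalg.norm(u)


def _elbow_ik(shoulder: np.ndarray, hand: np.ndarray, side: str) -> np.ndarray:
    """Two-segment arm inverse kinematics; elbow biased down and outward."""
    shoulder = np.atleast_2d(shoulder)
    hand = np.atleast_2d(hand)
    w = hand - shoulder
    d = np.linalg.norm(w, axis=1)
    if np.any(d >= _UPPER_ARM + _FOREARM - 1e-9):
        raise SimulationError("unreachable target: arm fully extended")
    if np.any(d <= abs(_UPPER_ARM - _FOREARM) + 1e-9):
        raise SimulationError("unreachable target: hand too close to shoulder")
    a = (_UPPER_ARM**2 - _FOREARM**2 + d**2) / (2.0 * d)
    h = np.sqrt(np.maximum(_UPPER_ARM**2 - a**2, 0.0))
    u = w / d[:, None]
    s = 1.0 if side == "left" else -1.0
    ref = np.array([0.0, s * 0.5, -1.0])  # outward + down bias
    perp = ref - np.sum(ref * u, axis=1)[:, None] * u
    pn = np.linalg.norm(perp, axis=1)
    if np.any(pn < 1e-9):
        raise SimulationError("degenerate arm configuration")
    perp = perp / pn[:, None]
    return shoulder + a[:, None] * u + h[:, None] * perp


def minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def minimum_jerk_trajectory(
    p0: np.ndarray, p1: np.ndarray, T: float, sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk point-to-point path from ``p0`` to ``p1`` over ``T`` seconds.

    Returns (times, positions).  Velocity and acceleration vanish at both
    ends; peak speed is 15 ||p1 - p0|| / (8 T) at mid-movement.
    """
    if T <= 0:
        raise SimulationError("movement duration must be positive")
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    times = np.arange(0.0, T + 0.5 / sample_rate, 1.0 / sample_rate)
    prof = minimum_jerk_profile(times / T)
    return times, p0 + prof[:, None] * (p1 - p0)


@dataclass(frozen=True)
class ReachParams:
    """Per-reach trajectory parameters.

    ``undershoot`` > 0 makes the primary movement stop short of the target
    by that amount; a corrective minimum-jerk submovement (duration
    ``correction_T``) covering the remainder starts at ``onset_frac`` of
    the primary movement, overlapping its deceleration — the standard
    overlapping-submovement model of corrective reaching.  It adds a
    second velocity peak, the smoothness signature of less efficient
    reaching.  ``bow`` is the lateral sagitta of the hand path (mm): a
    curved path has a path-length ratio above 1.
    """

    T: float  # primary movement time, s
    undershoot: float = 0.0  # mm
    correction_T: float = 0.45  # s
    onset_frac: float = 0.95  # corrective submovement starts at this fraction of T
    bow: float = 0.0  # mm

    @property
    def total_T(self) -> float:
        if self.undershoot > 0:
            return max(self.T, self.onset_frac * self.T + self.correction_T)
        return self.T


def _lateral_unit(u: np.ndarray) -> np.ndarray:
    n = np.cross(u, np.array([0.0, 0.0, 1.0]))
    return n / np.linalg.norm(n)


def _curve_point(x: np.ndarray, start: np.ndarray, u: np.ndarray,
                 D: float, bow: float) -> np.ndarray:
    """Hand path: straight line start -> start + D u, bowed laterally by ``bow``."""
    x = np.asarray(x, dtype=float)
    lat = bow * np.sin(np.pi * np.clip(x, 0.0, D) / D)
    return start + x[:, None] * u + lat[:, None] * _lateral_unit(u)


def _forward_progress(t: np.ndarray, p: ReachParams, D: float) -> np.ndarray:
    """Progress x(t) along the path during one forward reach (t from 0)."""
    if p.undershoot > 0:
        t_on = p.onset_frac * p.T
        x = (D - p.undershoot) * minimum_jerk_profile(t / p.T)
        x = x + p.undershoot * minimum_jerk_profile((t - t_on) / p.correction_T)
    else:
        x = D * minimum_jerk_profile(t / p.T)
    return np.clip(x, 0.0, D)


_TRUTH_DT = 5e-4  # s, dense grid for the generator's ground-truth evaluation


def _reach_ground_truth(p: ReachParams, D: float,
                        prominence: float = 0.05) -> dict:
    """Spatio-temporal ground truth of one reach from the exact curve.

    Evaluated on a dense (2 kHz) grid of the closed-form path, independent
    of any measurement-pipeline code path (no filtering, no segmentation).
    """
    t = np.arange(0.0, p.total_T + _TRUTH_DT / 2, _TRUTH_DT)
    x = _forward_progress(t, p, D)
    pos = _curve_point(x, np.zeros(3), np.array([1.0, 0.0, 0.0]), D, p.bow)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path = float(steps.sum())
    spd = np.linalg.norm(np.gradient(pos, _TRUTH_DT, axis=0), axis=1)
    peak = float(spd.max())
    from scipy.signal import find_peaks

    pk, _ = find_peaks(spd, prominence=prominence * peak)
    return {
        "movement_time": p.total_T,
        "path_length_ratio": path / D,
        "time_to_peak_velocity": float(t[int(np.argmax(spd))]),
        "n_velocity_peaks": max(int(pk.size), 1),
        "peak_velocity": peak,
        "mean_velocity": path / p.total_T,
    }


@dataclass(frozen=True)
class TruthTrial:
    """Noiseless recording plus its analytic per-reach ground truth."""

    recording: TrialRecording
    reaches: list  # KinematicSummary per reach
    pau: float
    trunk_gain: float
    reach_duration: float


def _draw_reach_params(cfg: SyntheticConfig, T: float, bow: float,
                       rng: np.random.Generator | None) -> list:
    """Per-reach parameters: smooth and corrective reaches take the same time.

    A corrective reach packs a fast primary movement (duration ``T``) plus
    an overlapped correction; a smooth reach covers the distance in one
    slower movement of the same total duration (speed-accuracy tradeoff),
    so movement time and smoothness vary independently across reaches.
    """
    draw_subs = rng is not None and cfg.submovement_prob > 0
    p0 = ReachParams(T=T, undershoot=1.0, correction_T=cfg.submovement_duration)
    total = p0.total_T if draw_subs else T
    params = []
    for _ in range(cfg.reaches_per_condition):
        if draw_subs and rng.uniform() < cfg.submovement_prob:
            params.append(ReachParams(T=T, undershoot=float(rng.uniform(*cfg.submovement_undershoot)),
                                      correction_T=cfg.submovement_duration, bow=bow))
        else:
            params.append(ReachParams(T=total, undershoot=0.0, bow=bow))
    return params


def simulate_truth_trial(
    cfg: SyntheticConfig,
    subject_id: str,
    condition: str,
    reach_duration: float | None = None,
    trunk_gain: float | None = None,
    reach_params: list | None = None,
    rng: np.random.Generator | None = None,
) -> TruthTrial:
    """Noise-free trial: reach-return cycles with trunk compensation.

    The hand travels ``reach_distance`` along a (possibly bowed) path with
    a minimum-jerk progress profile, optionally undershooting and
    correcting (see :class:`ReachParams`); trunk marker and shoulders
    translate forward by ``trunk_gain`` x the hand progress; the elbow
    follows from the arm model.  Ground-truth per-reach summaries are
    evaluated from the closed-form trajectory and endpoint geometry,
    independent of the measurement pipeline.

    Per-reach variability (undershoots) is drawn from ``rng`` when
    ``reach_params`` is not given explicitly; with neither, every reach is
    a smooth straight-path movement.
    """
    side = cfg.assessed_side
    T = reach_duration if reach_duration is not None else cfg.duration()
    gain = trunk_gain if trunk_gain is not None else cfg.trunk_gain(condition)
    D = cfg.reach_distance
    posture = _static_posture(side)
    u = _reach_direction(side)
    target = posture["hand"] + D * u
    if reach_params is None:
        bow = float(rng.uniform(0.0, cfg.path_bow_max)) if rng is not None else 0.0
        reach_params = _draw_reach_params(cfg, T, bow, rng)

    total = cfg.rest_duration + sum(
        p.total_T + cfg.hold_duration + p.T + cfg.rest_duration for p in reach_params
    )
    times = np.arange(0.0, total, 1.0 / cfg.gold_rate)
    x = np.zeros_like(times)  # progress along the path toward the target
    t_cursor = cfg.rest_duration
    for p in reach_params:
        fwd = (times >= t_cursor) & (times < t_cursor + p.total_T)
        x[fwd] = _forward_progress(times[fwd] - t_cursor, p, D)
        t_cursor += p.total_T
        hold = (times >= t_cursor) & (times < t_cursor + cfg.hold_duration)
        x[hold] = D
        t_cursor += cfg.hold_duration
        back = (times >= t_cursor) & (times < t_cursor + p.T)
        x[back] = D * (1.0 - minimum_jerk_profile((times[back] - t_cursor) / p.T))
        t_cursor += p.T + cfg.rest_duration

    shift = gain * x  # forward translation of the trunk girdle
    markers: dict[str, np.ndarray] = {}
    for name in ("hip_left", "hip_right"):
        markers[name] = np.tile(posture[name], (times.size, 1))
    for name in ("trunk", "shoulder", "shoulder_contra"):
        markers[name] = np.tile(posture[name], (times.size, 1))
        markers[name][:, 0] += shift
    bow0 = reach_params[0].bow if reach_params else 0.0
    markers["hand"] = _curve_point(x, posture["hand"], u, D, bow0)
    markers["elbow"] = _elbow_ik(markers["shoulder"], markers["hand"], side)

    rec = TrialRecording(
        subject_id=subject_id,
        sensor="gold",
        condition=condition,
        assessed_side=side,
        times=times,
        markers=markers,
        target=target,
        meta={"truth": "noiseless"},
    )

    angles = _endpoint_angle_truth(posture, u, D, gain, side)
    delta_elbow = angles.pop("_de")
    reaches = [
        KinematicSummary(
            **angles,
            **_reach_ground_truth(p, D),
            delta_trunk=gain * D,
            delta_shoulder=gain * D,
            delta_elbow=delta_elbow,
            delta_hand=D,
        )
        for p in reach_params
    ]
    return TruthTrial(
        recording=rec,
        reaches=reaches,
        pau=compute_pau(D, gain * D),
        trunk_gain=gain,
        reach_duration=T,
    )


def _endpoint_angle_truth(
    posture: dict, u: np.ndarray, D: float, gain: float, side: str
) -> dict:
    """Geometric ground truth of the retained angles and the elbow delta."""
    start = {k: v.copy() for k, v in posture.items()}
    end = {k: v.copy() for k, v in posture.items()}
    for name in ("trunk", "shoulder", "shoulder_contra"):
        end[name][0] += gain * D
    end["hand"] = start["hand"] + D * u
    for cfgd in (start, end):
        cfgd["elbow"] = _elbow_ik(cfgd["shoulder"], cfgd["hand"], side)[0]

    def pair(name):
        return np.vstack([start[name], end[name]])

    elbow = elbow_angle(pair("shoulder"), pair("elbow"), pair("hand"))
    if side == "right":
        sh_r, sh_l = pair("shoulder"), pair("shoulder_contra")
    else:
        sh_l, sh_r = pair("shoulder"), pair("shoulder_contra")
    tflex, trot = trunk_angles(pair("trunk"), pair("hip_left"), pair("hip_right"),
                               sh_l, sh_r, assessed_side=side)
    sflex, sabd = shoulder_angles(pair("shoulder"), pair("elbow"), pair("trunk"),
                                  pair("hip_left"), pair("hip_right"),
                                  assessed_side=side)
    return {
        "elbow_extension": float(elbow[1] - elbow[0]),
        "shoulder_abduction": float(sabd[1] - sabd[0]),
        "shoulder_flexion": float(sflex[1] - sflex[0]),
        "trunk_anterior_flexion": float(tflex[1] - tflex[0]),
        "trunk_rotation": float(trot[1] - trot[0]),
        "_de": float(np.linalg.norm(end["elbow"] - start["elbow"])),
    }


# ----------------------------------------------------------------------
# sensor models
# ----------------------------------------------------------------------

def frame_transform(cfg: SyntheticConfig) -> RigidTransform:
    """Device-to-lab rigid transform of the obliquely mounted markerless sensor."""
    ang = np.radians(cfg.frame_rotation)
    c, s = np.cos(ang), np.sin(ang)
    rot_y = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return RigidTransform(rot_y, np.asarray(cfg.frame_translation, float))


def _armrest_point(side: str) -> np.ndarray:
    # back part of the armrest, behind and below the resting hand
    start = _static_posture(side)["hand"]
    return start + np.array([-150.0, 0.0, -20.0])


def apply_sensor_model(
    truth: TrialRecording,
    sensor: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> TrialRecording:
    """Turn a noiseless trial into one sensor's measurement of it.

    gold: resample to ``gold_rate``, add white Gaussian position noise.
    markerless: resample to ``markerless_rate``, inject armrest-capture
    artifacts on hand and elbow, add white noise, then express everything
    in the sensor's own oblique frame (the inverse of
    :func:`frame_transform`).
    """
    rate = cfg.gold_rate if sensor == "gold" else cfg.markerless_rate
    grid = np.arange(truth.times[0], truth.times[-1] + 1e-12, 1.0 / rate)
    grid = grid[grid <= truth.times[-1]]
    rec = resample_to(truth, grid)
    markers = {k: v.copy() for k, v in rec.markers.items()}
    target = rec.target.copy()

    if sensor == "gold":
        sd = cfg.gold_noise_sd
        if sd > 0:
            for name in markers:
                markers[name] = markers[name] + rng.normal(0.0, sd, markers[name].shape)
        return rec.with_markers(markers, sensor="gold")

    # -- markerless --
    duration = float(grid[-1] - grid[0])
    distractor = _armrest_point(truth.assessed_side)
    for name, rate_mult in (("hand", 1.0), ("elbow", 2.0)):
        lam = cfg.artifact_rate * rate_mult * duration
        n_events = rng.poisson(lam) if lam > 0 else 0
        event_times = np.sort(rng.uniform(grid[0], grid[-1], n_events))
        pos = markers[name]
        for te in event_times:
            i = int(np.searchsorted(grid, te))
            if i >= grid.size:
                continue
            direction = distractor - pos[i]
            nd = np.linalg.norm(direction)
            if nd < 1e-9:
                continue
            direction = direction / nd
            decay = np.exp(-(grid[i:] - te) / cfg.artifact_decay)
            pos[i:] = pos[i:] + cfg.artifact_magnitude * decay[:, None] * direction
        markers[name] = pos
    sd = cfg.markerless_noise_sd
    if sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(0.0, sd, markers[name].shape)
    # express in the device's oblique frame
    to_device = frame_transform(cfg).inverse()
    markers = {name: to_device.apply_points(pos) for name, pos in markers.items()}
    target = to_device.apply_points(target)
    return rec.with_markers(markers, sensor="markerless", target=target)


# ----------------------------------------------------------------------
# full dataset
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TrialPair:
    subject_id: str
    condition: str
    gold: TrialRecording
    markerless: TrialRecording
    truth: TruthTrial


@dataclass(frozen=True)
class SyntheticDataset:
    config: SyntheticConfig
    pairs: list
    manifest: pd.DataFrame

    def pair(self, subject_id: str, condition: str) -> TrialPair:
        for p in self.pairs:
            if p.subject_id == subject_id and p.condition == condition:
                return p
        raise KeyError((subject_id, condition))

    def write(self, out_dir: str | Path) -> Path:
        """Write all recordings (tidy CSV) plus the ground-truth manifest."""
        out_dir = Path(out_dir)
        rec_dir = out_dir / "recordings"
        rec_dir.mkdir(parents=True, exist_ok=True)
        for p in self.pairs:
            stem = f"{p.subject_id}_{p.condition}"
            write_trial(p.gold, rec_dir / f"{stem}_gold.csv")
            write_trial(p.markerless, rec_dir / f"{stem}_markerless.csv")
        self.manifest.to_csv(out_dir / "manifest.csv", index=False)
        self.config.to_json(out_dir / "config.json")
        return out_dir


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Simulate the full study: n subjects x 2 conditions x 2 sensors.

    All randomness flows from ``cfg.seed`` through a splittable seed
    sequence, so per-trial noise streams are independent but the whole
    dataset is bit-reproducible.
    """
    root_ss = np.random.SeedSequence(cfg.seed)
    subj_ss = root_ss.spawn(cfg.n_subjects)
    pairs: list[TrialPair] = []
    manifest_rows = []
    for si in range(cfg.n_subjects):
        subject_id = f"S{si + 1:02d}"
        sub_rng = np.random.default_rng(subj_ss[si])
        T = cfg.duration() + sub_rng.uniform(-cfg.reach_duration_jitter,
                                             cfg.reach_duration_jitter)
        for condition in ("spontaneous", "restrained"):
            gain = cfg.trunk_gain(condition)
            if cfg.trunk_gain_jitter_sd > 0:
                gain = float(np.clip(
                    gain + sub_rng.normal(0.0, cfg.trunk_gain_jitter_sd), 0.0, 0.9))
            truth = simulate_truth_trial(cfg, subject_id, condition,
                                         reach_duration=T, trunk_gain=gain,
                                         rng=sub_rng)
            gold = apply_sensor_model(truth.recording, "gold", cfg,
                                      np.random.default_rng(sub_rng.integers(2**31)))
            markerless = apply_sensor_model(truth.recording, "markerless", cfg,
                                            np.random.default_rng(sub_rng.integers(2**31)))
            pairs.append(TrialPair(subject_id, condition, gold, markerless, truth))
            for ri, summary in enumerate(truth.reaches):
                manifest_rows.append(
                    {
                        "subject_id": subject_id,
                        "condition": condition,
                        "reach": ri + 1,
                        "trunk_gain": truth.trunk_gain,
                        "reach_duration": truth.reach_duration,
                        "pau": truth.pau,
                        **summary.to_dict(),
                    }
                )
    manifest = pd.DataFrame(manifest_rows)
    return SyntheticDataset(config=cfg, pairs=pairs, manifest=manifest)
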