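"""Spatial and temporal alignment of the markerless stream to the gold frame.

The markerless camera is mounted obliquely, so its coordinate frame differs
from the lab frame of the gold-standard system by an unknown rigid motion.
:func:`fit_rigid_transform` recovers that motion from corresponding point
pairs by the classic SVD least-squares solution (Arun/Kabsch), with the
reflection branch corrected so the result is always a proper rotation.

Temporal offset between the two streams is estimated from the hand-speed
profiles (:func:`estimate_lag`), the signal with the best signal-to-noise
ratio, by normalized cross-correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajectory_io import TrialRecording

#: markers used by default to build the rigid-fit correspondence set:
#: slow-moving and least artifact-prone.
CALIBRATION_MARKERS = ("shoulder", "shoulder_contra", "trunk", "hip_left", "hip_right")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t`` with its fit residual.

    ``rotation`` is 3x3 orthonormal with det +1; ``translation`` in mm;
    ``rms_residual`` is the root-mean-square point mismatch of the fit, mm.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise AlignmentError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise AlignmentError("rotation is a reflection (det -1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation, self.rms_residual)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rms_residual": float(self.rms_residual),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]),
                   float(d.get("rms_residual", 0.0)))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_rigid_transform(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping ``source_points`` onto ``target_points``.

    Minimises ``sum ||R s_i + t - p_i||^2`` over proper rotations R and
    translations t via the centroid-and-SVD construction.  If the
    unconstrained optimum is a reflection, the smallest singular direction
    is sign-flipped so a proper rotation is always returned.

    Requires at least 3 non-collinear correspondences.
    """
    S = np.asarray(source_points, dtype=float)
    P = np.asarray(target_points, dtype=float)
    if S.ndim != 2 or S.shape[1] != 3 or S.shape != P.shape:
        raise AlignmentError("expected matching N x 3 point arrays")
    n = S.shape[0]
    if n < 3:
        raise AlignmentError("degenerate correspondence set: need >= 3 point pairs")
    cs = S.mean(axis=0)
    cp = P.mean(axis=0)
    S0 = S - cs
    P0 = P - cp
    # collinearity check: second singular value of the centered source cloud
    sv = np.linalg.svd(S0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise AlignmentError("degenerate correspondence set: source points collinear")
    H = S0.T @ P0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cp - R @ cs
    resid = P - (S @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(R, t, rms)


def apply_transform(tf: RigidTransform, rec: TrialRecording) -> TrialRecording:
    """Map every marker position (and the target) through ``tf``; metadata kept."""
    new_markers = {name: tf.apply_points(pos) for name, pos in rec.markers.items()}
    return rec.with_markers(new_markers, target=tf.apply_points(rec.target))


def estimate_lag(
    gold_times: np.ndarray,
    gold_speed: np.ndarray,
    test_times: np.ndarray,
    test_speed: np.ndarray,
    max_lag_s: float = 1.0,
    min_correlation: float = 0.3,
) -> float:
    """Temporal lag of the test stream relative to the gold stream, seconds.

    The test speed series is interpolated onto the gold grid and the lag
    maximizing the normalized cross-correlation within ``+-max_lag_s`` is
    returned.  A positive lag means the test stream runs late: subtract it
    from the test timestamps to synchronize.

    Raises :class:`AlignmentError` when either series carries no movement
    signal (zero variance, or best correlation below ``min_correlation``).
    """
    gold_times = np.asarray(gold_times, float)
    gold_speed = np.asarray(gold_speed, float)
    test_speed_g = np.interp(np.asarray(gold_times), np.asarray(test_times, float),
                             np.asarray(test_speed, float))
    a = gold_speed - gold_speed.mean()
    b = test_speed_g - test_speed_g.mean()
    sa, sb = np.linalg.norm(a), np.linalg.norm(b)
    if sa == 0.0 or sb == 0.0:
        raise AlignmentError("no movement to align: flat speed series")
    a /= sa
    b /= sb
    dt = float(np.median(np.diff(gold_times)))
    max_shift = max(1, int(round(max_lag_s / dt)))
    full = np.correlate(a, b, mode="full")  # index n-1 <-> zero shift
    n = a.size
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= max_shift
    full = full[keep]
    lags = lags[keep]
    best = int(np.argmax(full))
    if full[best] < min_correlation:
        raise AlignmentError("no movement to align: speed series uncorrelated")
    # correlate(a, b)[k] pairs a[i] with b[i - lag]; positive lag means the
    # test signal is delayed relative to gold.
    return -float(lags[best]) * dt


def calibration_points(
    gold: TrialRecording,
    markerless: TrialRecording,
    markers: tuple[str, ...] = CALIBRATION_MARKERS,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled time-aligned correspondence set for the rigid fit.

    The markerless stream is linearly interpolated onto the gold time grid
    (restricted to the common span) and the samples of the slow-moving
    trunk-girdle markers are stacked.
    """
    t0 = max(gold.times[0], markerless.times[0])
    t1 = min(gold.times[-1], markerless.times[-1])
    keep = (gold.times >= t0) & (gold.times <= t1)
    src, dst = [], []
    for name in markers:
        g = gold.markers[name][keep]
        m = np.column_stack(
            [
                np.interp(gold.times[keep], markerless.times, markerless.markers[name][:, ax])
                for ax in range(3)
            ]
        )
        src.append(m)
        dst.append(g)
    return np.vstack(src), np.vstack(dst)
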