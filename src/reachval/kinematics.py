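"""Per-reach kinematic variables and the proximal-arm-use scores.

This module computes the standard battery of seated-reaching variables:

* retained joint/trunk angles (value at movement end minus value at
  movement onset): elbow extension, shoulder flexion, shoulder abduction,
  trunk anterior flexion, trunk rotation;
* spatio-temporal efficiency: movement time, path length ratio (PLR),
  time to peak velocity, number of velocity peaks (NVP), peak and mean
  hand velocity;
* net marker displacements (trunk, shoulder, elbow, hand);
* Proximal Arm Use, PAU = 100 x (dHand - dTrunk) / dHand, the share of the
  hand displacement not contributed by the trunk; and Proximal Arm
  Non-Use, PANU = PAU(restrained) - PAU(spontaneous), with non-mandatory
  trunk compensation flagged when PANU exceeds 6.5%.

Anatomical angle constructions (projection planes, sign conventions) are
defined here once, package-wide: see the individual functions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np
from scipy.signal import find_peaks

from .preprocessing import differentiate
from .segmentation import ReachSegment
from .trajectory_io import TrialRecording

#: PANU above this value (percentage points) indicates non-mandatory
#: trunk compensation.
PANU_NONUSE_THRESHOLD = 6.5

#: velocity-peak prominence threshold, as a fraction of peak speed
DEFAULT_PEAK_PROMINENCE = 0.05


class KinematicsError(ValueError):
    pass


@dataclass(frozen=True)
class KinematicSummary:
    """The per-reach variable battery (angles deg, lengths mm, times s)."""

    elbow_extension: float
    shoulder_abduction: float
    shoulder_flexion: float
    trunk_anterior_flexion: float
    trunk_rotation: float
    movement_time: float
    path_length_ratio: float
    time_to_peak_velocity: float
    n_velocity_peaks: int
    peak_velocity: float
    mean_velocity: float
    delta_trunk: float
    delta_shoulder: float
    delta_elbow: float
    delta_hand: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class ConditionSummary:
    """Across-reach mean of one condition's summaries, plus its PAU score."""

    condition: str
    n_reaches: int
    means: KinematicSummary
    pau: float


# ----------------------------------------------------------------------
# angles
# ----------------------------------------------------------------------

def retained_angle(angle_series: np.ndarray, i0: int, i_final: int) -> float:
    """Retained angle: anatomical angle at movement end minus at onset (deg)."""
    a = np.asarray(angle_series, dtype=float)
    return float(a[i_final] - a[i0])


def elbow_angle(shoulder: np.ndarray, elbow: np.ndarray, wrist: np.ndarray) -> np.ndarray:
    """Elbow angle (deg, 0-180): angle at the elbow between upper arm and forearm.

    180 deg is a fully extended arm.  Vectorized over (n, 3) series.
    """
    shoulder, elbow, wrist = (np.atleast_2d(np.asarray(p, float)) for p in (shoulder, elbow, wrist))
    u = shoulder - elbow
    v = wrist - elbow
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-9) or np.any(nv < 1e-9):
        raise KinematicsError("degenerate joint configuration: coincident points")
    cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def trunk_angles(
    trunk: np.ndarray,
    hip_left: np.ndarray,
    hip_right: np.ndarray,
    shoulder_left: np.ndarray,
    shoulder_right: np.ndarray,
    assessed_side: str = "right",
) -> tuple[np.ndarray, np.ndarray]:
    """Trunk anterior flexion and axial rotation series (deg).

    Anterior flexion: signed angle between the trunk axis (mid-hip to the
    manubrium marker) and lab vertical +Z, measured in the lab sagittal
    X-Z plane; positive = leaning forward (+X).

    Rotation: signed angle of the shoulder line projected on the
    transverse X-Y plane, relative to its orientation at the first sample;
    positive when the assessed-side shoulder advances (+X).
    """
    trunk = np.atleast_2d(np.asarray(trunk, float))
    mid_hip = (np.atleast_2d(np.asarray(hip_left, float)) +
               np.atleast_2d(np.asarray(hip_right, float))) / 2.0
    axis = trunk - mid_hip
    if np.any(np.linalg.norm(axis, axis=1) < 1e-9):
        raise KinematicsError("degenerate trunk axis")
    flexion = np.degrees(np.arctan2(axis[:, 0], axis[:, 2]))

    w = np.atleast_2d(np.asarray(shoulder_right, float)) - np.atleast_2d(
        np.asarray(shoulder_left, float)
    )
    w = w[:, :2]  # transverse-plane projection
    if np.any(np.linalg.norm(w, axis=1) < 1e-9):
        raise KinematicsError("degenerate shoulder line")
    w0 = w[0]
    cross = w0[0] * w[:, 1] - w0[1] * w[:, 0]
    dot = w @ w0
    rotation = np.degrees(np.arctan2(cross, dot))
    if assessed_side == "left":
        rotation = -rotation
    return flexion, rotation


def trunk_frame(
    trunk: np.ndarray, hip_left: np.ndarray, hip_right: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample orthonormal trunk frame (anterior, left-to-right, longitudinal).

    Longitudinal axis: mid-hip to the manubrium marker; medio-lateral axis:
    hip line (left to right) orthogonalized against it; anterior axis
    completes the right-handed triad.
    """
    trunk = np.atleast_2d(np.asarray(trunk, float))
    hl = np.atleast_2d(np.asarray(hip_left, float))
    hr = np.atleast_2d(np.asarray(hip_right, float))
    mid_hip = (hl + hr) / 2.0
    ell = trunk - mid_hip
    norms = np.linalg.norm(ell, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise KinematicsError("degenerate trunk axis")
    ell = ell / norms
    m = hr - hl
    m = m - np.sum(m * ell, axis=1, keepdims=True) * ell
    mnorm = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(mnorm < 1e-9):
        raise KinematicsError("degenerate trunk frame: hip line parallel to trunk axis")
    m = m / mnorm
    anterior = np.cross(ell, m)
    return anterior, m, ell


def shoulder_angles(
    shoulder: np.ndarray,
    elbow: np.ndarray,
    trunk: np.ndarray,
    hip_left: np.ndarray,
    hip_right: np.ndarray,
    assessed_side: str = "right",
) -> tuple[np.ndarray, np.ndarray]:
    """Shoulder flexion and abduction series (deg), in the trunk frame.

    The humerus vector (shoulder to elbow) is expressed in the per-sample
    trunk frame.  Flexion is the angle of its sagittal-plane projection
    from the downward longitudinal axis, positive forward; abduction the
    same construction in the frontal plane, positive away from the trunk.
    An arm hanging along the trunk scores 0 on both.
    """
    anterior, m, ell = trunk_frame(trunk, hip_left, hip_right)
    h = np.atleast_2d(np.asarray(elbow, float)) - np.atleast_2d(np.asarray(shoulder, float))
    if np.any(np.linalg.norm(h, axis=1) < 1e-9):
        raise KinematicsError("degenerate joint configuration: coincident points")
    h_ant = np.sum(h * anterior, axis=1)
    h_lat = np.sum(h * m, axis=1)
    if assessed_side == "left":
        h_lat = -h_lat
    # +0.0 avoids the negative-zero branch of atan2 for a horizontal humerus
    down = -np.sum(h * ell, axis=1) + 0.0
    flexion = np.degrees(np.arctan2(h_ant, down))
    abduction = np.degrees(np.arctan2(h_lat, down))
    return flexion, abduction


# ----------------------------------------------------------------------
# hand metrics and displacements
# ----------------------------------------------------------------------

def hand_metrics(
    hand: np.ndarray,
    segment: ReachSegment,
    sample_rate: float,
    peak_prominence: float = DEFAULT_PEAK_PROMINENCE,
) -> dict:
    """Spatio-temporal efficiency variables of one reach.

    Speed is the 3D Euclidean norm of the differentiated hand position.
    The path length ratio divides the travelled path by the straight-line
    start-to-end distance (1 for a perfectly straight reach).  Velocity
    peaks are local speed maxima with prominence at least
    ``peak_prominence`` x peak speed; a reach has at least one.
    """
    hand = np.asarray(hand, dtype=float)
    s = np.linalg.norm(differentiate(hand, sample_rate), axis=1)
    i0, i1 = segment.i0, segment.i_final
    seg_speed = s[i0 : i1 + 1]
    seg_pos = hand[i0 : i1 + 1]
    net = float(np.linalg.norm(seg_pos[-1] - seg_pos[0]))
    if net < 1e-9:
        raise KinematicsError("zero displacement, PLR undefined")
    path = float(np.sum(np.linalg.norm(np.diff(seg_pos, axis=0), axis=1)))
    peak = float(np.max(seg_speed))
    i_pk = int(np.argmax(seg_speed))
    peaks, _ = find_peaks(seg_speed, prominence=peak_prominence * peak)
    return {
        "movement_time": segment.movement_time,
        "path_length_ratio": path / net,
        "time_to_peak_velocity": i_pk / sample_rate,
        "n_velocity_peaks": max(int(peaks.size), 1),
        "peak_velocity": peak,
        "mean_velocity": float(np.mean(seg_speed)),
    }


def displacement_deltas(
    rec_markers: dict, segment: ReachSegment
) -> dict:
    """Net start-to-end displacement magnitude per marker (mm).

    Net, not path: a marker moving out and fully back scores 0.
    """
    out = {}
    for short, name in (
        ("delta_hand", "hand"),
        ("delta_elbow", "elbow"),
        ("delta_shoulder", "shoulder"),
        ("delta_trunk", "trunk"),
    ):
        p = np.asarray(rec_markers[name], dtype=float)
        out[short] = float(np.linalg.norm(p[segment.i_final] - p[segment.i0]))
    return out


# ----------------------------------------------------------------------
# proximal arm use / non-use
# ----------------------------------------------------------------------

def compute_pau(delta_hand: float, delta_trunk: float) -> float:
    """Proximal Arm Use (%): hand displacement share not owed to the trunk."""
    if delta_hand <= 0:
        raise KinematicsError("PAU undefined: zero hand displacement")
    return 100.0 * (delta_hand - delta_trunk) / delta_hand


def compute_panu(
    pau_restrained: float, pau_spontaneous: float,
    threshold: float = PANU_NONUSE_THRESHOLD,
) -> tuple[float, bool]:
    """Proximal Arm Non-Use (%) and the non-mandatory-compensation flag.

    PANU > threshold means the extra arm use available under trunk
    restraint is not exploited spontaneously: part of the trunk
    compensation is not mandatory for task success.
    """
    panu = pau_restrained - pau_spontaneous
    return panu, bool(panu > threshold)


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def summarize_reach(
    rec: TrialRecording,
    segment: ReachSegment,
    peak_prominence: float = DEFAULT_PEAK_PROMINENCE,
) -> KinematicSummary:
    """Compute the full variable battery for one segmented reach.

    ``rec`` should already be frame-aligned and filtered.  Deterministic:
    identical inputs give identical output.
    """
    side = rec.assessed_side
    if side == "right":
        sh_r, sh_l = rec.markers["shoulder"], rec.markers["shoulder_contra"]
    else:
        sh_l, sh_r = rec.markers["shoulder"], rec.markers["shoulder_contra"]

    elbow_series = elbow_angle(rec.markers["shoulder"], rec.markers["elbow"], rec.markers["hand"])
    flex_series, rot_series = trunk_angles(
        rec.markers["trunk"], rec.markers["hip_left"], rec.markers["hip_right"],
        sh_l, sh_r, assessed_side=side,
    )
    sflex_series, sabd_series = shoulder_angles(
        rec.markers["shoulder"], rec.markers["elbow"], rec.markers["trunk"],
        rec.markers["hip_left"], rec.markers["hip_right"], assessed_side=side,
    )
    i0, i1 = segment.i0, segment.i_final
    hm = hand_metrics(rec.markers["hand"], segment, rec.sample_rate, peak_prominence)
    deltas = displacement_deltas(rec.markers, segment)
    return KinematicSummary(
        elbow_extension=retained_angle(elbow_series, i0, i1),
        shoulder_abduction=retained_angle(sabd_series, i0, i1),
        shoulder_flexion=retained_angle(sflex_series, i0, i1),
        trunk_anterior_flexion=retained_angle(flex_series, i0, i1),
        trunk_rotation=retained_angle(rot_series, i0, i1),
        **hm,
        **deltas,
    )


def summarize_condition(
    condition: str, summaries: list[KinematicSummary]
) -> ConditionSummary:
    """Average the per-reach summaries of one condition and compute PAU.

    PAU is computed per reach and then averaged (averaging precedes the
    PANU subtraction).
    """
    if not summaries:
        raise KinematicsError("no reaches to summarize")
    means = KinematicSummary(
        **{
            name: float(np.mean([getattr(s, name) for s in summaries]))
            for name in KinematicSummary.field_names()
        }
    )
    pau = float(np.mean([compute_pau(s.delta_hand, s.delta_trunk) for s in summaries]))
    return ConditionSummary(condition=condition, n_reaches=len(summaries),
                            means=means, pau=pau)
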