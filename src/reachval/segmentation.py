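"""Reach detection in the one-dimensional task space.

The goal of a reaching movement is to reduce the hand-to-target Euclidean
distance, which collapses the 3D effector space into a 1D task space.
Movement onset ``t0`` is the moment task-space velocity (the negative
derivative of distance) becomes positive and stays positive up to its
maximum; movement end ``t_final`` is the moment the hand-to-target distance
reaches its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import find_peaks

from .preprocessing import differentiate


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class ReachSegment:
    """Onset / peak-velocity / end landmarks of one reach.

    Times in seconds on the source grid; ``i0``/``i_peak``/``i_final`` are
    the corresponding sample indices.  ``d0`` and ``d_final`` are the
    hand-to-target distances at onset and end (mm); ``truncated`` flags a
    peak velocity at a window edge.
    """

    t0: float
    t_peak: float
    t_final: float
    i0: int
    i_peak: int
    i_final: int
    d0: float
    d_final: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.t0 < self.t_peak <= self.t_final):
            raise SegmentationError(
                f"invalid segment ordering: t0={self.t0}, t_peak={self.t_peak}, "
                f"t_final={self.t_final}"
            )

    @property
    def movement_time(self) -> float:
        return self.t_final - self.t0

    def to_dict(self) -> dict:
        return asdict(self)


def task_space_distance(hand: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Hand-to-target Euclidean distance series, mm."""
    hand = np.asarray(hand, dtype=float)
    target = np.asarray(target, dtype=float).reshape(3)
    return np.linalg.norm(hand - target, axis=1)


def _first_min_within_band(d: np.ndarray, tol: float) -> int:
    """Earliest local minimizer of ``d`` whose value is within ``tol`` of min(d).

    On a reach-and-hold trial the hand settles at the target, so the
    distance series bottoms out into a near-flat band; a strict global
    argmin would land at an arbitrary point of that band (wherever noise
    or filter ringing happens to be smallest).  The earliest local
    minimizer inside the band is the moment the distance first "reached
    its minimum".  Falls back to the global argmin when no local minimizer
    qualifies (e.g. a monotone approach truncated by the window edge).
    """
    d_min = float(np.min(d))
    # non-strict on both sides so the entry sample of a flat minimum
    # plateau qualifies (the hand settling at the target)
    interior = np.flatnonzero((d[1:-1] <= d[:-2]) & (d[1:-1] <= d[2:])) + 1
    for i in interior:
        if d[i] <= d_min + tol:
            return int(i)
    return int(np.argmin(d))


def detect_reach_bounds(
    hand: np.ndarray,
    target: np.ndarray,
    times: np.ndarray,
    sample_rate: float,
    window: tuple[int, int] | None = None,
    end_tolerance: float = 0.01,
) -> ReachSegment:
    """Locate one reach inside ``window`` (index range, end exclusive).

    Algorithm: with d(t) the task-space distance and v(t) = -d'(t) the
    task-space velocity (positive while approaching), ``t_final`` is the
    earliest local minimizer of d within ``end_tolerance`` x (approach
    depth) of the global minimum (see :func:`_first_min_within_band`),
    ``t_peak`` the first maximizer of v before ``t_final``, and ``t0`` one
    sample after the last non-positive v at or before ``t_peak`` (window
    start if v is positive throughout).
    """
    times = np.asarray(times, dtype=float)
    lo, hi = window if window is not None else (0, times.size)
    if hi - lo < 3:
        raise SegmentationError("window too short to segment")
    d = task_space_distance(np.asarray(hand, float)[lo:hi], target)
    v = -differentiate(d, sample_rate)
    i_final = _first_min_within_band(d, end_tolerance * float(np.ptp(d)))
    if i_final == 0:
        raise SegmentationError("no movement toward target detected")
    v_pre = v[: i_final + 1]
    if np.max(v_pre) <= 0:
        raise SegmentationError("no movement toward target detected")
    i_peak = int(np.argmax(v_pre))
    truncated = i_peak in (0, hi - lo - 1)
    if i_peak == 0:
        raise SegmentationError("truncated movement: peak velocity at window start")
    nonpos = np.flatnonzero(v[: i_peak + 1] <= 0)
    i0 = int(nonpos[-1]) + 1 if nonpos.size else 0
    if i0 >= i_peak:
        i0 = i_peak - 1
    return ReachSegment(
        t0=float(times[lo + i0]),
        t_peak=float(times[lo + i_peak]),
        t_final=float(times[lo + i_final]),
        i0=lo + i0,
        i_peak=lo + i_peak,
        i_final=lo + i_final,
        d0=float(d[i0]),
        d_final=float(d[i_final]),
        truncated=truncated,
    )


def split_reaches(
    hand: np.ndarray,
    target: np.ndarray,
    sample_rate: float,
    min_gap: float = 0.5,
    proximity_fraction: float = 0.3,
) -> list[tuple[int, int]]:
    """Cut a multi-reach trial into windows, one approach per window.

    Window boundaries are local maxima of the hand-to-target distance (the
    rest plateaus between reach-return cycles) separated by at least
    ``min_gap`` seconds.  A window qualifies only if the hand gets closer
    to the target than ``proximity_fraction`` of the starting distance,
    which discards fidgeting around rest.  Returns (start, end)-exclusive
    index pairs; empty list when no reach is found.
    """
    d = task_space_distance(np.asarray(hand, float), target)
    n = d.size
    d_rest = d[0]
    span = d.max() - d.min()
    if span <= 0:
        return []
    peaks, _ = find_peaks(
        d,
        distance=max(1, int(round(min_gap * sample_rate))),
        prominence=0.2 * span,
    )
    bounds = [0, *peaks.tolist(), n]
    windows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < 3:
            continue
        if d[lo:hi].min() < proximity_fraction * d_rest:
            windows.append((lo, hi))
    return windows
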