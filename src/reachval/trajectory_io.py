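"""Data model and disk format for paired-sensor marker trajectory recordings.

A :class:`TrialRecording` holds the time-stamped 3D positions of a named
marker set captured by one sensor during one trial (one condition, one
assessed side).  Package-wide conventions:

* coordinates in **millimetres**, lab frame: +X anterior (toward the
  target), +Y to the participant's left, +Z vertical up;
* time in **seconds**, strictly increasing, uniformly sampled;
* required markers: ``hand``, ``elbow``, ``shoulder`` (assessed side),
  ``shoulder_contra``, ``trunk`` (manubrium), ``hip_left``, ``hip_right``.

Recordings are stored as tidy long CSV, one file per trial x sensor:
``#``-prefixed ``key=value`` metadata lines followed by a
``time_s,marker,x,y,z,unit`` table (unit ``mm`` or ``m``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

REQUIRED_MARKERS = (
    "hand",
    "elbow",
    "shoulder",
    "shoulder_contra",
    "trunk",
    "hip_left",
    "hip_right",
)

SENSORS = ("gold", "markerless")
CONDITIONS = ("spontaneous", "restrained")
SIDES = ("left", "right")

#: longest device dropout (s) repaired by linear interpolation
MAX_GAP_S = 0.2


class TrialValidationError(ValueError):
    """Raised when a recording violates the trial data contract."""


@dataclass
class TrialRecording:
    """One sensor's view of one trial.

    Parameters
    ----------
    subject_id : str
        Participant identifier.
    sensor : {"gold", "markerless"}
        Which capture system produced the data.
    condition : {"spontaneous", "restrained"}
        Trunk-use condition of the reaching protocol.
    assessed_side : {"left", "right"}
        Side of the reaching arm; the ``shoulder`` marker belongs to it.
    times : ndarray, shape (n,)
        Sample times in seconds, strictly increasing, uniform.
    markers : dict of str -> ndarray, shape (n, 3)
        Marker positions in mm.
    target : ndarray, shape (3,)
        Fixed target position in mm, same frame as the markers.
    """

    subject_id: str
    sensor: str
    condition: str
    assessed_side: str
    times: np.ndarray
    markers: dict[str, np.ndarray]
    target: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.target = np.asarray(self.target, dtype=float).reshape(3)
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def sample_rate(self) -> float | None:
        """Sampling rate in Hz; ``None`` for recordings with < 2 samples."""
        if self.times.size < 2:
            return None
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0

    def validate(self) -> None:
        if self.sensor not in SENSORS:
            raise TrialValidationError(f"unknown sensor {self.sensor!r}")
        if self.condition not in CONDITIONS:
            raise TrialValidationError(f"unknown condition {self.condition!r}")
        if self.assessed_side not in SIDES:
            raise TrialValidationError(f"unknown assessed_side {self.assessed_side!r}")
        if not self.markers:
            raise TrialValidationError("empty recording: no markers")
        missing = [m for m in REQUIRED_MARKERS if m not in self.markers]
        if missing:
            raise TrialValidationError(
                "incomplete marker set: " + ", ".join(missing)
            )
        n = self.times.size
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise TrialValidationError("time ordering: times must strictly increase")
            med = np.median(dt)
            if np.any(np.abs(dt - med) > 0.01 * med):
                raise TrialValidationError(
                    "time ordering: inter-sample interval not uniform within 1%"
                )
        for name, pos in self.markers.items():
            if pos.shape != (n, 3):
                raise TrialValidationError(
                    f"marker {name!r} has shape {pos.shape}, expected ({n}, 3)"
                )
            if not np.all(np.isfinite(pos)):
                raise TrialValidationError(f"non-finite positions in marker {name!r}")
        if not np.all(np.isfinite(self.target)):
            raise TrialValidationError("non-finite target position")

    # ------------------------------------------------------------------
    def with_markers(self, markers: Mapping[str, np.ndarray], **updates) -> "TrialRecording":
        """Copy of this recording with replaced marker arrays."""
        return replace(self, markers=dict(markers), **updates)

    def marker(self, name: str) -> np.ndarray:
        return self.markers[name]


# ----------------------------------------------------------------------
# tidy-CSV round trip
# ----------------------------------------------------------------------

def write_trial(rec: TrialRecording, path: str | Path) -> Path:
    """Write a recording to the tidy long-CSV dialect.

    One row per (time, marker); metadata as ``# key=value`` header lines.
    """
    if not rec.markers:  # pragma: no cover - guarded by validate()
        raise TrialValidationError("empty recording")
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# subject_id={rec.subject_id}\n")
    buf.write(f"# sensor={rec.sensor}\n")
    buf.write(f"# condition={rec.condition}\n")
    buf.write(f"# assessed_side={rec.assessed_side}\n")
    buf.write(f"# target_x={float(rec.target[0])!r}\n")
    buf.write(f"# target_y={float(rec.target[1])!r}\n")
    buf.write(f"# target_z={float(rec.target[2])!r}\n")
    frames = []
    for name, pos in rec.markers.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": rec.times,
                    "marker": name,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "z": pos[:, 2],
                    "unit": "mm",
                }
            )
        )
    table = pd.concat(frames, ignore_index=True).sort_values(
        ["time_s", "marker"], kind="stable"
    )
    table.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_trial(path: str | Path) -> TrialRecording:
    """Read a recording from the tidy long-CSV dialect.

    The ``unit`` column is honoured (``m`` converted to mm).  Raises
    :class:`TrialValidationError` on a missing required marker or
    non-monotone time vector.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                data_lines.append(line)
    table = pd.read_csv(io.StringIO("".join(data_lines)))
    for col in ("time_s", "marker", "x", "y", "z"):
        if col not in table.columns:
            raise TrialValidationError(f"missing column {col!r}")
    if "unit" in table.columns:
        scale = table["unit"].map({"mm": 1.0, "m": 1000.0})
        if scale.isna().any():
            bad = sorted(table.loc[scale.isna(), "unit"].unique())
            raise TrialValidationError(f"unknown unit(s): {bad}")
        for col in ("x", "y", "z"):
            table[col] = table[col] * scale
    target = np.array(
        [float(meta.get(f"target_{ax}", "nan")) for ax in "xyz"], dtype=float
    )
    markers: dict[str, np.ndarray] = {}
    times: np.ndarray | None = None
    for name, grp in table.groupby("marker", sort=False):
        grp = grp.sort_values("time_s", kind="stable")
        t = grp["time_s"].to_numpy(dtype=float)
        if times is None:
            times = t
        elif t.shape != times.shape or not np.allclose(t, times):
            raise TrialValidationError(
                f"marker {name!r} sampled on a different time grid"
            )
        markers[str(name)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    if times is None:
        raise TrialValidationError("empty recording")
    return TrialRecording(
        subject_id=meta.get("subject_id", "unknown"),
        sensor=meta.get("sensor", "gold"),
        condition=meta.get("condition", "spontaneous"),
        assessed_side=meta.get("assessed_side", "right"),
        times=times,
        markers=markers,
        target=target,
        meta={
            k: v
            for k, v in meta.items()
            if k
            not in {
                "subject_id",
                "sensor",
                "condition",
                "assessed_side",
                "target_x",
                "target_y",
                "target_z",
            }
        },
    )


def resample_to(rec: TrialRecording, times_ref: np.ndarray) -> TrialRecording:
    """Resample every marker onto ``times_ref`` by per-axis linear interpolation.

    ``times_ref`` must lie within the recorded span; extrapolation is refused.
    Endpoint positions are preserved exactly and resampling onto the source
    grid is the identity.
    """
    times_ref = np.asarray(times_ref, dtype=float)
    if times_ref[0] < rec.times[0] - 1e-12 or times_ref[-1] > rec.times[-1] + 1e-12:
        raise TrialValidationError(
            "extrapolation requested: times_ref outside the recorded span"
        )
    new_markers = {}
    for name, pos in rec.markers.items():
        out = np.empty((times_ref.size, 3))
        for ax in range(3):
            out[:, ax] = np.interp(times_ref, rec.times, pos[:, ax])
        new_markers[name] = out
    return rec.with_markers(new_markers, times=times_ref)


def repair_gaps(times: np.ndarray, pos: np.ndarray, max_gap_s: float = MAX_GAP_S) -> np.ndarray:
    """Fill NaN runs in one marker series by linear interpolation.

    Runs longer than ``max_gap_s`` (or touching either end) reject the trial.
    """
    pos = np.array(pos, dtype=float)
    bad = ~np.all(np.isfinite(pos), axis=1)
    if not bad.any():
        return pos
    idx = np.flatnonzero(bad)
    # split into contiguous runs
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        if run[0] == 0 or run[-1] == len(times) - 1:
            raise TrialValidationError("gap at recording edge cannot be repaired")
        if times[run[-1] + 1] - times[run[0] - 1] > max_gap_s + 1e-12:
            raise TrialValidationError(
                f"dropout of {times[run[-1] + 1] - times[run[0] - 1]:.3f} s exceeds "
                f"the {max_gap_s} s repair limit"
            )
    good = ~bad
    for ax in range(3):
        pos[bad, ax] = np.interp(times[bad], times[good], pos[good, ax])
    return pos
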