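"""End-to-end validation workflow: align, filter, segment, summarize, compare.

For every trial the markerless stream is synchronized to the gold stream
(cross-correlation lag on hand speed), rigidly re-aligned into the gold
frame (least-squares fit on the slow trunk-girdle markers), both streams
are zero-phase low-pass filtered at their native rates, reaches are
segmented independently per sensor, and the kinematic variable battery is
computed per reach and per condition.  Variables are then paired across
the dataset and summarized in an agreement report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from .alignment import (
    AlignmentError,
    apply_transform,
    calibration_points,
    estimate_lag,
    fit_rigid_transform,
)
from .kinematics import (
    KinematicsError,
    compute_panu,
    summarize_condition,
    summarize_reach,
)
from .preprocessing import butterworth_lowpass_dualpass, speed, DEFAULT_CUTOFF_HZ
from .segmentation import SegmentationError, detect_reach_bounds, split_reaches
from .trajectory_io import TrialRecording, read_trial

logger = logging.getLogger("reachval")

PER_REACH_VARIABLES = [
    "elbow_extension",
    "shoulder_abduction",
    "shoulder_flexion",
    "trunk_anterior_flexion",
    "trunk_rotation",
    "movement_time",
    "path_length_ratio",
    "time_to_peak_velocity",
    "n_velocity_peaks",
    "peak_velocity",
    "mean_velocity",
    "delta_trunk",
    "delta_shoulder",
    "delta_elbow",
    "delta_hand",
]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineOptions:
    """Tunable pipeline decisions (all logged with the run)."""

    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    filter_enabled: bool = True
    align: bool = True
    shared_bounds: bool = False  # transfer gold segment bounds to markerless
    pooling: str = "reach"  # "reach" or "subject"
    min_gap: float = 0.5
    proximity_fraction: float = 0.3
    peak_prominence: float = 0.05


@dataclass
class TrialResult:
    subject_id: str
    condition: str
    lag_s: float
    transform_residual_mm: float
    segments: dict = field(default_factory=dict)  # sensor -> list[ReachSegment]
    summaries: dict = field(default_factory=dict)  # sensor -> list[KinematicSummary]
    pau: dict = field(default_factory=dict)  # sensor -> float


@dataclass
class ValidationResult:
    report: agr.AgreementReport
    summaries: pd.DataFrame  # one row per sensor x reach
    trials: list
    pairs: list  # PairedVariable list fed to the report

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(out_dir / "summaries.csv", index=False)
        self.report.write_csv(out_dir / "agreement.csv")
        self.report.write_json(out_dir / "agreement.json")
        segments = [
            {
                "subject_id": tr.subject_id,
                "condition": tr.condition,
                "sensor": sensor,
                "segments": [s.to_dict() for s in segs],
            }
            for tr in self.trials
            for sensor, segs in tr.segments.items()
        ]
        (out_dir / "segments.json").write_text(json.dumps(segments, indent=2))
        plot_dir = out_dir / "plotdata"
        plot_dir.mkdir(exist_ok=True)
        for pv in self.pairs:
            pd.DataFrame({"gold": pv.gold_values, "test": pv.test_values}).to_csv(
                plot_dir / f"{pv.name}.csv", index=False
            )
        return out_dir


# ----------------------------------------------------------------------
# single-trial processing
# ----------------------------------------------------------------------

def _filter_recording(rec: TrialRecording, cutoff: float) -> TrialRecording:
    fs = rec.sample_rate
    markers = {
        name: butterworth_lowpass_dualpass(pos, fs, cutoff=cutoff)
        for name, pos in rec.markers.items()
    }
    return rec.with_markers(markers)


def align_pair(
    gold: TrialRecording, markerless: TrialRecording, opts: PipelineOptions
) -> tuple[TrialRecording, float, float]:
    """Synchronize and re-frame the markerless stream; returns (aligned, lag, residual)."""
    gs = speed(gold.markers["hand"], gold.sample_rate)
    ms = speed(markerless.markers["hand"], markerless.sample_rate)
    lag = estimate_lag(gold.times, gs, markerless.times, ms)
    if abs(lag) > 1e-12:
        markerless = dataclasses.replace(markerless, times=markerless.times - lag)
    src, dst = calibration_points(gold, markerless)
    tf = fit_rigid_transform(src, dst)
    return apply_transform(tf, markerless), lag, tf.rms_residual


def segment_and_summarize(
    rec: TrialRecording,
    opts: PipelineOptions,
    windows: list | None = None,
) -> tuple[list, list]:
    """Split a trial into reaches and compute each reach's summary.

    Reach-level failures are logged and skipped.  Returns (segments,
    summaries), index-matched.
    """
    hand = rec.markers["hand"]
    fs = rec.sample_rate
    if windows is None:
        windows = split_reaches(hand, rec.target, fs, min_gap=opts.min_gap,
                                proximity_fraction=opts.proximity_fraction)
    segments, summaries = [], []
    for lo, hi in windows:
        try:
            seg = detect_reach_bounds(hand, rec.target, rec.times, fs, window=(lo, hi))
            summaries.append(summarize_reach(rec, seg, opts.peak_prominence))
            segments.append(seg)
        except (SegmentationError, KinematicsError) as exc:
            logger.warning(
                "%s/%s/%s: reach window [%d, %d) skipped: %s",
                rec.subject_id, rec.condition, rec.sensor, lo, hi, exc,
            )
    return segments, summaries


def _windows_from_segments(rec: TrialRecording, gold: TrialRecording,
                           gold_windows: list) -> list:
    """Transfer gold split windows onto the (aligned) markerless grid."""
    out = []
    for lo, hi in gold_windows:
        t_lo, t_hi = gold.times[lo], gold.times[min(hi, gold.times.size - 1)]
        i_lo = int(np.searchsorted(rec.times, t_lo))
        i_hi = int(np.searchsorted(rec.times, t_hi, side="right"))
        out.append((i_lo, min(i_hi, rec.times.size)))
    return out


def process_trial_pair(
    gold: TrialRecording,
    markerless: TrialRecording,
    opts: PipelineOptions = PipelineOptions(),
) -> TrialResult:
    """Run alignment, filtering, segmentation and summarization on one trial."""
    lag, resid = 0.0, 0.0
    if opts.align:
        markerless, lag, resid = align_pair(gold, markerless, opts)
    if opts.filter_enabled:
        gold = _filter_recording(gold, opts.cutoff_hz)
        markerless = _filter_recording(markerless, opts.cutoff_hz)
    result = TrialResult(
        subject_id=gold.subject_id, condition=gold.condition,
        lag_s=lag, transform_residual_mm=resid,
    )
    gold_windows = split_reaches(gold.markers["hand"], gold.target,
                                 gold.sample_rate, min_gap=opts.min_gap,
                                 proximity_fraction=opts.proximity_fraction)
    segs, sums = segment_and_summarize(gold, opts, windows=gold_windows)
    result.segments["gold"], result.summaries["gold"] = segs, sums
    ml_windows = (
        _windows_from_segments(markerless, gold, gold_windows)
        if opts.shared_bounds
        else None
    )
    segs, sums = segment_and_summarize(markerless, opts, windows=ml_windows)
    result.segments["markerless"], result.summaries["markerless"] = segs, sums
    for sensor in ("gold", "markerless"):
        if result.summaries[sensor]:
            cond = summarize_condition(gold.condition, result.summaries[sensor])
            result.pau[sensor] = cond.pau
    return result


# ----------------------------------------------------------------------
# dataset-level assembly
# ----------------------------------------------------------------------

def _load_pairs_from_dir(dataset_dir: Path) -> list[tuple[TrialRecording, TrialRecording]]:
    rec_dir = dataset_dir / "recordings" if (dataset_dir / "recordings").is_dir() else dataset_dir
    by_key: dict[tuple, dict] = {}
    for path in sorted(rec_dir.glob("*.csv")):
        rec = read_trial(path)
        by_key.setdefault((rec.subject_id, rec.condition), {})[rec.sensor] = rec
    pairs = []
    for key, sensors in sorted(by_key.items()):
        if "gold" in sensors and "markerless" in sensors:
            pairs.append((sensors["gold"], sensors["markerless"]))
        else:
            logger.warning("unpaired trial %s skipped (sensors: %s)",
                           key, sorted(sensors))
    return pairs


def run_validation(
    dataset,
    opts: PipelineOptions = PipelineOptions(),
    out_dir: str | Path | None = None,
) -> ValidationResult:
    """Validate the markerless sensor against the gold standard on a dataset.

    ``dataset`` may be a :class:`reachval.synthetic.SyntheticDataset` or a
    directory of paired tidy-CSV recordings.  Returns the agreement report
    plus per-reach summaries; optionally writes everything under
    ``out_dir`` (``summaries.csv``, ``agreement.csv``/``.json``,
    ``segments.json``, ``plotdata/``).
    """
    if isinstance(dataset, (str, Path)):
        rec_pairs = _load_pairs_from_dir(Path(dataset))
    else:
        rec_pairs = [(p.gold, p.markerless) for p in dataset.pairs]
    if not rec_pairs:
        raise PipelineError("no paired trials in dataset")
    logger.info("validating %d trial pairs with options %s", len(rec_pairs), opts)

    trials: list[TrialResult] = []
    for gold, markerless in rec_pairs:
        try:
            trials.append(process_trial_pair(gold, markerless, opts))
        except (AlignmentError, SegmentationError, KinematicsError) as exc:
            logger.warning("trial %s/%s failed: %s", gold.subject_id,
                           gold.condition, exc)
    if not trials:
        raise PipelineError("all trials failed")

    summaries = _summary_table(trials)
    pairs = assemble_paired_variables(trials, pooling=opts.pooling)
    report = agr.build_agreement_report(pairs)
    result = ValidationResult(report=report, summaries=summaries,
                              trials=trials, pairs=pairs)
    if out_dir is not None:
        result.write(out_dir)
    return result


def _summary_table(trials: list) -> pd.DataFrame:
    rows = []
    for tr in trials:
        for sensor, sums in tr.summaries.items():
            for ri, s in enumerate(sums):
                rows.append(
                    {
                        "subject_id": tr.subject_id,
                        "condition": tr.condition,
                        "sensor": sensor,
                        "reach": ri + 1,
                        **s.to_dict(),
                    }
                )
    return pd.DataFrame(rows)


def _match_reaches(segs_gold: list, segs_test: list,
                   max_offset_s: float = 1.0) -> list[tuple[int, int]]:
    """Match detected reaches across sensors by segment-midpoint proximity.

    Spurious artifact-induced windows on one sensor must not shift the
    correspondence of all later reaches, so index-order pairing is not
    enough.  Greedy one-to-one assignment by increasing midpoint distance,
    capped at ``max_offset_s``.
    """
    cands = []
    for ig, sg in enumerate(segs_gold):
        mg = (sg.t0 + sg.t_final) / 2.0
        for im, sm in enumerate(segs_test):
            off = abs(mg - (sm.t0 + sm.t_final) / 2.0)
            if off <= max_offset_s:
                cands.append((off, ig, im))
    cands.sort()
    used_g: set[int] = set()
    used_m: set[int] = set()
    matches = []
    for _, ig, im in cands:
        if ig not in used_g and im not in used_m:
            matches.append((ig, im))
            used_g.add(ig)
            used_m.add(im)
    matches.sort()
    return matches


def assemble_paired_variables(trials: list, pooling: str = "reach") -> list:
    """Pair per-reach, per-condition and per-subject variables across sensors.

    Per-reach variables are paired reach-by-reach within each trial (up to
    the smaller detected reach count); with ``pooling="subject"`` they are
    first averaged within subject x condition.  PAU is paired per
    condition, PANU per subject.
    """
    reach_rows: dict[str, list] = {name: [] for name in PER_REACH_VARIABLES}
    pau_pairs: list[tuple[float, float]] = []
    panu_by_subject: dict[str, dict] = {}

    for tr in trials:
        sums_g = tr.summaries.get("gold", [])
        sums_m = tr.summaries.get("markerless", [])
        matches = _match_reaches(tr.segments.get("gold", []),
                                 tr.segments.get("markerless", []))
        if len(matches) < max(len(sums_g), len(sums_m)):
            logger.warning("%s/%s: paired %d reaches (gold=%d markerless=%d)",
                           tr.subject_id, tr.condition, len(matches),
                           len(sums_g), len(sums_m))
        trial_vals = {name: [] for name in PER_REACH_VARIABLES}
        for ig, im in matches:
            for name in PER_REACH_VARIABLES:
                trial_vals[name].append(
                    (getattr(sums_g[ig], name), getattr(sums_m[im], name))
                )
        k = len(matches)
        if pooling == "subject" and k > 0:
            for name, vals in trial_vals.items():
                g = float(np.mean([v[0] for v in vals]))
                m = float(np.mean([v[1] for v in vals]))
                reach_rows[name].append((g, m))
        else:
            for name, vals in trial_vals.items():
                reach_rows[name].extend(vals)
        if "gold" in tr.pau and "markerless" in tr.pau:
            pau_pairs.append((tr.pau["gold"], tr.pau["markerless"]))
            panu_by_subject.setdefault(tr.subject_id, {})[tr.condition] = tr.pau

    panu_pairs = []
    for subject, conds in sorted(panu_by_subject.items()):
        if {"spontaneous", "restrained"} <= set(conds):
            pg, _ = compute_panu(conds["restrained"]["gold"],
                                 conds["spontaneous"]["gold"])
            pm, _ = compute_panu(conds["restrained"]["markerless"],
                                 conds["spontaneous"]["markerless"])
            panu_pairs.append((pg, pm))

    pairs = []
    for name in PER_REACH_VARIABLES:
        vals = reach_rows[name]
        if len(vals) >= 3:
            pairs.append(agr.PairedVariable(
                name, [v[0] for v in vals], [v[1] for v in vals]))
    if len(pau_pairs) >= 3:
        pairs.append(agr.PairedVariable(
            "pau", [v[0] for v in pau_pairs], [v[1] for v in pau_pairs]))
    if len(panu_pairs) >= 3:
        pairs.append(agr.PairedVariable(
            "panu", [v[0] for v in panu_pairs], [v[1] for v in panu_pairs]))
    return pairs


# ----------------------------------------------------------------------
# reporting / plots
# ----------------------------------------------------------------------

def run_report(result_dir: str | Path, plot_dir: str | Path | None = None) -> list[Path]:
    """Render Bland-Altman and regression plots from a written validation run.

    Reads ``agreement.json`` and the per-variable ``plotdata`` CSVs;
    writes one plot pair per variable plus a summary scatter of relative
    error vs ICC.  Returns the created file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    result_dir = Path(result_dir)
    report_path = result_dir / "agreement.json"
    if not report_path.is_file():
        raise PipelineError(f"malformed report: {report_path} missing")
    rows = json.loads(report_path.read_text())
    plot_dir = Path(plot_dir) if plot_dir is not None else result_dir / "plots"
    plot_dir.mkdir(parents=True, exist_ok=True)
    created = []
    for row in rows:
        data_path = result_dir / "plotdata" / f"{row['name']}.csv"
        if not data_path.is_file():
            logger.warning("no plot data for %s", row["name"])
            continue
        data = pd.read_csv(data_path)
        g, t = data["gold"].to_numpy(), data["test"].to_numpy()
        fig, (ax_ba, ax_reg) = plt.subplots(1, 2, figsize=(9, 4))
        means, diffs = (g + t) / 2.0, t - g
        ax_ba.scatter(means, diffs, s=12, alpha=0.6)
        if row["bias"] is not None:
            ax_ba.axhline(row["bias"], color="k")
            ax_ba.axhline(row["loa_low"], color="k", linestyle="--")
            ax_ba.axhline(row["loa_high"], color="k", linestyle="--")
        ax_ba.set_xlabel("mean of sensors")
        ax_ba.set_ylabel("markerless - gold")
        ax_ba.set_title(f"{row['name']}: Bland-Altman")
        ax_reg.scatter(g, t, s=12, alpha=0.6)
        lims = [min(g.min(), t.min()), max(g.max(), t.max())]
        ax_reg.plot(lims, lims, "k--", linewidth=1)
        ax_reg.set_xlabel("gold")
        ax_reg.set_ylabel("markerless")
        icc = row.get("icc")
        ax_reg.set_title(f"ICC = {icc:.2f}" if icc is not None else "ICC: NA")
        fig.tight_layout()
        out = plot_dir / f"{row['name']}.png"
        fig.savefig(out, dpi=110)
        plt.close(fig)
        created.append(out)
    # summary scatter: relative error vs ICC
    ok = [r for r in rows if r.get("icc") is not None and r.get("relative_error") is not None]
    if ok:
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter([r["relative_error"] for r in ok], [r["icc"] for r in ok])
        for r in ok:
            ax.annotate(r["name"], (r["relative_error"], r["icc"]), fontsize=7)
        ax.axvline(0, color="k", linewidth=0.5)
        ax.set_xlabel("relative systematic error (%)")
        ax.set_ylabel("one-way ICC")
        ax.set_ylim(None, 1.02)
        fig.tight_layout()
        out = plot_dir / "summary_validity_reliability.png"
        fig.savefig(out, dpi=110)
        plt.close(fig)
        created.append(out)
    elif not rows:
        logger.warning("empty report: no plots produced")
    return created
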