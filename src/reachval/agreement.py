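"""Paired-sensor validity and reliability statistics.

Each kinematic variable yields a set of paired observations (gold-standard
value, test-sensor value).  Reliability is summarized by the one-way
single-rating intraclass correlation coefficient and the coefficient of
determination; accuracy by RMSE and range-normalized RMSE; validity by the
Bland-Altman bias with 95% limits of agreement and by the relative
systematic error.  Categorical labels follow the Koo & Li bands:
ICC < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >= 0.9 excellent, and
the complementary |relative error| cut-offs 10/25/50% for validity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class PairedVariable:
    """Paired observations of one variable from both sensors."""

    name: str
    gold_values: np.ndarray
    test_values: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gold_values, dtype=float)
        t = np.asarray(self.test_values, dtype=float)
        object.__setattr__(self, "gold_values", g)
        object.__setattr__(self, "test_values", t)
        if g.ndim != 1 or g.shape != t.shape:
            raise AgreementError(f"{self.name}: paired vectors must be 1-D, equal length")
        if g.size < 3:
            raise AgreementError(f"{self.name}: need at least 3 paired observations")
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(t))):
            raise AgreementError(f"{self.name}: non-finite values")

    @property
    def n(self) -> int:
        return self.gold_values.size


def icc_oneway(pv: PairedVariable) -> float:
    """One-way random-effects, single-rating ICC over N subjects x 2 raters.

    From the one-way ANOVA decomposition with k measurements per subject:
    ICC = (MSB - MSW) / (MSB + (k - 1) MSW).  Unlike a consistency-type
    two-way ICC, this penalizes systematic offsets between the sensors.
    """
    data = np.column_stack([pv.gold_values, pv.test_values])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((data - row_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom <= 0:
        raise AgreementError(f"{pv.name}: ICC undefined, zero total variance")
    return float((msb - msw) / denom)


def rmse(pv: PairedVariable) -> float:
    """Root-mean-square error of the test sensor against the gold standard."""
    return float(np.sqrt(np.mean((pv.gold_values - pv.test_values) ** 2)))


def nrmse(pv: PairedVariable) -> float:
    """RMSE normalized by the gold-standard range of the variable, percent."""
    rng = float(np.max(pv.gold_values) - np.min(pv.gold_values))
    if rng <= 0:
        raise AgreementError(f"{pv.name}: NRMSE undefined, zero gold range")
    return 100.0 * rmse(pv) / rng


def r_squared(pv: PairedVariable) -> float:
    """Squared Pearson correlation of gold vs test values."""
    g, t = pv.gold_values, pv.test_values
    if np.std(g) == 0 or np.std(t) == 0:
        raise AgreementError(f"{pv.name}: r^2 undefined, zero variance")
    r = np.corrcoef(g, t)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)


def bland_altman(pv: PairedVariable) -> BlandAltman:
    """Bland-Altman analysis: bias = mean(test - gold), 95% limits of agreement.

    Limits are bias +- 1.96 x sample SD (N-1 denominator) of the paired
    differences; per-pair means and differences are returned for plotting.
    """
    diff = pv.test_values - pv.gold_values
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(pv.test_values + pv.gold_values) / 2.0,
        differences=diff,
    )


def relative_error(pv: PairedVariable) -> tuple[float, str]:
    """Relative systematic error (%) and its direction.

    100 x (mean(test) - mean(gold)) / mean(gold); positive values are
    reported as overestimation by the test sensor.
    """
    mg = float(np.mean(pv.gold_values))
    mt = float(np.mean(pv.test_values))
    if mg == 0.0:
        raise AgreementError(f"{pv.name}: relative error undefined, zero gold mean")
    err = 100.0 * (mt - mg) / mg
    return err, ("overestimation" if err >= 0 else "underestimation")


def classify_reliability(icc: float) -> str:
    """Koo & Li reliability band for an ICC value."""
    if icc >= 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def classify_validity(relative_error_percent: float) -> str:
    """Validity band from |relative error|: 10/25/50% cut-offs."""
    e = abs(relative_error_percent)
    if e <= 10.0:
        return "excellent"
    if e <= 25.0:
        return "good"
    if e <= 50.0:
        return "moderate"
    return "poor"


@dataclass
class AgreementRow:
    """All agreement statistics and labels for one variable."""

    name: str
    n: int
    icc: float | None = None
    r_squared: float | None = None
    rmse: float | None = None
    nrmse: float | None = None
    bias: float | None = None
    bias_sd: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    relative_error: float | None = None
    direction: str | None = None
    reliability_label: str | None = None
    validity_label: str | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


#: canonical variable order (grouped: angles, efficiency, planning,
#: smoothness, speed, displacements)
VARIABLE_ORDER = [
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
    "panu",
    "pau",
    "delta_trunk",
    "delta_shoulder",
    "delta_elbow",
    "delta_hand",
]


def analyze_pair(pv: PairedVariable) -> AgreementRow:
    """All statistics for one paired variable; failures become row-level NA."""
    row = AgreementRow(name=pv.name, n=pv.n)
    problems = []
    for attr, fn in (("icc", icc_oneway), ("r_squared", r_squared),
                     ("rmse", rmse), ("nrmse", nrmse)):
        try:
            setattr(row, attr, fn(pv))
        except AgreementError as exc:
            problems.append(str(exc))
    try:
        ba = bland_altman(pv)
        row.bias, row.bias_sd = ba.bias, ba.sd
        row.loa_low, row.loa_high = ba.loa_low, ba.loa_high
    except AgreementError as exc:  # pragma: no cover - BA has no failure mode
        problems.append(str(exc))
    try:
        row.relative_error, row.direction = relative_error(pv)
        row.validity_label = classify_validity(row.relative_error)
    except AgreementError as exc:
        problems.append(str(exc))
    if row.icc is not None:
        row.reliability_label = classify_reliability(row.icc)
    if problems:
        row.error = "; ".join(problems)
    return row


@dataclass
class AgreementReport:
    rows: list[AgreementRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.rows])

    def row(self, name: str) -> AgreementRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps([r.to_dict() for r in self.rows], indent=2))
        return path


def build_agreement_report(pairs: list[PairedVariable]) -> AgreementReport:
    """One :class:`AgreementRow` per variable, in the canonical order.

    Per-variable failures (zero variance, zero range ...) are reported as
    row-level NA with a reason instead of aborting the whole report.
    """
    order = {name: i for i, name in enumerate(VARIABLE_ORDER)}
    ordered = sorted(pairs, key=lambda p: order.get(p.name, len(order)))
    return AgreementReport(rows=[analyze_pair(p) for p in ordered])
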