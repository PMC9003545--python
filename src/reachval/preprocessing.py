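"""Low-pass filtering, spectral checks and numerical differentiation.

Markerless skeleton tracking produces high-frequency position noise, so
every position series is zero-phase low-pass filtered before segmentation
and differentiation.  The default cut-off of 2.5 Hz is justified by the
spectral criterion implemented in :func:`band_power_fraction`: natural-pace
seated reaches keep at least 95% of their spectral density below 2.5 Hz.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

DEFAULT_CUTOFF_HZ = 2.5
DEFAULT_ORDER = 2
#: minimum series length accepted by the filter (3x the kernel support)
_MIN_FILTER_LEN = 3 * (2 * DEFAULT_ORDER + 1)


class PreprocessingError(ValueError):
    pass


def butterworth_lowpass_dualpass(
    series: np.ndarray,
    sample_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Dual-pass (forward-backward) Butterworth low-pass filter.

    The filter is applied once forward and once backward, cancelling the
    phase response; the effective magnitude response is the square of the
    single-pass response, i.e. gain 0.5 (-6 dB) at the cut-off for any
    order.  Edges are handled by reflective padding.

    Works on 1-D series or (n, k) arrays (filtered along axis 0).
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if cutoff >= sample_rate / 2:
        raise PreprocessingError(
            f"cutoff above Nyquist: {cutoff} Hz >= {sample_rate / 2} Hz"
        )
    if n < max(_MIN_FILTER_LEN, 3 * (2 * order + 1)):
        raise PreprocessingError("insufficient samples for filtering")
    b, a = signal.butter(order, cutoff, btype="low", fs=sample_rate)
    # pad with ~3 filter time constants of mirrored signal, capped by length
    padlen = min(n - 1, int(round(3 * order * sample_rate / cutoff)))
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def band_power_fraction(
    series: np.ndarray, sample_rate: float, f_hi: float = DEFAULT_CUTOFF_HZ
) -> float:
    """Fraction of the periodogram power at frequencies <= ``f_hi``.

    The series is mean-detrended before spectral estimation.  Raises on a
    constant series (zero total power).  Invariant to amplitude scaling and
    mean offset.
    """
    x = np.asarray(series, dtype=float)
    freqs, pxx = signal.periodogram(x, fs=sample_rate, detrend="constant",
                                    window="boxcar")
    total = float(np.sum(pxx))
    if total <= 0.0:
        raise PreprocessingError("zero total power: constant series")
    return float(np.sum(pxx[freqs <= f_hi]) / total)


def differentiate(series: np.ndarray, sample_rate: float) -> np.ndarray:
    """Time derivative: central differences interior, one-sided at the edges.

    Accepts 1-D series or (n, k) arrays; output has the same shape, in
    units of the input per second.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 3:
        raise PreprocessingError("too short to differentiate")
    return np.gradient(x, 1.0 / sample_rate, axis=0)


def speed(positions: np.ndarray, sample_rate: float) -> np.ndarray:
    """Euclidean speed of a 3D position series, mm/s."""
    vel = differentiate(positions, sample_rate)
    return np.linalg.norm(vel, axis=1)
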