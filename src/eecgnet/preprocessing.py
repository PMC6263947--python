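"""Raw ECG -> fixed-length averaged-beat vector -> 2D beat image.

The chain, per lead: subtract a wide moving-average baseline estimate, smooth
with a short moving average, detect R peaks by thresholded local maxima with a
refractory window, extract a fixed window around every usable peak and average
them.  Per-lead averaged beats are concatenated in lead order, linearly
resampled to the target length (e.g. 784 -> 28x28, 1600 -> 40x40) and
amplitude-normalized (zero mean, unit max-abs); the result reshapes row-major
into the beat image that feeds the filter-bank network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ECGRecord

__all__ = [
    "Signal1D",
    "PeakList",
    "moving_average",
    "remove_baseline",
    "smooth",
    "detect_r_peaks",
    "average_beat",
    "build_beat_vector",
    "to_image",
    "DEFAULT_BASELINE_WIDTH",
    "DEFAULT_SMOOTH_WIDTH",
    "DEFAULT_BEAT_WINDOW",
]

DEFAULT_BASELINE_WIDTH = 500
DEFAULT_SMOOTH_WIDTH = 10
DEFAULT_BEAT_WINDOW = 400


@dataclass(frozen=True)
class Signal1D:
    """One lead of samples in mV with its sampling rate."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise ValueError("signal must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PeakList:
    """Strictly increasing R-peak sample positions."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).ravel()
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size


def moving_average(signal: Signal1D, width: int) -> Signal1D:
    """Centered moving average with truncated (shrinking) edge windows.

    Output sample i is the mean of the window of ``width`` samples centered on
    i — for even widths the extra sample falls after i — intersected with the
    signal's range, so edges average fewer samples instead of seeing padding.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x = signal.values
    if width == 1:
        return Signal1D(values=x.copy(), fs=signal.fs)
    n = x.size
    left = (width - 1) // 2
    right = width // 2  # inclusive extent after i
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right, n - 1)
    sums = csum[hi + 1] - csum[lo]
    return Signal1D(values=sums / (hi - lo + 1), fs=signal.fs)


def remove_baseline(signal: Signal1D, width: int = DEFAULT_BASELINE_WIDTH) -> Signal1D:
    """Subtract a wide moving-average estimate of the baseline drift."""
    base = moving_average(signal, width)
    return Signal1D(values=signal.values - base.values, fs=signal.fs)


def smooth(signal: Signal1D, width: int = DEFAULT_SMOOTH_WIDTH) -> Signal1D:
    """Short moving-average smoothing of the baseline-corrected signal."""
    return moving_average(signal, width)


def detect_r_peaks(
    signal: Signal1D,
    refractory: float = 0.3,
    rel_threshold: float = 0.5,
) -> PeakList:
    """Thresholded local maxima with a greedy refractory rule.

    Candidates are local maxima whose value reaches ``rel_threshold`` times the
    global maximum (the global maximum itself is always a candidate).  They are
    accepted in decreasing-amplitude order — earlier index first on exact ties
    — and a candidate closer than the refractory window to an already accepted
    peak is dropped, so the larger of two nearby candidates wins.
    """
    x = signal.values
    if x.size < 1 or np.ptp(x) == 0:
        raise ValueError("no peak definable on a constant or empty signal")
    gmax_idx = int(np.argmax(x))
    gmax = x[gmax_idx]
    thresh = rel_threshold * gmax
    interior = np.arange(1, x.size - 1)
    is_local = (x[interior] >= x[interior - 1]) & (x[interior] > x[interior + 1])
    cand = interior[is_local & (x[interior] >= thresh)]
    if gmax_idx not in cand:
        cand = np.append(cand, gmax_idx)
    refractory_samples = int(round(refractory * signal.fs))
    # Greedy: by descending value, ascending index on ties.
    order = np.lexsort((cand, -x[cand]))
    kept: list[int] = []
    for c in cand[order]:
        if all(abs(int(c) - k) >= refractory_samples for k in kept):
            kept.append(int(c))
    return PeakList(indices=np.sort(kept))


def average_beat(
    signal: Signal1D, peaks: PeakList, window: int = DEFAULT_BEAT_WINDOW
) -> np.ndarray:
    """Mean of the window-length segments centered on each usable peak.

    The window spans ``window // 2`` samples before the peak and the remainder
    after it (odd windows put the extra sample after).  Peaks whose window
    crosses a signal boundary are discarded; at least one must survive.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = signal.values
    left = window // 2
    right = window - left
    segments = [
        x[p - left : p + right]
        for p in peaks.indices
        if p - left >= 0 and p + right <= x.size
    ]
    if not segments:
        raise ValueError("no peak has a full window inside the signal")
    return np.mean(segments, axis=0)


def _resample_linear(x: np.ndarray, target_len: int) -> np.ndarray:
    if x.size == target_len:
        return x.copy()
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, target_len)
    return np.interp(dst, src, x)


def build_beat_vector(
    record: ECGRecord,
    target_len: int,
    baseline_width: int = DEFAULT_BASELINE_WIDTH,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
    window: int = DEFAULT_BEAT_WINDOW,
    refractory: float = 0.3,
    rel_threshold: float = 0.5,
    normalize: bool = True,
) -> np.ndarray:
    """Full per-record chain -> length-``target_len`` averaged-beat vector.

    Per lead: remove_baseline -> smooth -> detect_r_peaks -> average_beat;
    the per-lead averages are concatenated in lead order, linearly resampled
    to ``target_len``, and (by default) normalized to zero mean and unit
    maximum absolute value.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    pieces = []
    for lead in range(record.n_leads):
        sig = Signal1D(values=record.samples[:, lead], fs=record.fs)
        sig = remove_baseline(sig, baseline_width)
        sig = smooth(sig, smooth_width)
        peaks = detect_r_peaks(sig, refractory=refractory, rel_threshold=rel_threshold)
        pieces.append(average_beat(sig, peaks, window))
    vec = _resample_linear(np.concatenate(pieces), target_len)
    if normalize:
        vec = vec - vec.mean()
        m = np.max(np.abs(vec))
        if m > 0:
            vec = vec / m
    return vec


def to_image(vec: np.ndarray, m: int, n: int) -> np.ndarray:
    """Row-major reshape of a beat vector into an m x n image."""
    v = np.asarray(vec, dtype=float).ravel()
    if m * n != v.size:
        raise ValueError(f"cannot reshape length-{v.size} vector to {m}x{n}")
    return v.reshape(m, n)
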