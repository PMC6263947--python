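"""Signal-fidelity and compression metrics for original/reconstructed pairs.

Given an original signal Xs and a reconstruction Xr of equal length N:

    CR   = B0 / Bc                                   (bit-count ratio)
    PRD  = 100 * sqrt( sum (Xs-Xr)^2 / sum Xs^2 )            (%)
    PRDN = 100 * sqrt( sum (Xs-Xr)^2 / sum (Xs-mean)^2 )     (%)
    RMS  = 100 * sqrt( sum (Xs-Xr)^2 / (N-1) )
    SNR  = 10 * log10( sum (Xs-mean)^2 / sum (Xs-Xr)^2 )     (dB)

Degenerate denominators raise ``ValueError`` rather than returning infinities.
"""

from __future__ import annotations

import numpy as np

__all__ = ["compression_ratio", "prd", "prdn", "rms_error", "snr"]


def _pair(xs, xr) -> tuple[np.ndarray, np.ndarray]:
    xs = np.asarray(xs, dtype=float).ravel()
    xr = np.asarray(xr, dtype=float).ravel()
    if xs.size != xr.size:
        raise ValueError("original and reconstructed signals must have equal length")
    if xs.size == 0:
        raise ValueError("signals must be non-empty")
    return xs, xr


def compression_ratio(b0: int, bc: int) -> float:
    """Bits of the original over bits of the compressed representation."""
    if bc <= 0:
        raise ValueError("compressed bit count must be positive")
    return b0 / bc


def prd(xs, xr) -> float:
    """Percent root-mean-square difference relative to signal energy."""
    xs, xr = _pair(xs, xr)
    denom = float(np.sum(xs**2))
    if denom == 0:
        raise ValueError("PRD undefined for an all-zero original signal")
    return 100.0 * float(np.sqrt(np.sum((xs - xr) ** 2) / denom))


def prdn(xs, xr) -> float:
    """Mean-normalized PRD, independent of the signal's DC offset."""
    xs, xr = _pair(xs, xr)
    denom = float(np.sum((xs - xs.mean()) ** 2))
    if denom == 0:
        raise ValueError("PRDN undefined for a constant original signal")
    return 100.0 * float(np.sqrt(np.sum((xs - xr) ** 2) / denom))


def rms_error(xs, xr) -> float:
    """Root-mean-square reconstruction error, scaled by 100."""
    xs, xr = _pair(xs, xr)
    if xs.size < 2:
        raise ValueError("RMS needs at least 2 samples (N-1 denominator)")
    return 100.0 * float(np.sqrt(np.sum((xs - xr) ** 2) / (xs.size - 1)))


def snr(xs, xr) -> float:
    """Signal-to-noise ratio of the reconstruction in dB."""
    xs, xr = _pair(xs, xr)
    num = float(np.sum((xs - xs.mean()) ** 2))
    den = float(np.sum((xs - xr) ** 2))
    if num == 0:
        raise ValueError("SNR undefined for a constant original signal")
    if den == 0:
        raise ValueError("SNR undefined for a perfect reconstruction")
    return 10.0 * float(np.log10(num / den))
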