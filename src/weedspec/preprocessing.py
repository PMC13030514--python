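"""Spectral smoothing and scatter correction.

The processing chain applies a moving average first and Standard Normal
Variate (SNV) second; :func:`preprocess` enforces that order.  No band
trimming happens here — the full acquired range is retained, and any band
windowing belongs to the metrics layer.

SNV uses the population (divisor-n) standard deviation, the chemometrics
convention, so test values are exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["moving_average", "snv", "preprocess"]


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Boxcar-smooth spectra along the last axis with a shrunk-edge window.

    ``window`` must be odd; at the spectrum edges the window truncates to the
    available samples, so output length always equals input length and a
    constant spectrum passes through unchanged.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds spectrum length {n}")
    if window == 1:
        return values.copy()
    kernel = np.ones(window)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    sums = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1, values
    )
    return sums / counts


def snv(values: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: centre and scale each spectrum to sd 1.

    Operates along the last axis (each row of a pixel x band matrix is one
    spectrum).  Rejects spectra with fewer than 2 bands or zero spread,
    where the transform is undefined.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 bands per spectrum")
    mean = values.mean(axis=-1, keepdims=True)
    sd = values.std(axis=-1, keepdims=True)  # population convention
    if np.any(sd == 0):
        raise ValueError("SNV undefined for zero-spread spectrum")
    return (values - mean) / sd


def preprocess(values: np.ndarray, window: int = 5, apply_snv: bool = True) -> np.ndarray:
    """Smoothing-then-SNV chain with the package defaults (window = 5 bands)."""
    out = moving_average(values, window)
    if apply_snv:
        out = snv(out)
    return out
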