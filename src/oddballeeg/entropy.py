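"""Multiscale sample entropy on concatenated clean epochs.

Sample entropy is the negative log conditional probability that two
subsequences matching for ``m`` points (Chebyshev distance <= r)
continue to match at ``m + 1`` points, self-matches excluded.
Multiscale entropy evaluates it on progressively coarse-grained copies
of a signal; here the tolerance r is fixed from the scale-1 series
(0.15 of its SD), which makes the per-scale values comparable and is
what produces the characteristic decline of entropy with scale for
white-like noise.

The multiscale feature block works on ~20 s of data per channel
(5,000 samples at a 250 Hz working rate) gathered by concatenating a
subject's earliest clean epochs; every other montage channel is used,
and 20 timescales, giving 64 x 20 = 1,280 values on a 128-channel net.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import signal as sp_signal

from .containers import CleanMask, EpochedRecording, ValidationError

__all__ = [
    "coarse_grain",
    "sample_entropy",
    "mmse_features",
]

#: default working sampling rate for the multiscale block, Hz
WORKING_FS = 250.0
#: default number of contiguous working-rate samples per channel
TARGET_SAMPLES = 5000


def coarse_grain(x: np.ndarray, scale: int, mode: str = "nonoverlap") -> np.ndarray:
    """Window means of ``x`` at the given scale.

    ``"nonoverlap"`` (default): means of consecutive disjoint windows,
    output length ``floor(N / scale)``.  ``"moving"``: sliding-window
    means, output length ``N - scale + 1``.
    """
    x = np.asarray(x, dtype=np.float64)
    if scale < 1:
        raise ValidationError("scale must be >= 1")
    if x.size < scale:
        raise ValidationError("series shorter than the coarse-graining scale")
    if scale == 1:
        return x.copy()
    if mode == "nonoverlap":
        n = x.size // scale
        return x[: n * scale].reshape(n, scale).mean(axis=1)
    if mode == "moving":
        kernel = np.full(scale, 1.0 / scale)
        return np.convolve(x, kernel, mode="valid")
    raise ValidationError(f"unknown coarse-graining mode '{mode}'")


def _match_counts(
    x: np.ndarray, m: int, r: float, n_templates: int, chunk: int = 512
) -> int:
    """Unordered template pairs (i < j) within Chebyshev r at length m."""
    windows = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    total = 0
    for start in range(0, n_templates, chunk):
        blk = windows[start : start + chunk]
        d = np.abs(blk[:, None, :] - windows[None, :, :]).max(axis=2)
        within = d <= r
        # count only j > i to exclude self-matches and double counting
        j = np.arange(n_templates)
        i = np.arange(start, start + blk.shape[0])
        total += int((within & (j[None, :] > i[:, None])).sum())
    return total


def sample_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None
) -> float:
    """Sample entropy -ln(A/B) with embedding ``m`` and tolerance ``r``.

    ``r`` defaults to 0.15 x SD(x).  ``B`` counts template pairs
    matching at length ``m``, ``A`` at length ``m + 1``; both use
    Chebyshev distance <= r over the first ``N - m`` templates and
    exclude self-matches.  A constant series returns 0; other
    degenerate counts return NaN with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size <= m + 1:
        raise ValidationError(f"series length must exceed m + 1 = {m + 1}")
    if np.ptp(x) == 0:
        return 0.0
    if r is None:
        r = 0.15 * x.std()
    # both counts run over the same N - m templates (the length-(m+1)
    # windows number exactly N - m)
    n_templates = x.size - m
    b = _match_counts(x, m, r, n_templates)
    a = _match_counts(x, m + 1, r, n_templates)
    if b == 0 or a == 0:
        warnings.warn(
            "sample entropy undefined (no template matches); returning NaN",
            stacklevel=2,
        )
        return math.nan
    return -math.log(a / b)


def _decimate(x: np.ndarray, fs: float, working_fs: float) -> np.ndarray:
    if fs == working_fs:
        return x
    q = fs / working_fs
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValidationError(
            f"sampling rate {fs} Hz is not an integer multiple of the "
            f"{working_fs} Hz working rate"
        )
    # order-8 low-pass antialiasing filter, then keep every q-th sample
    return sp_signal.decimate(x, int(round(q)), n=8, ftype="iir")


def mmse_features(
    recording: EpochedRecording,
    mask: CleanMask,
    n_scales: int = 20,
    target_samples: int = TARGET_SAMPLES,
    working_fs: float = WORKING_FS,
    m: int = 2,
    r_factor: float = 0.15,
) -> np.ndarray:
    """Multiscale entropy block: every other channel x ``n_scales``.

    Per kept channel the earliest clean epochs are concatenated,
    decimated to the working rate, and truncated to exactly
    ``target_samples``; sample entropy is computed at scales
    ``1..n_scales`` with r fixed from the scale-1 series.  Output is
    channel-major (channel 1 scales 1..20, channel 2 scales 1..20, ...),
    length ``ceil(C / 2) * n_scales`` — 1,280 for a 128-channel net.

    Channels with insufficient clean data fall back to whatever clean
    samples exist (all-zero features if none), with a warning.
    """
    kept_channels = np.arange(recording.n_channels)[::2]
    out = np.zeros(kept_channels.size * n_scales)
    q = int(round(recording.fs / working_fs)) if recording.fs != working_fs else 1
    for k, c in enumerate(kept_channels):
        clean_epochs = np.flatnonzero(mask.keep[c])
        if clean_epochs.size == 0:
            warnings.warn(
                f"channel {recording.channels[c]}: no clean epochs; "
                "multiscale features set to 0",
                stacklevel=2,
            )
            continue
        needed = math.ceil(target_samples * q / recording.n_samples) + 1
        series = recording.data[c, clean_epochs[:needed], :].ravel()
        series = _decimate(series, recording.fs, working_fs)
        if series.size < target_samples:
            warnings.warn(
                f"channel {recording.channels[c]}: only {series.size} clean "
                f"working-rate samples (target {target_samples})",
                stacklevel=2,
            )
        series = series[:target_samples]
        if series.size <= (m + 1) * n_scales:
            continue
        r = r_factor * series.std()
        for s in range(1, n_scales + 1):
            grained = coarse_grain(series, s)
            if grained.size <= m + 1:
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = sample_entropy(grained, m=m, r=r)
            out[k * n_scales + (s - 1)] = 0.0 if math.isnan(val) else val
    return out
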