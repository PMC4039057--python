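"""Robust ERP features: median waveforms, SSD, and partitioned variance.

All features derive from a subject's pooled median waveforms.  The
clean standard cells — every retained (channel, epoch) vector,
regardless of channel — are reduced to an elementwise median standard
response ``s_bar``; deviant cells give ``d_bar``; their difference
``delta = d_bar - s_bar`` is the per-subject difference waveform.  The
sum of signed differences (SSD) integrates ``delta`` over 24
equal-length partitions (50 ms each at the default geometry) and the
variance features summarise its variability over 12 coarser
partitions.  The 23-dimensional selected vector drops the four
pre-stimulus SSD partitions and keeps variance partitions 4-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CleanMask, EpochedRecording, ValidationError

__all__ = [
    "MedianWaveforms",
    "median_waveforms",
    "ssd_features",
    "variance_features",
    "select_features",
    "interval_ssd",
    "interval_ssd_group_test",
]

N_SSD_PARTITIONS = 24
N_VARIANCE_PARTITIONS = 12
#: 1-based SSD partitions retained after dropping the baseline (5..24)
SSD_KEEP = slice(4, 24)
#: 1-based variance partitions retained (4..6)
VARIANCE_KEEP = slice(3, 6)
N_SELECTED = 23


@dataclass
class MedianWaveforms:
    """Per-subject pooled median responses and their difference."""

    s_bar: np.ndarray
    d_bar: np.ndarray
    n_standard_vectors: int
    n_deviant_vectors: int

    @property
    def delta(self) -> np.ndarray:
        return self.d_bar - self.s_bar


def median_waveforms(
    recording: EpochedRecording, mask: CleanMask
) -> MedianWaveforms:
    """Elementwise medians of the pooled clean standard/deviant vectors.

    Cells are pooled across channels and epochs: with ~100 channels and
    hundreds of epochs, tens of thousands of vectors enter each median,
    which is what makes the statistic robust to the retained noise.
    """
    if mask.shape != recording.data.shape[:2]:
        raise ValidationError("mask shape does not match recording")
    dev = recording.is_deviant()
    out = {}
    for name, sel in (("standard", ~dev), ("deviant", dev)):
        cells = mask.keep[:, sel]
        vecs = recording.data[:, sel, :][cells]  # (n_clean, T)
        if vecs.shape[0] == 0:
            raise ValidationError(
                f"no clean {name} epoch-channels retained by the mask"
            )
        out[name] = (np.median(vecs, axis=0), vecs.shape[0])
    return MedianWaveforms(
        s_bar=out["standard"][0],
        d_bar=out["deviant"][0],
        n_standard_vectors=out["standard"][1],
        n_deviant_vectors=out["deviant"][1],
    )


def _partition(x: np.ndarray, n_partitions: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D difference waveform")
    if x.size % n_partitions != 0:
        raise ValidationError(
            f"waveform length {x.size} not divisible into {n_partitions} partitions"
        )
    return x.reshape(n_partitions, -1)


def ssd_features(
    delta: np.ndarray, n_partitions: int = N_SSD_PARTITIONS
) -> np.ndarray:
    """Sum of signed differences in equal contiguous partitions.

    Partition ``i`` (1-based) is the sum of ``delta`` over its i-th
    block of ``T / n_partitions`` samples — the (signed) area under the
    difference curve in that interval.
    """
    return _partition(delta, n_partitions).sum(axis=1)


def variance_features(
    delta: np.ndarray, n_partitions: int = N_VARIANCE_PARTITIONS
) -> np.ndarray:
    """Sample variance (n-1 divisor) of ``delta`` in equal partitions."""
    parts = _partition(delta, n_partitions)
    if parts.shape[1] < 2:
        raise ValidationError("variance partitions need >= 2 samples each")
    return parts.var(axis=1, ddof=1)


def select_features(ssd: np.ndarray, variance: np.ndarray) -> np.ndarray:
    """Concatenate SSD partitions 5-24 with variance partitions 4-6.

    The first four SSD partitions cover the 200 ms pre-stimulus
    baseline and are discarded; variance partitions 4-6 carry the
    post-stimulus group difference.  Output length is always 23.
    """
    ssd = np.asarray(ssd, dtype=np.float64)
    variance = np.asarray(variance, dtype=np.float64)
    if ssd.shape != (N_SSD_PARTITIONS,):
        raise ValidationError(f"expected {N_SSD_PARTITIONS} SSD values")
    if variance.shape != (N_VARIANCE_PARTITIONS,):
        raise ValidationError(f"expected {N_VARIANCE_PARTITIONS} variance values")
    return np.concatenate([ssd[SSD_KEEP], variance[VARIANCE_KEEP]])


def interval_ssd(
    delta: np.ndarray,
    fs: float,
    pre_stim_ms: float,
    intervals: list[tuple[float, float]] = (
        (0.0, 150.0),
        (150.0, 250.0),
        (250.0, 400.0),
        (400.0, 1000.0),
    ),
) -> np.ndarray:
    """SSD over arbitrary post-stimulus intervals (ms, half-open)."""
    delta = np.asarray(delta, dtype=np.float64)
    pre = int(round(pre_stim_ms * fs / 1000.0))
    out = np.empty(len(intervals))
    for k, (lo, hi) in enumerate(intervals):
        i0 = pre + int(round(lo * fs / 1000.0))
        i1 = pre + int(round(hi * fs / 1000.0))
        if i0 < 0 or i1 > delta.size or i0 >= i1:
            raise ValidationError(
                f"interval ({lo}, {hi}) ms outside the epoch"
            )
        out[k] = delta[i0:i1].sum()
    return out


def interval_ssd_group_test(
    deltas: list[np.ndarray],
    groups: list[str],
    fs: float,
    pre_stim_ms: float,
    intervals: list[tuple[float, float]] = (
        (0.0, 150.0),
        (150.0, 250.0),
        (250.0, 400.0),
        (400.0, 1000.0),
    ),
) -> pd.DataFrame:
    """Welch two-sample t-test of interval SSDs between the two groups.

    Returns one row per interval with the per-group means and the
    p-value.  Degenerate inputs (both groups constant) get p = 1.
    """
    values = np.stack(
        [interval_ssd(d, fs, pre_stim_ms, intervals) for d in deltas]
    )
    groups_arr = np.asarray(groups)
    names = np.unique(groups_arr)
    if names.size != 2:
        raise ValidationError("group test needs exactly two groups")
    a = values[groups_arr == names[0]]
    b = values[groups_arr == names[1]]
    rows = []
    for k, (lo, hi) in enumerate(intervals):
        if np.ptp(values[:, k]) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a[:, k], b[:, k], equal_var=False).pvalue)
        rows.append(
            {
                "interval_ms": (lo, hi),
                f"mean_{names[0]}": float(a[:, k].mean()),
                f"mean_{names[1]}": float(b[:, k].mean()),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
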