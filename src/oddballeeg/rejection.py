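"""Channel-by-epoch artifact rejection and its traditional comparator.

Rejection operates on individual ``(channel, epoch)`` cells rather than
whole epochs: a cell survives both an amplitude-threshold criterion and
a trend-line criterion, and the retained cells form the clean set P.
The traditional comparator keeps an epoch only when *every*
(non-blacklisted) channel is clean in it, which on noisy high-density
recordings can reject nearly everything.  Retention curves quantify the
difference, and the rejection topography compares per-channel rejection
rates between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CRIT_NONE,
    CRIT_THRESHOLD,
    CRIT_TRENDLINE,
    CleanMask,
    EpochedRecording,
    StudySet,
    ValidationError,
)

__all__ = [
    "RejectionConfig",
    "baseline_correct",
    "reject_threshold",
    "reject_trendline",
    "combine_masks",
    "reject_cells",
    "reject_channels_kurtosis",
    "traditional_reject",
    "retention_curve",
    "rejection_topography",
]


@dataclass
class RejectionConfig:
    """Bounds for the rejection criteria (all strictly positive).

    ``threshold_uv``: post-baseline absolute amplitude bound.
    ``trend_slope_uv_per_epoch``: least-squares slope bound with the
    time axis normalised so the whole epoch spans one unit.
    ``trend_min_r2``: minimum coefficient of determination for the
    trend criterion to fire.
    ``kurtosis_z``: channel-screening bound in SD units across channels.
    """

    threshold_uv: float = 100.0
    trend_slope_uv_per_epoch: float = 50.0
    trend_min_r2: float = 0.3
    kurtosis_z: float = 5.0

    def __post_init__(self) -> None:
        for f_name in (
            "threshold_uv",
            "trend_slope_uv_per_epoch",
            "trend_min_r2",
            "kurtosis_z",
        ):
            if getattr(self, f_name) <= 0:
                raise ValueError(f"{f_name} must be > 0")


def baseline_correct(recording: EpochedRecording) -> EpochedRecording:
    """Subtract each cell's mean over the pre-stimulus window."""
    if recording.pre_stim_ms <= 0:
        raise ValidationError("baseline correction requires pre_stim_ms > 0")
    pre = recording.pre_samples
    means = recording.data[:, :, :pre].mean(axis=2, keepdims=True)
    return recording.copy_with(data=recording.data - means)


def reject_threshold(
    recording: EpochedRecording, threshold_uv: float = 100.0
) -> CleanMask:
    """Reject cells whose absolute amplitude strictly exceeds the bound.

    Assumes the recording is baseline-corrected; a sample exactly at the
    bound is kept.
    """
    peak = np.abs(recording.data).max(axis=2)
    keep = ~(peak > threshold_uv)
    criteria = np.where(keep, CRIT_NONE, CRIT_THRESHOLD).astype(np.uint8)
    return CleanMask(keep, criteria)


def trendline_fit(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell OLS line fit against normalised time.

    ``data`` is (C, E, T); the time axis is scaled so the epoch spans
    one unit, making the slope directly comparable to a
    "uV per epoch" bound.  Returns (slope, r2), each (C, E).  Cells with
    zero variance get r2 = 0 (a flat epoch has nothing to reject).
    """
    C, E, T = data.shape
    u = np.arange(T) / (T - 1)
    u_c = u - u.mean()
    su = float(u_c @ u_c)
    y_mean = data.mean(axis=2, keepdims=True)
    y_c = data - y_mean
    slope = y_c @ u_c / su
    ss_tot = np.einsum("cet,cet->ce", y_c, y_c)
    ss_reg = slope**2 * su
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, ss_reg / ss_tot, 0.0)
    return slope, r2


def reject_trendline(
    recording: EpochedRecording,
    slope_bound: float = 50.0,
    r2_min: float = 0.3,
) -> CleanMask:
    """Reject cells with a strong, well-fitting linear trend.

    A cell is rejected when |slope| > ``slope_bound`` (uV per epoch,
    either direction) *and* R^2 >= ``r2_min``.
    """
    if recording.n_samples < 3:
        raise ValidationError("trend-line rejection needs T >= 3")
    slope, r2 = trendline_fit(recording.data)
    reject = (np.abs(slope) > slope_bound) & (r2 >= r2_min)
    keep = ~reject
    criteria = np.where(keep, CRIT_NONE, CRIT_TRENDLINE).astype(np.uint8)
    return CleanMask(keep, criteria)


def combine_masks(a: CleanMask, b: CleanMask) -> CleanMask:
    """Cellwise AND: a cell survives only if both criteria kept it."""
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    keep = a.keep & b.keep
    criteria = (a.criteria | b.criteria).astype(np.uint8)
    criteria[keep] = CRIT_NONE
    return CleanMask(keep, criteria)


def reject_cells(
    recording: EpochedRecording, config: RejectionConfig | None = None
) -> CleanMask:
    """Threshold + trend-line rejection combined (the main pipeline)."""
    config = config or RejectionConfig()
    return combine_masks(
        reject_threshold(recording, config.threshold_uv),
        reject_trendline(
            recording, config.trend_slope_uv_per_epoch, config.trend_min_r2
        ),
    )


def reject_channels_kurtosis(
    recording: EpochedRecording, z_bound: float = 5.0
) -> dict[int, set[str]]:
    """Per-block channel screening by excess kurtosis.

    Within each block, the excess (Fisher) kurtosis of every channel's
    pooled samples is standardised across the block's channels; channels
    with |z| > ``z_bound`` are flagged.  Returns block -> rejected
    channel ids.
    """
    if recording.n_channels < 2:
        raise ValidationError("kurtosis screening needs >= 2 channels")
    out: dict[int, set[str]] = {}
    for b in recording.blocks:
        sel = recording.block_of == b
        pooled = recording.data[:, sel, :].reshape(recording.n_channels, -1)
        k = stats.kurtosis(pooled, axis=1, fisher=True, bias=True)
        sd = k.std()
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(
                f"block {b}: zero spread in channel kurtosis; no rejections",
                stacklevel=2,
            )
            out[int(b)] = set()
            continue
        z = (k - k.mean()) / sd
        out[int(b)] = {
            recording.channels[c] for c in np.flatnonzero(np.abs(z) > z_bound)
        }
    return out


def traditional_reject(
    recording: EpochedRecording,
    threshold_uv: float = 100.0,
    channel_blacklist: set[str] | None = None,
) -> np.ndarray:
    """Whole-epoch rejection: keep an epoch only if every channel passes.

    ``channel_blacklist`` (e.g. from kurtosis screening) removes
    channels from consideration before the all-channels criterion is
    applied.  Returns a boolean (E,) kept-epoch vector.
    """
    mask = reject_threshold(recording, threshold_uv)
    keep_cells = mask.keep
    if channel_blacklist:
        rows = np.array(
            [c not in channel_blacklist for c in recording.channels]
        )
        keep_cells = keep_cells[rows]
    return keep_cells.all(axis=0)


def retention_curve(
    recording: EpochedRecording,
    thresholds: list[float] | np.ndarray,
    channel_blacklist: set[str] | None = None,
) -> pd.DataFrame:
    """Retained proportion per block vs threshold, both methods.

    For the channel-by-epoch method the proportion is over cells; for
    the traditional method it is over whole epochs.  Returns a tidy
    frame with columns ``threshold``, ``method``, ``median``, ``q1``,
    ``q3`` summarising across blocks.
    """
    rows = []
    blocks = recording.blocks
    for t in thresholds:
        mask = reject_threshold(recording, t)
        kept_epochs = traditional_reject(recording, t, channel_blacklist)
        cell_props = [
            mask.keep[:, recording.block_of == b].mean() for b in blocks
        ]
        trad_props = [
            kept_epochs[recording.block_of == b].mean() for b in blocks
        ]
        for method, props in (
            ("channel_by_epoch", cell_props),
            ("traditional", trad_props),
        ):
            q1, med, q3 = np.percentile(props, [25, 50, 75])
            rows.append(
                {
                    "threshold": float(t),
                    "method": method,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TopographyReport:
    """Study-wide rejection topography.

    ``channel_counts``: total rejected cells per channel over the study.
    ``periocular``: per periocular channel, the median per-subject
    rejection proportion in each group and a two-sample Kruskal-Wallis
    p-value for the group difference.
    """

    channel_counts: pd.Series
    periocular: pd.DataFrame = field(default_factory=pd.DataFrame)


def rejection_topography(
    study: StudySet, masks: list[CleanMask]
) -> TopographyReport:
    """Aggregate per-channel rejection counts and test periocular sites."""
    if len(masks) != len(study):
        raise ValidationError("one mask per subject required")
    groups = np.asarray(study.group_labels)
    for g in np.unique(groups):
        if (groups == g).sum() == 0:  # pragma: no cover - defensive
            raise ValidationError(f"group {g} has no subjects")
    if len(np.unique(groups)) < 2:
        raise ValidationError("rejection topography needs two groups")
    channels = study.recordings[0].channels
    counts = np.zeros(len(channels))
    # per-subject rejection proportion per channel
    props = np.stack([1.0 - m.keep.mean(axis=1) for m in masks])
    for m in masks:
        counts += (~m.keep).sum(axis=1)
    rows = []
    g1, g2 = np.unique(groups)[:2]
    perioc = study.recordings[0].periocular
    lut = {c: i for i, c in enumerate(channels)}
    for ch in perioc:
        i = lut[ch]
        a = props[groups == g1, i]
        b = props[groups == g2, i]
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # all-tied samples: no evidence of a difference
        else:
            p = float(stats.kruskal(a, b).pvalue)
        rows.append(
            {
                "channel": ch,
                f"median_{g1}": float(np.median(a)),
                f"median_{g2}": float(np.median(b)),
                "p_value": p,
            }
        )
    return TopographyReport(
        channel_counts=pd.Series(counts, index=channels, name="rejected_cells"),
        periocular=pd.DataFrame(rows),
    )
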