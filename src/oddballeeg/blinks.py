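"""ICA-based eye-blink identification, removal and counting.

Each recording block is concatenated across epochs, reduced to ten
principal components, and unmixed with FastICA.  Blink components are
scored by how strongly their channel-space mixing weights load on the
flagged periocular sites relative to the whole montage (ties broken by
the sub-5 Hz power fraction of the activation, since blinks are slow).
Blink *removal* subtracts the top-scored components' contributions;
blink *counting* thresholds the top component's activation per epoch at
a subject-specific multiple of its standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .containers import EpochedRecording, ValidationError

__all__ = [
    "Decomposition",
    "decompose",
    "decompose_blocks",
    "score_blink_components",
    "remove_blinks",
    "count_blinks",
]

N_COMPONENTS = 10


@dataclass
class Decomposition:
    """PCA-then-ICA decomposition of one block's continuous data.

    ``mixing`` (C x K) maps component activations back to channels;
    ``activations`` (K x N) are the component time courses;
    ``channel_means`` (C,) is the removed per-channel mean.
    Reconstruction from all components reproduces the PCA rank-K
    approximation of the input.
    """

    mixing: np.ndarray
    activations: np.ndarray
    channel_means: np.ndarray
    frontal_scores: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self, exclude: list[int] | None = None) -> np.ndarray:
        """Channel-space signal from all components except ``exclude``."""
        keep = np.ones(self.n_components, dtype=bool)
        if exclude:
            keep[list(exclude)] = False
        return (
            self.mixing[:, keep] @ self.activations[keep]
            + self.channel_means[:, None]
        )


def decompose(
    block: np.ndarray, n_components: int = N_COMPONENTS, seed: int = 0
) -> Decomposition:
    """PCA to ``n_components`` dimensions, then FastICA on the scores.

    ``block`` is a continuous (C, N) array (a block's epochs
    concatenated in time, baseline-corrected).  Deterministic for a
    fixed seed.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2:
        raise ValidationError("block must be 2-D (C, N)")
    C, N = block.shape
    if N <= C:
        raise ValidationError("need more time samples than channels")
    pca = PCA(n_components=n_components, random_state=seed)
    try:
        scores = pca.fit_transform(block.T)  # (N, K)
    except ValueError as exc:
        raise ValidationError(
            f"cannot extract {n_components} components; try a lower K"
        ) from exc
    if pca.n_components_ < n_components or np.any(
        pca.explained_variance_ <= 1e-12
    ):
        raise ValidationError(
            f"data rank below {n_components}; try a lower K"
        )
    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        whiten="unit-variance",
        max_iter=1000,
    )
    sources = ica.fit_transform(scores)  # (N, K)
    # channel-space mixing: X ~= mean + mixing @ sources.T
    mixing = pca.components_.T @ ica.mixing_  # (C, K)
    return Decomposition(
        mixing=mixing,
        activations=sources.T,
        channel_means=pca.mean_,
    )


def _concat_block(recording: EpochedRecording, block: int) -> np.ndarray:
    sel = recording.block_of == block
    C = recording.n_channels
    return recording.data[:, sel, :].reshape(C, -1)


def decompose_blocks(
    recording: EpochedRecording, n_components: int = N_COMPONENTS, seed: int = 0
) -> dict[int, Decomposition]:
    """Run :func:`decompose` on every block of an epoched recording.

    The component count is capped at the channel count so small montages
    remain decomposable.
    """
    k = min(n_components, recording.n_channels)
    return {
        int(b): decompose(_concat_block(recording, b), k, seed)
        for b in recording.blocks
    }


def _low_freq_fraction(activation: np.ndarray, fs: float, f_cut: float = 5.0):
    spec = np.abs(np.fft.rfft(activation)) ** 2
    freqs = np.fft.rfftfreq(activation.size, d=1.0 / fs)
    total = spec[1:].sum()
    if total == 0:
        return 0.0
    return float(spec[1:][freqs[1:] < f_cut].sum() / total)


def score_blink_components(
    dec: Decomposition,
    periocular_idx: np.ndarray,
    fs: float | None = None,
) -> list[int]:
    """Rank components by blink-likeness, most blink-like first.

    Score = mean |mixing weight| over periocular channels divided by the
    mean over all channels; exact ties fall back to the sub-5 Hz power
    fraction of the activation (requires ``fs``).
    """
    periocular_idx = np.asarray(periocular_idx, dtype=np.intp)
    if periocular_idx.size == 0:
        raise ValidationError("no periocular channels flagged in the montage")
    absw = np.abs(dec.mixing)
    overall = absw.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(
            overall > 0, absw[periocular_idx].mean(axis=0) / overall, 0.0
        )
    if fs is not None:
        lf = np.array(
            [_low_freq_fraction(a, fs) for a in dec.activations]
        )
    else:
        lf = np.zeros(dec.n_components)
    order = sorted(
        range(dec.n_components), key=lambda k: (-scores[k], -lf[k], k)
    )
    dec.frontal_scores = scores
    return order


def remove_blinks(
    recording: EpochedRecording,
    decompositions: dict[int, Decomposition] | None = None,
    k_max: int = 2,
    seed: int = 0,
    min_score: float = 1.5,
) -> EpochedRecording:
    """Subtract up to ``k_max`` top blink-scored components per block.

    Only components whose periocular score reaches ``min_score`` count
    as blink-like (manual identification kept *up to* two components,
    not always two); on blink-free data nothing qualifies and the
    signal passes through unchanged.  Non-blink components are
    untouched.
    """
    if k_max < 0:
        raise ValidationError("k_max must be >= 0")
    if k_max == 0:
        return recording.copy_with(data=recording.data.copy())
    if decompositions is None:
        decompositions = decompose_blocks(recording, seed=seed)
    perioc = recording.periocular_idx
    data = recording.data.copy()
    T = recording.n_samples
    for b in recording.blocks:
        dec = decompositions[int(b)]
        order = score_blink_components(dec, perioc, recording.fs)
        blink = [
            k for k in order[:k_max] if dec.frontal_scores[k] >= min_score
        ]
        if not blink:
            continue
        contribution = dec.mixing[:, blink] @ dec.activations[blink]
        sel = np.flatnonzero(recording.block_of == b)
        contribution = contribution.reshape(recording.n_channels, sel.size, T)
        data[:, sel, :] -= contribution
    return recording.copy_with(data=data)


@dataclass
class BlinkCount:
    """Per-epoch blink flags and the subject's blink frequency."""

    flags: np.ndarray
    frequency: float
    threshold: float

    @property
    def n_blinks(self) -> int:
        return int(self.flags.sum())


def count_blinks(
    recording: EpochedRecording,
    decompositions: dict[int, Decomposition] | None = None,
    sd_multiplier: float = 3.0,
    seed: int = 0,
    component_override: dict[int, int] | None = None,
    smooth_ms: float = 50.0,
) -> BlinkCount:
    """Flag epochs whose blink-component activation exceeds a threshold.

    The top blink-scored component of each block (overridable per block
    via ``component_override``) is sign-oriented so its periocular
    loading is positive, concatenated across the subject's blocks,
    zero-meaned, and compared against ``sd_multiplier`` x SD; an epoch
    is flagged when its maximum activation exceeds the threshold.

    Blinks last hundreds of milliseconds, so the activation is smoothed
    with a ``smooth_ms`` moving average first; this attenuates
    single-sample noise excursions that would otherwise be picked up by
    the per-epoch maximum.
    """
    if decompositions is None:
        decompositions = decompose_blocks(recording, seed=seed)
    perioc = recording.periocular_idx
    T = recording.n_samples
    per_epoch = np.empty((recording.n_epochs, T))
    for b in recording.blocks:
        dec = decompositions[int(b)]
        if component_override and int(b) in component_override:
            k = component_override[int(b)]
        else:
            k = score_blink_components(dec, perioc, recording.fs)[0]
        sign = np.sign(dec.mixing[perioc, k].mean())
        act = dec.activations[k] * (sign if sign != 0 else 1.0)
        # scale to channel space so blocks are comparable
        act = act * np.abs(dec.mixing[perioc, k]).mean()
        win = max(1, int(round(smooth_ms * recording.fs / 1000.0)))
        if win > 1:
            act = np.convolve(act, np.full(win, 1.0 / win), mode="same")
        sel = np.flatnonzero(recording.block_of == b)
        per_epoch[sel] = act.reshape(sel.size, T)
    per_epoch -= per_epoch.mean()
    sd = per_epoch.std()
    if sd == 0:
        warnings.warn("blink component has zero variance; zero blinks", stacklevel=2)
        return BlinkCount(
            flags=np.zeros(recording.n_epochs, dtype=bool),
            frequency=0.0,
            threshold=0.0,
        )
    threshold = sd_multiplier * sd
    flags = per_epoch.max(axis=1) > threshold
    return BlinkCount(
        flags=flags,
        frequency=float(flags.mean()),
        threshold=float(threshold),
    )
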