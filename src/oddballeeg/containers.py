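"""Core in-memory containers for epoched oddball EEG.

The central object is :class:`EpochedRecording`, a ``channels x epochs x
samples`` array in microvolts together with per-epoch stimulus labels
(``standard`` / ``deviant``), block membership and montage metadata.
Artifact rejection produces a :class:`CleanMask` over the same
``channels x epochs`` grid, and a cohort of subjects is a
:class:`StudySet`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STANDARD",
    "DEVIANT",
    "CRIT_NONE",
    "CRIT_THRESHOLD",
    "CRIT_TRENDLINE",
    "CRIT_BOTH",
    "EpochedRecording",
    "CleanMask",
    "StudySet",
]

STANDARD = "standard"
DEVIANT = "deviant"

# Rejection-criterion codes stored per (channel, epoch) cell.
CRIT_NONE = 0
CRIT_THRESHOLD = 1
CRIT_TRENDLINE = 2
CRIT_BOTH = 3

_CRIT_NAMES = {
    CRIT_NONE: "none",
    CRIT_THRESHOLD: "threshold",
    CRIT_TRENDLINE: "trendline",
    CRIT_BOTH: "both",
}


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


class FormatError(ValueError):
    """Raised when an on-disk container is malformed (missing fields)."""


@dataclass
class EpochedRecording:
    """Epoched multichannel EEG in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(C, E, T)``: channels x epochs x time samples, uV.
    fs
        Sampling rate in Hz.
    pre_stim_ms
        Duration of the pre-stimulus baseline included at the start of
        every epoch, in milliseconds.
    labels
        Per-epoch stimulus class, ``"standard"`` or ``"deviant"``.
    block_of
        Per-epoch recording-block index (epochs are acquired in blocks,
        typically of 400 stimuli).
    channels
        Ordered channel identifiers, length ``C``.
    periocular
        Subset of ``channels`` flagged as periocular/frontal (eye-blink
        dominated) sites.
    subject_id
        Opaque subject identifier.
    group
        Optional diagnostic group, ``"ASD"`` or ``"TD"``.
    positions
        Optional ``(C, 2)`` schematic sensor positions on the unit disk
        (nose at +y); used only for blink topography and plotting.
    """

    data: np.ndarray
    fs: float
    pre_stim_ms: float
    labels: np.ndarray
    block_of: np.ndarray
    channels: list[str]
    periocular: list[str] = field(default_factory=list)
    subject_id: str = ""
    group: str | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.block_of = np.asarray(self.block_of, dtype=np.int64)
        self.channels = [str(c) for c in self.channels]
        self.periocular = [str(c) for c in self.periocular]
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.float64)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (C, E, T); got shape {self.data.shape}"
            )
        C, E, T = self.data.shape
        if min(C, E, T) < 1:
            raise ValidationError("C, E and T must all be >= 1")
        if len(self.channels) != C:
            raise ValidationError(
                f"{len(self.channels)} channel ids for {C} channels"
            )
        if self.labels.shape != (E,):
            raise ValidationError(
                f"labels has length {self.labels.size}, expected E={E}"
            )
        if self.block_of.shape != (E,):
            raise ValidationError(
                f"block_of has length {self.block_of.size}, expected E={E}"
            )
        bad = set(self.labels) - {STANDARD, DEVIANT}
        if bad:
            raise ValidationError(f"unknown stimulus labels: {sorted(bad)}")
        missing = set(self.periocular) - set(self.channels)
        if missing:
            raise ValidationError(
                f"periocular ids not in montage: {sorted(missing)}"
            )
        if self.positions is not None and self.positions.shape != (C, 2):
            raise ValidationError(
                f"positions must be (C, 2); got {self.positions.shape}"
            )
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.pre_stim_ms < 0:
            raise ValidationError("pre_stim_ms must be >= 0")

    # -- derived geometry ----------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def pre_samples(self) -> int:
        """Number of samples in the pre-stimulus baseline."""
        return int(round(self.pre_stim_ms * self.fs / 1000.0))

    @property
    def post_stim_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0 - self.pre_stim_ms

    @property
    def periocular_idx(self) -> np.ndarray:
        """Indices of flagged periocular channels in montage order."""
        lut = {c: i for i, c in enumerate(self.channels)}
        return np.array([lut[c] for c in self.periocular], dtype=np.intp)

    def is_deviant(self) -> np.ndarray:
        return np.asarray([lab == DEVIANT for lab in self.labels])

    @property
    def blocks(self) -> np.ndarray:
        return np.unique(self.block_of)

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset (onset = 0)."""
        return (np.arange(self.n_samples) - self.pre_samples) / self.fs * 1000.0

    def copy_with(self, **overrides) -> "EpochedRecording":
        kwargs = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
        }
        kwargs.update(overrides)
        return EpochedRecording(**kwargs)


@dataclass
class CleanMask:
    """Retained (channel, epoch) cells after channel-by-epoch rejection.

    ``keep[c, e]`` is True when that cell survived; ``criteria[c, e]``
    records which criterion rejected it (``CRIT_*`` codes).  The retained
    cells are the set P of clean pairs; restricted to standard or deviant
    epochs they yield the pooled vector sets the median waveforms are
    computed from.
    """

    keep: np.ndarray
    criteria: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 2:
            raise ValidationError("keep must be a (C, E) grid")
        if self.criteria is None:
            self.criteria = np.where(self.keep, CRIT_NONE, CRIT_THRESHOLD)
        self.criteria = np.asarray(self.criteria, dtype=np.uint8)
        if self.criteria.shape != self.keep.shape:
            raise ValidationError("criteria shape must match keep")
        if np.any((self.criteria == CRIT_NONE) != self.keep):
            raise ValidationError(
                "keep[c,e] must be False exactly where a criterion fired"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.keep.shape

    @property
    def n_cells(self) -> int:
        return self.keep.size

    @property
    def n_rejected(self) -> int:
        return int(self.keep.size - self.keep.sum())

    @property
    def retained_fraction(self) -> float:
        return float(self.keep.mean())

    def criteria_log(self) -> np.ndarray:
        """Criterion names per cell ('none'|'threshold'|'trendline'|'both')."""
        out = np.empty(self.keep.shape, dtype=object)
        for code, name in _CRIT_NAMES.items():
            out[self.criteria == code] = name
        return out

    @classmethod
    def all_keep(cls, shape: tuple[int, int]) -> "CleanMask":
        return cls(np.ones(shape, dtype=bool))


@dataclass
class StudySet:
    """A cohort of subjects with group (and optionally sex) labels."""

    recordings: list[EpochedRecording]
    group_labels: list[str]
    sex: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.recordings)
        if len(self.group_labels) != n:
            raise ValidationError("one group label per recording required")
        if self.sex is not None and len(self.sex) != n:
            raise ValidationError("sex, when present, needs one entry per recording")

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.recordings]

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.group_labels:
            out[g] = out.get(g, 0) + 1
        return out


def subset_by_sex(study: StudySet, sex: str) -> StudySet:
    """Restrict a cohort to subjects of one sex, preserving order.

    Supports the males-only control analysis used to rule out the
    classifier exploiting the sex imbalance between groups.
    """
    if study.sex is None:
        raise ValidationError("study has no sex metadata")
    idx = [i for i, s in enumerate(study.sex) if s == sex]
    return StudySet(
        recordings=[study.recordings[i] for i in idx],
        group_labels=[study.group_labels[i] for i in idx],
        sex=[study.sex[i] for i in idx],
    )
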