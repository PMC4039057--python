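"""Reading and writing epoched recordings.

One HDF5 file per subject with datasets ``data``, ``labels``,
``block_of``, ``channels`` (and optionally ``positions``), plus root
attributes ``fs``, ``pre_stim_ms``, ``subject_id``, ``group`` and
``periocular``.  Continuous input is supported either as a raw
``(C, N)`` array plus an event list, or as an EDF file with a
tab-separated event table (columns ``sample_index``, ``class``).
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .containers import EpochedRecording, FormatError, ValidationError

__all__ = [
    "write_epoched",
    "read_epoched",
    "epoch_continuous",
    "read_event_table",
    "read_continuous_edf",
]

_REQUIRED_DATASETS = ("data", "labels", "block_of", "channels")
_REQUIRED_ATTRS = ("fs", "pre_stim_ms")


def write_epoched(recording: EpochedRecording, path: str | os.PathLike) -> None:
    """Write one subject's epoched recording to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset(
            "labels", data=np.asarray(recording.labels, dtype=str_dt)
        )
        f.create_dataset("block_of", data=recording.block_of)
        f.create_dataset(
            "channels", data=np.asarray(recording.channels, dtype=str_dt)
        )
        if recording.positions is not None:
            f.create_dataset("positions", data=recording.positions)
        f.attrs["fs"] = recording.fs
        f.attrs["pre_stim_ms"] = recording.pre_stim_ms
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["group"] = recording.group if recording.group is not None else ""
        f.attrs["periocular"] = np.asarray(recording.periocular, dtype=str_dt)


def read_epoched(path: str | os.PathLike) -> EpochedRecording:
    """Read a subject container written by :func:`write_epoched`.

    Raises
    ------
    FormatError
        If a required dataset or attribute is missing.
    ValidationError
        If the stored arrays violate the container invariants.
    """
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise FormatError(f"container missing dataset '{name}'")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"container missing attribute '{name}'")
        group = str(f.attrs.get("group", ""))
        return EpochedRecording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            pre_stim_ms=float(f.attrs["pre_stim_ms"]),
            labels=np.array([s.decode() if isinstance(s, bytes) else str(s)
                             for s in f["labels"][()]], dtype=object),
            block_of=f["block_of"][()],
            channels=[s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["channels"][()]],
            periocular=[s.decode() if isinstance(s, bytes) else str(s)
                        for s in f.attrs.get("periocular", [])],
            subject_id=str(f.attrs.get("subject_id", "")),
            group=group or None,
            positions=f["positions"][()] if "positions" in f else None,
        )


def epoch_continuous(
    signal: np.ndarray,
    events: list[tuple[int, str]],
    fs: float,
    pre_stim_ms: float,
    post_stim_ms: float,
    *,
    channels: list[str] | None = None,
    block_of: np.ndarray | None = None,
    **recording_kwargs,
) -> EpochedRecording:
    """Cut a continuous ``(C, N)`` signal into stimulus-locked epochs.

    Epoch windows are half-open ``[onset - pre, onset + post)`` with
    0-based sample indexing: epoch ``e`` sample ``k`` equals
    ``signal[:, onset_e - pre_samples + k]``.

    Raises
    ------
    ValidationError
        If any event window falls outside the signal, listing the
        offending events.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2:
        raise ValidationError("signal must be 2-D (C, N)")
    C, N = signal.shape
    pre = int(round(pre_stim_ms * fs / 1000.0))
    post = int(round(post_stim_ms * fs / 1000.0))
    T = pre + post
    onsets = np.array([int(e[0]) for e in events], dtype=np.int64)
    labels = np.array([str(e[1]) for e in events], dtype=object)
    bad = [(int(o), lab) for o, lab in zip(onsets, labels)
           if o - pre < 0 or o + post > N]
    if bad:
        raise ValidationError(f"event windows outside signal: {bad}")
    data = np.empty((C, len(events), T))
    for e, onset in enumerate(onsets):
        data[:, e, :] = signal[:, onset - pre : onset + post]
    if channels is None:
        channels = [f"E{i + 1}" for i in range(C)]
    if block_of is None:
        block_of = np.zeros(len(events), dtype=np.int64)
    return EpochedRecording(
        data=data,
        fs=fs,
        pre_stim_ms=pre_stim_ms,
        labels=labels,
        block_of=block_of,
        channels=channels,
        **recording_kwargs,
    )


def read_event_table(path: str | os.PathLike) -> list[tuple[int, str]]:
    """Read a tab-separated event table (``sample_index``, ``class``)."""
    table = pd.read_csv(path, sep="\t")
    for col in ("sample_index", "class"):
        if col not in table.columns:
            raise FormatError(f"event table missing column '{col}'")
    return list(zip(table["sample_index"].astype(int), table["class"].astype(str)))


def read_continuous_edf(
    edf_path: str | os.PathLike,
    events_path: str | os.PathLike,
    pre_stim_ms: float,
    post_stim_ms: float,
    **kwargs,
) -> EpochedRecording:
    """Read a continuous EDF recording plus an event table and epoch it.

    Requires the optional ``mne`` dependency. Channel values are
    converted from volts (mne's internal unit) to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF input requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    signal_uv = raw.get_data() * 1e6
    events = read_event_table(events_path)
    return epoch_continuous(
        signal_uv,
        events,
        fs=float(raw.info["sfreq"]),
        pre_stim_ms=pre_stim_ms,
        post_stim_ms=post_stim_ms,
        channels=list(raw.ch_names),
        **kwargs,
    )
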