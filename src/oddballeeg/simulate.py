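"""Synthetic auditory-oddball EEG cohorts.

Emulates the study design the analysis assumes: a high-density sensor
net, blocks of 400 stimuli with an 85/15 standard/deviant split and at
least four standards flanking every deviant, 1.2 s epochs with a 200 ms
pre-stimulus baseline, pink (1/f) background noise with a shared
component across channels, and injected artifacts — frontal eye blinks
with a group-dependent (and deviant-boosted) rate, slow drifts, and
spikes.  The group effect of interest is a more positive
deviant-minus-standard difference waveform for ASD subjects in the
0-200 ms and 400-1000 ms post-stimulus windows.

Every injection is recorded in a :class:`GroundTruth` so recovery tests
can compare what the pipeline reports against what was actually put in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DEVIANT, STANDARD, EpochedRecording, StudySet

__all__ = [
    "ErpComponent",
    "SimulationConfig",
    "GroundTruth",
    "make_schedule",
    "make_montage",
    "erp_templates",
    "pink_noise",
    "simulate_subject",
    "simulate_study",
]


@dataclass(frozen=True)
class ErpComponent:
    """A Gaussian bump in the ERP template.

    ``profile`` selects the scalp weighting: ``"frontal"`` decays with
    distance from the periocular sites, ``"central"`` from the vertex,
    ``"broad"`` is uniform.
    """

    latency_ms: float
    width_ms: float
    amplitude_uv: float
    profile: str = "central"


def _default_standard_components() -> list[ErpComponent]:
    # P1 / N1 / P2-like obligatory auditory response.
    return [
        ErpComponent(80.0, 25.0, 2.5, "central"),
        ErpComponent(120.0, 35.0, -3.5, "central"),
        ErpComponent(250.0, 70.0, 3.0, "broad"),
    ]


def _default_deviant_extra() -> list[ErpComponent]:
    # Mismatch-negativity-like deflection plus a P3a novelty response,
    # shared by both groups.
    return [
        ErpComponent(160.0, 45.0, -1.5, "frontal"),
        ErpComponent(350.0, 80.0, 2.0, "broad"),
    ]


@dataclass
class SimulationConfig:
    """Cohort-level generator settings (amplitudes in uV, times in ms)."""

    n_asd: int = 19
    n_td: int = 30
    n_channels: int = 128
    fs: float = 1000.0
    pre_stim_ms: float = 200.0
    post_stim_ms: float = 1000.0
    blocks_per_subject: int = 2
    epochs_per_block: int = 400
    deviant_fraction: float = 0.15
    min_gap: int = 4
    erp_components: list[ErpComponent] = field(
        default_factory=_default_standard_components
    )
    deviant_components: list[ErpComponent] = field(
        default_factory=_default_deviant_extra
    )
    #: extra amplitude added to the ASD deviant template inside the
    #: 0-200 ms and 400-1000 ms post-stimulus windows
    asd_deviant_boost: float = 2.5
    noise_sd: float = 15.0
    noise_shared_mix: float = 0.3
    blink_rate_asd: float = 0.30
    blink_rate_td: float = 0.12
    #: blink probability multiplier on deviant epochs (novelty-evoked
    #: blinking; this is what lets blink rate leak into the
    #: deviant-minus-standard difference waveform)
    blink_deviant_multiplier: float = 3.0
    blink_amplitude: float = 90.0
    blink_latency_ms: float = 300.0
    blink_width_ms: float = 55.0
    drift_prob: float = 0.02
    drift_slope: float = 80.0
    spike_prob: float = 0.01
    spike_amplitude: float = 150.0
    n_periocular: int = 7
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.deviant_fraction <= 1.0:
            raise ValueError("deviant_fraction must be in [0, 1]")
        for name in ("blink_rate_asd", "blink_rate_td", "drift_prob", "spike_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("noise_sd", "blink_amplitude", "spike_amplitude"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_channels < 1 or self.epochs_per_block < 1:
            raise ValueError("n_channels and epochs_per_block must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_stim_ms + self.post_stim_ms) * self.fs / 1000.0))


@dataclass
class GroundTruth:
    """Record of every injection made while simulating one subject."""

    #: (block, global epoch index) pairs where a blink was injected
    blink_epochs: set[tuple[int, int]]
    #: (channel, epoch) -> artifact kind ("drift" | "spike")
    injected_artifacts: dict[tuple[int, int], str]
    #: noise-free per-channel templates, keys "standard" and "deviant"
    templates: dict[str, np.ndarray]

    @property
    def n_blinks(self) -> int:
        return len(self.blink_epochs)


# ---------------------------------------------------------------------------
# stimulus schedule


def make_schedule(
    n_epochs: int,
    deviant_fraction: float,
    min_gap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random oddball label sequence honouring the flanking constraint.

    Exactly ``round(n_epochs * deviant_fraction)`` deviants; every
    deviant is preceded and followed by at least ``min_gap`` standards
    (so deviants are pairwise separated by >= ``min_gap`` standards and
    the sequence starts and ends with >= ``min_gap`` standards).
    """
    n_dev = int(round(n_epochs * deviant_fraction))
    if n_dev == 0:
        return np.array([STANDARD] * n_epochs, dtype=object)
    n_std = n_epochs - n_dev
    slack = n_std - min_gap * (n_dev + 1)
    if slack < 0:
        raise ValueError(
            f"no schedule with {n_dev} deviants among {n_epochs} epochs "
            f"satisfies a flanking gap of {min_gap}"
        )
    # distribute the surplus standards uniformly at random over the
    # n_dev + 1 inter-deviant slots
    extra = rng.multinomial(slack, np.full(n_dev + 1, 1.0 / (n_dev + 1)))
    labels: list[str] = []
    for i in range(n_dev):
        labels.extend([STANDARD] * (min_gap + int(extra[i])))
        labels.append(DEVIANT)
    labels.extend([STANDARD] * (min_gap + int(extra[n_dev])))
    return np.array(labels, dtype=object)


# ---------------------------------------------------------------------------
# montage and templates


def make_montage(n_channels: int, n_periocular: int = 7):
    """Schematic sensor layout on the unit disk (nose at +y).

    Channels are placed on a golden-angle spiral; the ``n_periocular``
    channels closest to the front rim are flagged as periocular.  No
    attempt is made at a realistic 10-20 geometry — only the
    frontal/central/perimeter distinction matters downstream.
    """
    idx = np.arange(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt((idx + 0.5) / n_channels)
    theta = golden * idx
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    channels = [f"E{i + 1}" for i in range(n_channels)]
    front = np.array([0.0, 1.0])
    d_front = np.linalg.norm(pos - front, axis=1)
    perioc_idx = np.argsort(d_front)[:n_periocular]
    periocular = [channels[i] for i in sorted(perioc_idx)]
    return channels, periocular, pos


def _profile_weights(profile: str, pos: np.ndarray) -> np.ndarray:
    front = np.array([0.0, 1.0])
    if profile == "frontal":
        d = np.linalg.norm(pos - front, axis=1)
        return np.exp(-(d**2) / (2 * 0.35**2))
    if profile == "central":
        d = np.linalg.norm(pos, axis=1)
        return np.exp(-(d**2) / (2 * 0.55**2))
    if profile == "broad":
        return np.full(pos.shape[0], 0.8)
    raise ValueError(f"unknown scalp profile '{profile}'")


def _boost_window(t_ms: np.ndarray, lo: float, hi: float, ramp: float = 50.0):
    """Smooth indicator of [lo, hi] ms with raised-cosine edges."""
    w = np.zeros_like(t_ms)
    inside = (t_ms >= lo + ramp) & (t_ms <= hi - ramp)
    w[inside] = 1.0
    rise = (t_ms >= lo) & (t_ms < lo + ramp)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - lo) / ramp))
    fall = (t_ms > hi - ramp) & (t_ms <= hi)
    w[fall] = 0.5 * (1 - np.cos(np.pi * (hi - t_ms[fall]) / ramp))
    return w


def erp_templates(
    config: SimulationConfig, group: str, pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-channel (C, T) standard and deviant templates."""
    T = config.n_samples
    t_ms = (np.arange(T) - round(config.pre_stim_ms * config.fs / 1000.0)) \
        / config.fs * 1000.0
    C = pos.shape[0]

    def render(components: list[ErpComponent]) -> np.ndarray:
        out = np.zeros((C, T))
        for comp in components:
            bump = comp.amplitude_uv * np.exp(
                -((t_ms - comp.latency_ms) ** 2) / (2 * comp.width_ms**2)
            )
            out += np.outer(_profile_weights(comp.profile, pos), bump)
        return out

    standard = render(config.erp_components)
    deviant = standard + render(config.deviant_components)
    if group == "ASD" and config.asd_deviant_boost != 0.0:
        win = _boost_window(t_ms, 0.0, 200.0) + _boost_window(t_ms, 400.0, 1000.0)
        deviant = deviant + config.asd_deviant_boost * np.outer(
            _profile_weights("broad", pos) / 0.8, win
        )
    return standard, deviant


# ---------------------------------------------------------------------------
# noise


def pink_noise(n_samples: int, rng: np.random.Generator, sd: float = 1.0):
    """1/f-power noise by spectral shaping of white noise.

    The amplitude spectrum is scaled by ``f**-0.5`` so the power
    spectral density falls off as 1/f (slope -1 on log-log axes).
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    scale = np.empty_like(f)
    scale[0] = 0.0  # no DC
    scale[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * scale, n=n_samples)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def _block_noise(
    config: SimulationConfig, n_epochs: int, rng: np.random.Generator
) -> np.ndarray:
    """(C, E*T) continuous pink noise with a shared across-channel part."""
    C, T = config.n_channels, config.n_samples
    n = n_epochs * T
    shared = pink_noise(n, rng)
    a = config.noise_shared_mix
    own_scale = np.sqrt(max(0.0, 1.0 - a**2))
    out = np.empty((C, n))
    for c in range(C):
        out[c] = own_scale * pink_noise(n, rng) + a * shared
    out *= config.noise_sd
    return out


# ---------------------------------------------------------------------------
# subjects and studies


def _blink_waveform(config: SimulationConfig) -> np.ndarray:
    T = config.n_samples
    t_ms = (np.arange(T) - round(config.pre_stim_ms * config.fs / 1000.0)) \
        / config.fs * 1000.0
    return np.exp(
        -((t_ms - config.blink_latency_ms) ** 2) / (2 * config.blink_width_ms**2)
    )


def _blink_topography(config: SimulationConfig, pos: np.ndarray) -> np.ndarray:
    """Weight 1 at the front rim decaying toward the back of the net."""
    d = np.linalg.norm(pos - np.array([0.0, 1.0]), axis=1)
    w = np.exp(-(d**2) / (2 * 0.35**2))
    return w / w.max()


def simulate_subject(
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> tuple[EpochedRecording, GroundTruth]:
    """Simulate one subject: templates + pink noise + injected artifacts."""
    config.validate()
    if group not in ("ASD", "TD"):
        raise ValueError("group must be 'ASD' or 'TD'")
    C, T = config.n_channels, config.n_samples
    channels, periocular, pos = make_montage(C, config.n_periocular)
    standard_t, deviant_t = erp_templates(config, group, pos)
    blink_topo = _blink_topography(config, pos)
    blink_wave = _blink_waveform(config)
    blink_rate = config.blink_rate_asd if group == "ASD" else config.blink_rate_td

    labels_all: list[np.ndarray] = []
    blocks_all: list[np.ndarray] = []
    data_blocks: list[np.ndarray] = []
    blink_epochs: set[tuple[int, int]] = set()
    injected: dict[tuple[int, int], str] = {}
    epoch_offset = 0
    for b in range(config.blocks_per_subject):
        E = config.epochs_per_block
        labels = make_schedule(E, config.deviant_fraction, config.min_gap, rng)
        deviant_mask = labels == DEVIANT
        block = _block_noise(config, E, rng).reshape(C, E, T)
        block += np.where(deviant_mask, 1.0, 0.0)[None, :, None] * deviant_t[:, None, :]
        block += np.where(deviant_mask, 0.0, 1.0)[None, :, None] * standard_t[:, None, :]

        # eye blinks: rank-one frontal lobe, rate boosted on deviants
        p = np.where(
            deviant_mask,
            min(1.0, blink_rate * config.blink_deviant_multiplier),
            blink_rate,
        )
        blink_here = rng.random(E) < p
        for e in np.flatnonzero(blink_here):
            amp = config.blink_amplitude * rng.lognormal(0.0, 0.3)
            block[:, e, :] += amp * np.outer(blink_topo, blink_wave)
            blink_epochs.add((b, epoch_offset + int(e)))

        # slow drifts (trend-line fodder) and spikes (threshold fodder)
        drift_cells = rng.random((C, E)) < config.drift_prob
        ramp = np.linspace(0.0, 1.0, T)
        for c, e in zip(*np.nonzero(drift_cells)):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            block[c, e, :] += sign * config.drift_slope * ramp
            injected[(int(c), epoch_offset + int(e))] = "drift"
        spike_cells = rng.random((C, E)) < config.spike_prob
        for c, e in zip(*np.nonzero(spike_cells)):
            t0 = int(rng.integers(1, T - 1))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            block[c, e, t0 - 1 : t0 + 2] += (
                sign * config.spike_amplitude * np.array([0.5, 1.0, 0.5])
            )
            injected[(int(c), epoch_offset + int(e))] = "spike"

        labels_all.append(labels)
        blocks_all.append(np.full(E, b, dtype=np.int64))
        data_blocks.append(block)
        epoch_offset += E

    recording = EpochedRecording(
        data=np.concatenate(data_blocks, axis=1),
        fs=config.fs,
        pre_stim_ms=config.pre_stim_ms,
        labels=np.concatenate(labels_all),
        block_of=np.concatenate(blocks_all),
        channels=channels,
        periocular=periocular,
        subject_id=subject_id,
        group=group,
        positions=pos,
    )
    truth = GroundTruth(
        blink_epochs=blink_epochs,
        injected_artifacts=injected,
        templates={"standard": standard_t, "deviant": deviant_t},
    )
    return recording, truth


def subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Per-subject substream derived from the study seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, subject_index)))


def simulate_study(
    config: SimulationConfig,
) -> tuple[StudySet, list[GroundTruth]]:
    """Simulate a full cohort: ``n_asd`` ASD then ``n_td`` TD subjects.

    Sex is assigned deterministically at the cohort's male fractions
    (16/19 for ASD, 15/30 for TD) so the males-only sub-analysis is
    exercisable on any cohort size.
    """
    config.validate()
    recordings, truths, groups, sexes = [], [], [], []
    plan = [("ASD", config.n_asd), ("TD", config.n_td)]
    subject_index = 0
    for group, n in plan:
        male_frac = 16 / 19 if group == "ASD" else 15 / 30
        n_male = int(round(male_frac * n))
        for j in range(n):
            rng = subject_rng(config.seed, subject_index)
            rec, truth = simulate_subject(
                config, group, rng, subject_id=f"{group.lower()}-{j + 1:02d}"
            )
            recordings.append(rec)
            truths.append(truth)
            groups.append(group)
            sexes.append("M" if j < n_male else "F")
            subject_index += 1
    return StudySet(recordings, groups, sex=sexes), truths
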