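"""Simulate a small oddball-EEG cohort and inspect its structure.

Builds a cohort of 3 ASD and 4 TD subjects on a reduced 16-channel
montage, then prints the block composition and the injected ground
truth for the first subject.
"""

import numpy as np

from oddballeeg import SimulationConfig, simulate_study

config = SimulationConfig(
    n_asd=3, n_td=4, n_channels=16, epochs_per_block=400,
    blocks_per_subject=1, seed=1,
)
study, truths = simulate_study(config)

rec, truth = study.recordings[0], truths[0]
print(f"cohort: {len(study)} subjects, groups {study.group_sizes()}")
print(f"subject {rec.subject_id}: data {rec.data.shape} (C x E x T), "
      f"fs={rec.fs:g} Hz, baseline {rec.pre_stim_ms:g} ms")
print(f"deviants per block: {int(rec.is_deviant().sum())} of {rec.n_epochs} "
      f"({rec.is_deviant().mean():.0%} of stimuli)")
print(f"periocular channels: {rec.periocular}")
print(f"injected blinks: {truth.n_blinks} epochs; "
      f"other artifacts: {len(truth.injected_artifacts)} cells")
amp = np.abs(rec.data).max()
print(f"peak absolute amplitude: {amp:.0f} uV "
      "(blinks and spikes dominate; background noise is ~15 uV pink)")
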