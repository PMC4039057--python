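"""From clean cells to a 23-dimensional feature vector.

Computes a subject's pooled median standard and deviant waveforms, the
difference waveform delta, and the SSD / variance features; shows where
the simulated ASD deviant effect lands in the feature vector.
"""

import numpy as np

from oddballeeg import (
    SimulationConfig,
    baseline_correct,
    interval_ssd,
    median_waveforms,
    reject_cells,
    select_features,
    simulate_subject,
    ssd_features,
    variance_features,
)
from oddballeeg.simulate import subject_rng

config = SimulationConfig(
    n_asd=1, n_td=0, n_channels=16, epochs_per_block=400,
    blocks_per_subject=1, seed=5,
)
rec, _ = simulate_subject(config, "ASD", subject_rng(5, 0))
rec = baseline_correct(rec)
mask = reject_cells(rec)

waves = median_waveforms(rec, mask)
print(f"pooled vectors: {waves.n_standard_vectors} standard, "
      f"{waves.n_deviant_vectors} deviant (clean cells across all channels)")

ssd = ssd_features(waves.delta)     # 24 x 50 ms partitions over -200..1000 ms
var = variance_features(waves.delta)  # 12 x 100 ms partitions
sel = select_features(ssd, var)     # drop 4 baseline SSDs, keep variances 4-6
print(f"SSD features: {ssd.shape[0]}, variance: {var.shape[0]}, "
      f"selected vector: {sel.shape[0]}")

iv = interval_ssd(waves.delta, rec.fs, rec.pre_stim_ms)
for (lo, hi), v in zip([(0, 150), (150, 250), (250, 400), (400, 1000)], iv):
    print(f"  SSD {lo:4d}-{hi:4d} ms: {v:8.1f} uV*sample")
print("The simulated ASD boost makes the early (0-150 ms) and late "
      "(400-1000 ms) sums clearly positive: the deviant response sits "
      "above the standard response there.")
print(f"late-window partition means dominate: "
      f"ssd[16:24] mean = {ssd[16:].mean():.1f} vs "
      f"baseline partitions mean = {ssd[:4].mean():.1f}")
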