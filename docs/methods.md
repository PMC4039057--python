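# Methods

This note documents the models, conventions and numerical choices the
package implements, the assumptions behind its synthetic-data
generator, and what the test suite does and does not demonstrate.

## Data model

A subject's epoched recording is a `C × E × T` array in microvolts
with per-epoch stimulus labels (standard/deviant), block indices, a
montage (ordered channel ids with a flagged periocular subset and
schematic 2-D positions), the sampling rate and the baseline duration.
Time indexing is 0-based and epoch windows are half-open
`[onset − pre, onset + post)`, so `T = round((pre + post) · fs /
1000)`. The default geometry is `fs = 1000 Hz`, 200 ms baseline,
1000 ms post-stimulus, `T = 1200`: with that geometry the feature
formulas below (24 × 50-sample and 12 × 100-sample partitions) apply
verbatim. A 250 Hz / `T = 300` recording is a supported container
configuration, but SSD partitioning requires `T` divisible by 24, so
the feature stage rejects it; recordings at integer multiples of
250 Hz are decimated internally where a 250 Hz working rate is needed.
Subjects are stored one per HDF5 file (`data`, `labels`, `block_of`,
`channels`, optional `positions`, root attributes `fs`,
`pre_stim_ms`, `subject_id`, `group`, `periocular`); continuous input
is accepted as a `(C, N)` array or an EDF file plus a tab-separated
event table.

## Artifact rejection

Baselining subtracts each cell's mean over the pre-stimulus window.
Two criteria then act per (channel, epoch) cell:

- **Threshold**: reject when max |amplitude| strictly exceeds
  `threshold_uv` (default 100 µV, post-baseline). A sample exactly at
  the bound is kept; the boundary convention is tested.
- **Trend line**: ordinary least squares of the cell against time with
  the axis normalised so the epoch spans one unit; reject when
  |slope| > 50 µV/epoch **and** R² ≥ 0.3. Both slope signs are
  rejected (a drift downward is as artifactual as one upward); a
  zero-variance cell gets R² = 0 and is kept.

A cell is discarded if either criterion fires; the retained cells form
the clean set P. The **traditional comparator** keeps an epoch only
when every non-blacklisted channel passes the threshold criterion in
it — equivalently, when the mask column is all-true — which makes the
dominance of cell-wise retention a logical consequence, asserted on
simulated blocks. **Kurtosis channel screening** (used in the
comparator experiment, optional elsewhere) computes each channel's
excess (Fisher) kurtosis over its pooled block samples and standardises
across the block's channels; |z| > 5 flags the channel. Standardising
across channels was chosen because a fixed "standard deviation of
kurtosis" is otherwise undefined; the alternatives (per-study
standardisation, analytic SE) are not exposed.

The rejection topography aggregates rejected-cell counts per channel
over a study and, for the flagged periocular channels, compares
per-subject rejection proportions between groups with a two-sample
Kruskal–Wallis test (p = 1 when all values tie, since tied ranks carry
no evidence).

## Features

**Median waveforms.** All clean standard cells are pooled across
channels and epochs and reduced elementwise to the median standard
response `s̄`; deviant cells give `d̄`; `δ = d̄ − s̄`. Pooling without
a per-channel averaging stage is deliberate: a noisy channel
contributes few clean epochs and therefore little weight. Even-count
medians average the two middle values.

**SSD.** `δ` is partitioned into 24 contiguous equal blocks (50 ms at
the default geometry) and summed within each: the signed area under
the difference curve. The four baseline partitions are discarded for
classification, leaving 20. Interval SSDs over (0–150, 150–250,
250–400, 400–1000) ms support the group Welch t-test.

**Variance.** Sample variance (n−1 divisor) of `δ` in 12 contiguous
partitions; partitions 4–6 are kept (indices, not a millisecond
window, define the selection). A `variance_source: standard` switch
computes the same partitions on `s̄` instead — the package follows the
difference-waveform formula by default but preserves the alternative
reading. Selected vector: 20 SSD + 3 variance = 23 values.

**Multiscale sample entropy.** Sample entropy uses embedding `m = 2`,
Chebyshev distance with tolerance `r = 0.15 × SD`, counts over the
first `N − m` templates with self-matches excluded, and the match
convention `d ≤ r`. A constant series returns 0; if no templates match
the value is an explicit NaN sentinel with a warning (mapped to 0 in
the feature block). The multiscale block keeps every other montage
channel (64 of 128), concatenates each channel's earliest clean epochs
to 5,000 samples at a 250 Hz working rate (decimating by an integer
factor after an order-8 low-pass when `fs` is higher), fixes `r` from
the scale-1 series, and evaluates scales 1–20 on non-overlapping
window means — 1,280 values, channel-major. Fixing `r` at scale 1
makes entropy decline with scale for white-like noise, which the tests
assert. Channels with insufficient clean data fall back to whatever
clean samples exist, with a warning.

## Eye blinks

Each block's epochs are concatenated in time, reduced to 10 principal
components, and unmixed with FastICA (seeded; the specific
nonlinearity is not load-bearing — the source-recovery test is the
contract). Components are scored by mean |mixing weight| over the
periocular channels divided by the mean over all channels, ties broken
by sub-5 Hz activation power. Removal subtracts up to `k_max = 2`
top-scored components per block, but only those whose score reaches
1.5 — the manual step this automates identified *up to* two blink-like
components, and on blink-free data nothing should qualify (tested: the
transform is then a near-identity). Counting sign-orients the top
component toward positive periocular loading, smooths the activation
with a 50 ms moving average (blinks last hundreds of ms; the smoothing
suppresses single-sample noise maxima that a per-epoch max would
otherwise catch), zero-means it across the subject, and flags epochs
whose maximum exceeds 3 × SD. The per-epoch statistic (max), the SD
multiplier, and the component choice are all configurable, since the
underlying conventions are genuinely open.

## Classification

Labels are ASD (positive) vs TD. Weighted accuracy is the mean of the
two class recalls; sensitivity is ASD recall, specificity TD recall.
Evaluation is LOOCV with all tuning inside the training fold:

- **Linear SVM**: C over powers of two in [2⁻⁴, 2⁶], chosen by
  stratified 3-fold search scored with weighted accuracy; ties go to
  the smallest (most regularised) C. Class weights inverse to
  frequency.
- **Logistic regression (l2)**: same scheme over [2⁻⁵, 2⁵].
- **Gaussian naive Bayes**: the typical-class posterior is thresholded
  at a cut chosen by inner LOOCV over {0.05, …, 0.95}; ties prefer the
  cut nearest 0.5. Class-conditional variances are floored at 1 % of
  each feature's overall variance so a near-constant class (e.g. one
  training subject) keeps a usable likelihood width; inner folds that
  would empty a class are skipped, and with no valid inner folds the
  cut defaults to 0.5.

**Stacking**: a linear SVM with fixed C = 0.1 and inverse-frequency
weights is LOOCV-evaluated on the 1,280-dimensional entropy block and
each subject's out-of-fold hard label (1 = ASD) becomes feature 24 —
stacking a prediction rather than concatenating avoids the entropy
block swamping the 23 selected features. The permutation test reruns
the full LOOCV pipeline on permuted labels and reports
`(1 + #{permuted ≥ observed}) / (n_perm + 1)`.

## Synthetic cohorts

The generator emulates the study design the analysis assumes, not any
particular dataset:

- **Schedule**: blocks of 400 stimuli, 15 % deviants, every deviant
  flanked by ≥ 4 standards (surplus standards distributed uniformly at
  random over the inter-deviant slots).
- **Templates**: sums of Gaussian bumps with schematic scalp profiles
  (P1/N1/P2-like standard response; an MMN-like deflection plus P3a
  added for deviants). The ASD deviant template additionally gains
  `asd_deviant_boost` µV (default 2.5) inside smoothed 0–200 ms and
  400–1000 ms post-stimulus windows — the group effect of interest.
  No quantitative effect size is available for it, so the default is
  calibrated such that the effect is recoverable by the pipeline at
  study-scale cohort sizes; it is a free parameter.
- **Noise**: pink noise by spectral shaping (amplitude ∝ f^−½, PSD
  slope −1), per-channel independent plus a shared component at 0.3
  mixing so that channels are correlated and ICA has real structure to
  find; default scale 15 µV.
- **Blinks**: a 200–400 ms positive lobe (Gaussian, 300 ms latency,
  55 ms width) with a frontal topography decaying from the periocular
  sites; per-event amplitude 90 µV × lognormal(0, 0.3). Per-epoch
  blink probability is group-dependent (ASD 0.30, TD 0.12) and tripled
  on deviant epochs (novelty-evoked blinking) — this deviant asymmetry
  is what lets blink rate leak into the deviant-minus-standard
  difference waveform, so that removing blink components genuinely
  removes a group signal. No blink-rate measurements accompany the
  study design, so these rates are calibrated once so that the
  blink-rate effect alone is recoverable by the classifier at
  study-scale cohort sizes, and then frozen.
- **Other artifacts**: per-cell drifts (probability 0.02, 80 µV/epoch
  ramps, trend-line fodder) and spikes (probability 0.01, 150 µV,
  threshold fodder).
- **Montage**: golden-angle spiral on the unit disk with the nose at
  +y; the 7 channels nearest the front rim are flagged periocular. No
  realistic 10–20 geometry is attempted.
- **Seeding**: a study seed spawns per-subject substreams via
  `SeedSequence((seed, subject_index))`, so cohorts are reproducible
  and subjects independent. Sex is assigned at fixed male fractions
  (16/19 ASD, 15/30 TD) to support the males-only sub-analysis.

What the simulator does *not* model: biophysical head geometry or
forward solutions, saccade/EMG artifacts, line noise, channel pops,
age effects, or any coupling between the deviant-response effect and
blink behaviour beyond their independent group differences. Passing
recovery tests therefore show the pipeline's machinery is sound and
its statistics behave as designed — not that comparable accuracy would
be obtained on clinical recordings.

## Problem sizes and numerical choices

Validation runs use study-sized cohorts (19 ASD / 30 TD; a single
400-epoch block) at reduced channel counts (16–32 channels) and the
entropy block at reduced sample targets, keeping full geometry checks
(128-channel masks, 1,280-value entropy blocks) on small inputs; these
sizes are the package's validation choices and all scale parameters
remain configurable. Oracles (partition sums, variances, least-squares
fits, medians, sample entropy) are checked to 1e-9 against brute-force
implementations. Degenerate inputs have defined behaviour throughout:
constant series (entropy 0, R² 0), all-tied rank tests (p = 1),
zero-variance activations (zero blinks, warning), single-class
cohorts (errors).

## Known limitations

- The EDF path is a thin reader (via `mne`) over the same epoching
  core; only the array path is exercised by automated tests.
- ICA on short or low-channel-count blocks may not isolate a blink
  component cleanly; blink counting is only as good as the component
  selection, which the score override exists to correct.
- The naive-Bayes inner LOOCV threshold search is O(n²) model fits per
  outer fold; fine at cohort sizes here, slow for hundreds of
  subjects.
- Retention curves summarise blocks by median/quartiles; with a single
  block the quartiles collapse onto the median.
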