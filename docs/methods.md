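# Methods

## Synthetic cohort model

The generator produces the minimal statistical structure needed to test a
PPG→BP assessment pipeline end to end.

**Pulse template.** One beat is a sum of two Gaussian bumps over beat
phase φ ∈ [0, 1): a systolic peak and a dicrotic notch,
`g(φ) = exp(−(φ−m₁)²/2s₁²) + a₂·exp(−(φ−m₂)²/2s₂²)` with parameters
θ = (peak position m₁, peak width s₁, notch amplitude a₂, notch delay
m₂−m₁).  The template is smooth and differentiable, so derivative channels
are well behaved, and has few interpretable parameters.

**Morphology ↔ BP mapping.** θ is a *linear* function of the standardized
instantaneous (SBP, DBP, HR) (centres 120/60/75, scales 25/15/25) through
a fixed population matrix (`MORPHOLOGY_BP_MAP`), plus a per-subject offset
vector that is constant for the subject's lifetime.  Linearity keeps the
regression problem solvable by small networks at desk scale; the fixed
offset is what makes train/test subject leakage detectable — at matched
(SBP, DBP, HR) the inter-subject waveform distance exceeds the
intra-subject distance.  Parameters are clipped to physiological ranges,
so very large offsets or extreme pressures saturate rather than produce
degenerate waveforms.

**Pressure trajectories.** SBP drifts as a sinusoid of configurable
amplitude (default 5 mmHg) and period (40–120 s) plus first-order
autoregressive jitter (ρ = 0.95, σ = 10% of the drift amplitude) on a 1 s
grid; DBP follows the same phase at half amplitude.  Zero drift amplitude
yields exactly constant pressures, which the exactness tests rely on.  The
arterial waveform oscillates beat-synchronously between the instantaneous
DBP and SBP: each beat's sampled shape is min–max normalized, so the
per-beat discrete extrema equal the instantaneous SBP/DBP exactly.

**Heart rate.** Beat-to-beat AR(1) jitter (ρ = 0.8) around the subject's
base rate, clipped to 30–200 bpm.

**Record lengths.** Log-normal (default median 300 s, σ_log 0.8, clipped),
emulating the long-tailed spread of samples per subject in large waveform
archives.  Cohort sampling, per-subject seeds and all downstream draws are
derived from a single seed via SHA-256, so cohorts are byte-reproducible.

**Camera traces.** The embedded pulse (unit peak, zero mean) modulates a
shared slowly varying illumination baseline times static per-channel
gains, with relative modulation strengths (R, G, B) = (0.33, 0.77, 0.53) —
the typical skin-reflection ordering, strongest in green.  Because the
baseline is common-mode, a pulse-free noise-free trace projects to exactly
zero under POS.  Motion artifacts are Gaussian transients at a Poisson
rate; reference BP is read off the drift trajectory on the one-minute grid
(inclusive endpoints — a 120 min trace yields 121 readings), with no
averaging, emulating bedside-monitor export.

**What the generator does not emulate:** real pathology classes,
medication effects, sensor contact-pressure artifacts, baseline wander,
ECG, or raw video.  Passing tests therefore demonstrate that the pipeline
machinery (windowing, gating, labelling, splitting, training protocols,
metrics) behaves correctly and that the qualitative effects — leakage
inflation, tail-error growth, personalization and transfer gains — appear
whenever subject-specific morphology exists; they do not certify clinical
performance on real recordings.

## Preprocessing

* Band-pass: 4th-order Butterworth, 0.5–8 Hz, applied forward–backward
  (zero phase) to avoid morphology-distorting phase lag.
* Heart rate: dominant spectral component in 0.5–3.0 Hz on a zero-padded
  FFT with bin width ≤ 0.02 Hz.
* `const_time`: consecutive disjoint fixed-duration segments.
  `const_beats`: local HR estimated on a 20 s neighbourhood of the window
  start, span = N_P·(60/HR) s, Fourier-resampled to N_P × 125 samples
  (effective 60 bpm).  Admissible lengths {1, 2, 5, 7, 9, 11, 13, 15, 17,
  20}; other values work with a warning.  Labels always come from the
  un-resampled arterial span (medians are resampling-invariant).
* SNR: power spectrum of the mean-removed window on the same padded FFT;
  E_P sums ±0.2 Hz bands around the pulse peak and its first harmonic,
  E_S the rest of 0.5–8 Hz; gate at −7 dB, boundary inclusive.  Band
  half-width is a package constant; the measure is amplitude-invariant and
  unreliable below ~4 s windows.
* Normalization: per-channel zero mean, unit *population* variance;
  constant channels are rejected with a structured error.  Derivatives
  (central differences, one-sided ends) are added before normalization.
* POS: 1.6 s sliding windows, per-channel running-mean normalization,
  projection rows (0, 1, −1) and (−2, 1, 1), recombination
  h = s₁ + (σ(s₁)/σ(s₂))·s₂, mean-removed overlap-add.
* Fixed stage order: filter → crop → SNR gate → label filter → normalize.

## Labels

Systolic peaks: local maxima at least 0.5·(60/HR_hint) apart with
prominence ≥ 10% of the segment range; diastolic values: the minimum
between consecutive peaks ("diastolic peaks" read as troughs).  SBP/DBP =
medians of those values, HR = median inverse inter-peak interval (from the
arterial waveform, never from PPG, so label validity does not depend on
PPG quality).  Plausibility bounds (75–165, 40–80 mmHg, 50–140 bpm) are
inclusive; a window violating several rules is counted once, in order
SBP → DBP → HR.

## Datasets

Per-subject cap 2000 windows (uniform seeded subsample).  Non-mixed splits
assign whole subjects to exactly one partition; oversized requests are
scaled down proportionally with a warning; excluded subjects are tagged,
not dropped.  Mixed splits shuffle pooled samples with fractions
(2/3, 1/6, 1/6), chosen to mirror the 1M/250k/250k sample ratio of the
non-mixed protocol.  Personalization: windows ordered by source offset;
first ⌈0.2n⌉ = systematic calibration; the last 80% is cut at its midpoint
into a spare pool and the test half; the random strategy draws ⌈0.2n⌉
windows from (first 20% ∪ spare pool).  The test half is identical across
strategies.  All randomness derives from a single split seed per subject
via SHA-256.

## Models and training

The engine is a small numpy layer library (1-D convolution, max/global
pooling, batch normalization, bidirectional LSTM, GRU, dense, residual and
parallel containers, Adam) with explicit forward/backward passes; all
gradients are finite-difference-checked in the test suite.

* `alexnet1d`: kernels 11/5/3 and conv channels 64/192/384/256/256 along
  time; the two fully connected layers default to 256/128 — a desk-scale
  choice (overridable via `hyperparams["dense_sizes"]`) since the original
  4096-wide heads dominate runtime without adding assessment value.
* `resnet1d`: ResNet-18 block layout (2 blocks per stage, channels
  64/128/256/512, stride-2 stage transitions, projection shortcuts), a
  `width` multiplier for scaled-down runs.
* `spectrotemporal`: parallel residual temporal conv stack and a fixed
  log-magnitude spectrogram branch (frame ≈ L/4, hop = frame/2) feeding a
  conv layer; the branches are aligned by nearest-index resampling,
  concatenated and read out by one GRU, dense, head.
* `cnn_lstm`: conv(32 filters, kernel 5, stride 1) + ReLU, three
  bidirectional LSTM layers with 64/64/32 units per direction, dense 128.
  Three recurrent layers (not four) were chosen because the enumerated
  sizes list three values; the stated sizes are read as per-direction.
* `cnn_small`: three strided conv blocks (16/32/32) + dense 64 — the
  workhorse for the directional experiments, where architecture capacity
  is not the object of study.

Every network ends in a two-neuron linear head.  Targets are standardized
internally (scaler fitted on the training labels, predictions returned in
mmHg).  Loss: MSE on the (SBP, DBP) pair; optimizer Adam, α = 0.001,
batch size 128 default.  Early stopping: patience 10 within 200 epochs by
default, monitoring validation MAE, always restoring the best checkpoint.
Divergence aborts with a diagnostic.  The window-length study harness runs
3 repetitions per (architecture × strategy × length) cell with
configurable sample budgets and feeds the paired-t comparison.

**Personalization** fine-tunes all layers on the calibration windows, with
the calibration set's temporal 10% tail as its early-stopping validation
split (the protocol leaves the freeze and stop rule open; all-layer tuning
plus the same patience rule is the simplest consistent choice).
**rPPG transfer** trains only the final layer; the freeze contract is a
byte-exact SHA-256 fingerprint over all non-head weights, checked on every
fold.  Folds rotate deterministically over sorted subjects: fold k tests
subject k with subject k+1 (cyclic) as validation, so each subject is
tested exactly once (15/1/1 at the 17-subject study size).

## Evaluation

Overall MAE plus 10 mmHg bins over the plausibility ranges (SBP 75–165:
9 bins; DBP 40–80: 4 bins), half-open and anchored at the lower bound,
final bin closed; empty bins report count 0 and no error value.  The
bin-weighted mean must reproduce the overall MAE to 1e-9 (asserted on
every report).  Distribution comparisons: two-sample KS on per-window
absolute errors (the only sample unit giving usable sizes) or paired t on
matched repetition cells, α = 0.05, no multiple-testing correction (the
number of tests is recorded).  A degenerate paired design (zero-variance
nonzero difference) is reported as perfectly separated rather than
crashing.  BHS-style grade: fraction of absolute errors < 10 mmHg,
pass above 85%.

## Reference experiment sizes

The reference experiments run at sizes chosen so the whole suite completes
in minutes on one CPU while every directional effect is comfortably
resolved: leakage/personalization use 50-subject cohorts (~40–60 windows
per subject at 7 s), the compact CNN, 30-epoch budgets; the transfer
experiment pre-trains on a 40-subject low-offset cohort (offset σ = 0.4,
so the population morphology→BP mapping is actually learned) with 7-beat
`const_beats` windows and fine-tunes over 17 camera-trace subjects whose
pulse template is shifted along the SBP axis of the population map
(`TRANSFER_DOMAIN_SHIFT`, ≈ −37 mmHg equivalent) — a systematic
contact-vs-camera morphology difference that head-only retraining can
correct.  The leakage cohorts use offset σ = 1.2, large enough that
subject identity dominates the population signal, which is the regime
that makes split-mode comparisons interesting.

## Known limitations

* The morphology→BP relation is linear and noise is white; real PPG shows
  nonlinear, non-stationary, equipment-dependent effects.
* The arterial-waveform shape uses one fixed in-beat template; no
  pathological waveform classes.
* `wfdb` ingestion of PhysioNet records is an optional adapter and
  requires the `wfdb` package at run time.
* The numpy engine is single-threaded BLAS-bound; it is meant for
  assessment-scale experiments, not production training.
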