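# ppgbp

Assessment pipeline for cuffless blood-pressure prediction from
photoplethysmography (PPG) and camera-derived remote PPG (rPPG) signals.

## The problem

Optical pulse waveforms carry morphological information about arterial
blood pressure, and end-to-end neural regressors that map a PPG window to
systolic/diastolic pressure (SBP/DBP, mmHg) report impressively low mean
absolute errors (MAE).  Much of that performance can be an artifact of how
the evaluation data were assembled: if windows from the same subject appear
in both training and test sets ("mixed" splits), the model can exploit
subject identity rather than physiology, and averaging the error over the
whole test set hides a strong growth of the error towards rare BP values.
This package implements the full assessment chain needed to expose those
effects, driven by a synthetic cohort generator so every stage is testable
without clinical waveform databases:

* **synthetic_data** — per-subject pulse waveforms (two-bump systolic +
  dicrotic-notch template) whose shape is a population function of the
  instantaneous (SBP, DBP, HR) plus a fixed subject-specific offset, with
  drifting pressures, controllable noise, long-tailed record lengths, and
  camera-style RGB traces with minute-resolution reference BP;
* **preprocess** — 4th-order Butterworth band-pass (0.5–8 Hz, zero-phase),
  spectral heart-rate estimation, `const_time` and `const_beats` window
  cropping (the latter resampled to N_P×125 samples, i.e. an effective
  60 bpm), derivative channels, z-scoring, and the de Haan spectral SNR
  `SNR = 10·log10(E_P / E_S)` with a −7 dB quality gate;
* **labels** — median systolic-peak / diastolic-trough extraction from the
  arterial waveform with plausibility filters (SBP 75–165 mmHg, DBP
  40–80 mmHg, HR 50–140 bpm);
* **datasets** — per-subject capping (2000 windows), subject-disjoint
  ("non-mixed") vs sample-random ("mixed") splits, and 20%-calibration
  personalization partitions (first-20% or random-20%, shared test half);
* **models** — a 1-D architecture zoo (AlexNet-style, ResNet-18-style,
  spectro-temporal, CNN + bidirectional LSTM, compact CNN) with a
  two-neuron linear regression head, plus a mean-regressor baseline; built
  on an internal numpy layer engine with verified analytic gradients;
* **training** — Adam (α = 0.001) with early stopping (patience 10,
  best-checkpoint restore), per-subject fine-tuning, and leave-two-out
  rPPG transfer where everything but the final layer is frozen (enforced
  byte-exactly via weight fingerprints);
* **evaluation** — overall and 10 mmHg-bin-wise MAE, Kolmogorov–Smirnov /
  paired-t comparisons (α = 0.05), and the BHS-style fraction of absolute
  errors under 10 mmHg against the 85% pass mark;
* **preprocess.pos_extract** — plane-orthogonal-to-skin (POS) pulse
  extraction from per-frame RGB traces.

## Worked example

```python
from ppgbp import synthetic, datasets, training, evaluation, models
from ppgbp.preprocess import WindowingConfig

cfg = synthetic.CohortConfig(
    n_subjects=12, seed=0,
    subject_size_distribution={"median_s": 200.0, "sigma_log": 0.3})
cohort = synthetic.generate_cohort(cfg)

pool = datasets.build_pool(
    cohort.records, windowing=WindowingConfig("const_beats", 7))
split = datasets.split_non_mixed(pool, n_train_subjects=8,
                                 n_val_subjects=2, n_test_subjects=2, seed=0)

model = models.build_model(
    models.ModelSpec("cnn_small", input_length=875, input_channels=1), seed=0)
history = training.train(model, split, training.TrainingConfig(
    max_epochs=20, patience=5, batch_size=64, seed=0))

preds = model.predict(split.test.X)
baseline = models.mean_regressor_fit(split.train.y).predict(split.test.X)
report = evaluation.build_report(preds, split.test.y,
                                 baseline_predictions=baseline)
```

Output of this exact script:

```
417 windows from 12 subjects
stopped at epoch 8, best epoch 3
test MAE      SBP 10.8 mmHg, DBP 5.4 mmHg
baseline MAE  SBP 11.5 mmHg, DBP 7.2 mmHg
|error| < 10 mmHg: SBP 55% (fail at 85%)
```

The trained CNN beats the mean regressor only modestly on a
subject-disjoint split — held-out subjects carry unseen morphology offsets
— and fails the 85%-within-10-mmHg criterion, which is exactly the
behaviour the assessment is designed to surface.  The same pipeline with
`datasets.split_mixed` produces a markedly lower (leakage-inflated) MAE.

A command-line interface mirrors the stages
(`ppgbp synth / prep / data / train / personalize / transfer / evaluate /
report`); run `ppgbp --help`.

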