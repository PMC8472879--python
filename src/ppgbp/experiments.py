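"""Desk-scale reproductions of the assessment protocols.

Each function runs one complete study protocol on a synthetic cohort at a
size that finishes in minutes on one CPU, returning plain dictionaries of
the quantities of interest.  These are the package's reference experiments:

* :func:`leakage_experiment` — mixed vs non-mixed split comparison (the
  subject-leakage effect) plus bin-wise tail/modal error resolution;
* :func:`personalization_experiment` — fine-tuning on a held-out subject's
  20% calibration windows, both selection strategies;
* :func:`transfer_experiment` — final-layer transfer of a contact-PPG
  model to camera-derived pulse windows under an injected morphology
  domain shift, leave-two-out over 17 subjects;
* :func:`pos_recovery_experiment` — POS pulse recovery fidelity;
* :func:`mini_pipeline_report` — a small end-to-end run used for
  determinism auditing.

Study conditions (cohort sizes, noise levels, offsets, epochs) are fixed
here as the experiment definitions; the ``seed`` argument controls every
source of randomness.
"""

from __future__ import annotations

import numpy as np

from ppgbp import synthetic as syn
from ppgbp import datasets as ds
from ppgbp import training as tr
from ppgbp import evaluation as ev
from ppgbp.models import ModelSpec, build_model, mean_regressor_fit
from ppgbp.preprocess import WindowingConfig, pos_extract

__all__ = [
    "leakage_experiment", "personalization_experiment",
    "transfer_experiment", "pos_recovery_experiment",
    "mini_pipeline_report", "TRANSFER_DOMAIN_SHIFT",
]

#: morphology shift applied to camera-pulse templates: a systematic
#: displacement along the SBP axis of the population map, emulating the
#: morphology difference between contact PPG and remote pulse signals
TRANSFER_DOMAIN_SHIFT = syn.MORPHOLOGY_BP_MAP[:, 0] * -1.5


def _study_cohort(seed: int, n_subjects: int, offset_sd: float = 1.2,
                  median_s: float = 300.0) -> syn.Cohort:
    cfg = syn.CohortConfig(
        n_subjects=n_subjects, seed=seed, subject_offset_sd=offset_sd,
        subject_size_distribution={"median_s": median_s, "sigma_log": 0.25},
        min_duration_s=200.0, max_duration_s=500.0, noise_sd=0.02)
    return syn.generate_cohort(cfg)


def leakage_experiment(seed: int, n_subjects: int = 50,
                       windowing: WindowingConfig | None = None,
                       max_epochs: int = 30) -> dict:
    """Mixed vs non-mixed comparison on one seeded cohort.

    Trains the same compact CNN under both split modes and reports test
    MAE, the mean-regressor baseline, and the bin-wise SBP error of the
    non-mixed model (modal bin vs the two outermost occupied bins).
    """
    windowing = windowing or WindowingConfig("const_time", 7)
    cohort = _study_cohort(seed, n_subjects)
    pool = ds.build_pool(cohort.records, windowing=windowing)
    cfg = tr.TrainingConfig(max_epochs=max_epochs, patience=5,
                            batch_size=64, seed=seed)
    out: dict = {"seed": seed, "n_windows": len(pool)}
    for mode in ("non_mixed", "mixed"):
        if mode == "non_mixed":
            n = len(pool.subjects())
            n_train = int(round(n * 2 / 3))
            n_rest = (n - n_train) // 2
            split = ds.split_non_mixed(pool, n_train, n_rest, n_rest, seed=seed)
        else:
            split = ds.split_mixed(pool, seed=seed)
        model = build_model(
            ModelSpec("cnn_small", pool.X.shape[1], pool.X.shape[2]),
            seed=seed)
        tr.train(model, split, cfg)
        mae_sbp, mae_dbp = tr.evaluate_windows(model, split.test)
        baseline = mean_regressor_fit(split.train.y).predict(split.test.X)
        base_sbp, base_dbp = ev.mae(baseline, split.test.y)
        out[f"{mode}_mae_sbp"] = mae_sbp
        out[f"{mode}_mae_dbp"] = mae_dbp
        out[f"{mode}_baseline_mae_sbp"] = base_sbp
        out[f"{mode}_baseline_mae_dbp"] = base_dbp
        if mode == "non_mixed":
            pred = model.predict(split.test.X)
            bins = ev.binwise_mae(split.test.y[:, 0], pred[:, 0],
                                  ev.SBP_BIN_RANGE)
            occupied = bins[bins["count"] > 0].reset_index(drop=True)
            modal = occupied.loc[occupied["count"].idxmax()]
            tails = occupied.iloc[[0, -1]]
            out["tail_bin_mae_sbp"] = float(tails["mae"].mean())
            out["modal_bin_mae_sbp"] = float(modal["mae"])
            out["n_occupied_bins_sbp"] = int(len(occupied))
    return out


def personalization_experiment(seed: int, n_subjects: int = 50,
                               n_pers_subjects: int = 10,
                               max_epochs: int = 30) -> dict:
    """Per-subject fine-tuning under both calibration strategies.

    Pre-trains on a non-mixed split, then personalizes for
    ``n_pers_subjects`` test subjects with the first-20% and random-20%
    strategies, always evaluating on the identical reserved test half.
    """
    cohort = _study_cohort(seed, n_subjects)
    pool = ds.build_pool(cohort.records,
                         windowing=WindowingConfig("const_time", 7))
    n = len(pool.subjects())
    n_test = max(n_pers_subjects, n // 5)
    split = ds.split_non_mixed(pool, n - 2 * n_test, n_test, n_test, seed=seed)
    model = build_model(
        ModelSpec("cnn_small", pool.X.shape[1], pool.X.shape[2]), seed=seed)
    tr.train(model, split, tr.TrainingConfig(
        max_epochs=max_epochs, patience=5, batch_size=64, seed=seed))
    subjects = sorted(set(split.test.subject))[:n_pers_subjects]
    pers_cfg = tr.TrainingConfig(max_epochs=30, patience=5, batch_size=16,
                                 seed=seed)
    out: dict = {"seed": seed, "subjects": subjects}
    for strategy in ("first_20", "random_20"):
        before, after = [], []
        for sid in subjects:
            part = ds.make_personalization_partition(
                split.test.by_subject(sid), strategy=strategy, seed=seed)
            before.append(float(np.mean(tr.evaluate_windows(model, part.test))))
            pers = tr.personalize(model, part, pers_cfg)
            after.append(float(np.mean(tr.evaluate_windows(pers, part.test))))
        out[f"{strategy}_mae_before"] = before
        out[f"{strategy}_mae_after"] = after
        out[f"{strategy}_n_improved"] = int(
            sum(a < b for a, b in zip(after, before)))
        out[f"{strategy}_mean_after"] = float(np.mean(after))
    return out


def build_rppg_cohort(seed: int, n_subjects: int = 17,
                      template_shift: np.ndarray | None = None,
                      pulse_strength: float = 0.08,
                      artifact_rate: float = 0.2) -> dict[str, ds.WindowSet]:
    """Camera-pulse window sets per subject (POS + 7-beat windows)."""
    cfg = syn.CohortConfig(
        n_subjects=n_subjects, seed=seed, subject_offset_sd=0.4,
        subject_size_distribution={"median_s": 480.0, "sigma_log": 0.01},
        min_duration_s=400.0, max_duration_s=600.0, noise_sd=0.003)
    sets = {}
    for i in range(n_subjects):
        profile = syn.sample_profile(cfg, i)
        trace = syn.generate_rppg_trace(
            profile, fs=32.0, pulse_strength=pulse_strength,
            artifact_rate=artifact_rate, template_shift=template_shift)
        ws = ds.rppg_windows_from_trace(trace, n_beats=7)
        if ws is not None:
            sets[profile.subject_id] = ws
    return sets


def transfer_experiment(seed: int, n_ppg_subjects: int = 40,
                        n_rppg_subjects: int = 17,
                        max_epochs: int = 15) -> dict:
    """rPPG final-layer transfer under an injected morphology shift.

    The contact-PPG model is pre-trained on a low-offset cohort with the
    7-beat const_beats strategy (so the population morphology-BP mapping
    is actually learned); camera traces carry
    :data:`TRANSFER_DOMAIN_SHIFT`.  Returns fold-level MAEs and the
    freeze-contract audit.
    """
    cohort = _study_cohort(seed, n_ppg_subjects, offset_sd=0.4)
    pool = ds.build_pool(cohort.records,
                         windowing=WindowingConfig("const_beats", 7))
    n = len(pool.subjects())
    n_rest = max(1, n // 7)
    split = ds.split_non_mixed(pool, n - 2 * n_rest, n_rest, n_rest, seed=seed)
    model = build_model(
        ModelSpec("cnn_small", pool.X.shape[1], pool.X.shape[2]), seed=seed)
    tr.train(model, split, tr.TrainingConfig(
        max_epochs=30, patience=5, batch_size=64, seed=seed))
    rppg_sets = build_rppg_cohort(seed + 100, n_rppg_subjects,
                                  template_shift=TRANSFER_DOMAIN_SHIFT)
    results = tr.transfer_to_rppg(
        model, rppg_sets,
        tr.TransferConfig(trainable_scope="final_layer_only"),
        tr.TrainingConfig(max_epochs=max_epochs, patience=4, batch_size=32,
                          seed=seed))
    return {
        "seed": seed,
        "n_folds": int(len(results)),
        "all_fingerprints_unchanged": bool(results.fingerprint_unchanged.all()),
        "median_sbp_mae_before": float(results.mae_sbp_before.median()),
        "median_sbp_mae_after": float(results.mae_sbp_after.median()),
        "median_dbp_mae_before": float(results.mae_dbp_before.median()),
        "median_dbp_mae_after": float(results.mae_dbp_after.median()),
        "folds": results,
    }


def pos_recovery_experiment(seed: int, duration_s: float = 120.0) -> dict:
    """Correlation between POS output and the embedded pulse."""
    profile = syn.SyntheticSubjectProfile(
        subject_id="pos", base_hr=66.0, hr_jitter_sd=1.0,
        bp_drift_amplitude=3.0, noise_sd=0.0, record_duration=duration_s,
        seed=seed)
    trace = syn.generate_rppg_trace(profile, fs=32.0, pulse_strength=0.05,
                                    artifact_rate=0.0)
    pulse = pos_extract(trace.rgb, trace.fs)
    corr = float(np.corrcoef(pulse, trace.hidden_pulse)[0, 1])
    return {"seed": seed, "pos_pulse_correlation": corr}


def mini_pipeline_report(seed: int, n_subjects: int = 6,
                         max_epochs: int = 5) -> ev.EvaluationReport:
    """Small end-to-end run (cohort -> windows -> split -> train -> report).

    Used to audit that identical (config, seed) reproduce every report
    value exactly.
    """
    cohort = _study_cohort(seed, n_subjects, median_s=200.0)
    pool = ds.build_pool(cohort.records,
                         windowing=WindowingConfig("const_time", 7))
    split = ds.split_mixed(pool, seed=seed)
    model = build_model(
        ModelSpec("cnn_small", pool.X.shape[1], pool.X.shape[2]), seed=seed)
    tr.train(model, split, tr.TrainingConfig(
        max_epochs=max_epochs, patience=2, batch_size=64, seed=seed))
    preds = model.predict(split.test.X)
    baseline = mean_regressor_fit(split.train.y).predict(split.test.X)
    return ev.build_report(preds, split.test.y,
                           baseline_predictions=baseline)
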