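"""Dataset construction: capping, mixed/non-mixed splits, personalization.

The central container is :class:`WindowSet`, aligned numpy arrays of model
inputs, (SBP, DBP) labels and per-window provenance (subject id, source
offset).  Splits come in two modes: ``non_mixed`` assigns whole subjects to
exactly one partition (the leakage-free protocol), ``mixed`` shuffles
pooled samples ignoring subject identity (the leakage-prone protocol the
package exists to expose).  Every subject's contribution is capped (default
2000 windows) to keep the pool balanced.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ppgbp import preprocess as pp
from ppgbp.labels import BPLabel, PlausibilityConfig, label_window
from ppgbp.preprocess import SignalWindow, WaveformRecord, WindowingConfig
from ppgbp.synthetic import RgbTrace

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSet", "DatasetSplit", "PersonalizationPartition",
    "windows_from_record", "build_pool", "rppg_windows_from_trace",
    "cap_subjects", "split_non_mixed", "split_mixed",
    "make_personalization_partition", "DEFAULT_SUBJECT_CAP",
]

DEFAULT_SUBJECT_CAP = 2000


@dataclass
class WindowSet:
    """Aligned arrays of windows, labels and provenance."""

    X: np.ndarray          # (n, length, channels)
    y: np.ndarray          # (n, 2): SBP, DBP in mmHg
    subject: np.ndarray    # (n,) str
    offset: np.ndarray     # (n,) int, sample offset in the parent record
    hr: np.ndarray         # (n,) estimated or label HR
    snr: np.ndarray        # (n,) dB

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(self.X[idx], self.y[idx], self.subject[idx],
                         self.offset[idx], self.hr[idx], self.snr[idx])

    def subjects(self) -> np.ndarray:
        return np.unique(self.subject)

    def by_subject(self, subject_id: str) -> "WindowSet":
        return self.subset(np.nonzero(self.subject == subject_id)[0])

    def window_ids(self) -> set[tuple[str, int]]:
        return set(zip(self.subject.tolist(), self.offset.tolist()))

    @classmethod
    def from_pairs(cls, pairs: list[tuple[SignalWindow, BPLabel]]) -> "WindowSet":
        if not pairs:
            raise ValueError("no windows")
        X = np.stack([
            w.samples if w.samples.ndim == 2 else w.samples[:, None]
            for w, _ in pairs])
        return cls(
            X=X,
            y=np.array([[lb.sbp, lb.dbp] for _, lb in pairs]),
            subject=np.array([w.subject_id for w, _ in pairs]),
            offset=np.array([w.source_offset for w, _ in pairs]),
            hr=np.array([lb.median_hr for _, lb in pairs]),
            snr=np.array([w.snr_db for w, _ in pairs]),
        )

    @classmethod
    def concat(cls, sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("nothing to concatenate")
        return cls(*[np.concatenate([getattr(s, f) for s in sets])
                     for f in ("X", "y", "subject", "offset", "hr", "snr")])


def windows_from_record(record: WaveformRecord,
                        windowing: WindowingConfig | None = None,
                        snr_threshold: float = -7.0,
                        plausibility: PlausibilityConfig | None = None,
                        derivatives: bool = False,
                        bandpass: bool = True,
                        ) -> tuple[list[tuple[SignalWindow, BPLabel]], dict]:
    """Run the standard preprocessing pipeline on one record.

    Stage order is fixed (asserted against ``preprocess.PIPELINE_ORDER``):
    band-pass filter, crop, SNR gate, label + plausibility filter,
    optional derivative channels, normalize.  Returns the surviving
    (window, label) pairs and an attrition log of counts per stage.
    """
    assert pp.PIPELINE_ORDER == ("bandpass", "crop", "snr_gate",
                                 "label_filter", "normalize")
    windowing = windowing or WindowingConfig()
    plausibility = plausibility or PlausibilityConfig()
    if bandpass:
        record = pp.bandpass_ppg(record)
    cropped = pp.crop_windows(record, windowing)
    attrition = {"cropped": len(cropped)}
    # SNR is computed on the model-input window (resampled timeline for
    # const_beats, where the notional rate is 125 Hz)
    snr_fs = 125.0 if windowing.strategy == "const_beats" else record.fs
    survivors = []
    for window, abp_seg in cropped:
        window.snr_db = pp.compute_snr(window.samples, snr_fs).snr_db
        if window.snr_db >= snr_threshold:
            survivors.append((window, abp_seg))
    attrition["snr_gated"] = len(survivors)
    pairs = []
    for window, abp_seg in survivors:
        if abp_seg is None:
            raise ValueError("record has no ABP channel; cannot label")
        hr_hint = window.estimated_hr if np.isfinite(window.estimated_hr) else 75.0
        label = label_window(abp_seg, record.fs, plausibility, hr_hint=hr_hint)
        if label.valid:
            pairs.append((window, label))
    attrition["label_filtered"] = len(pairs)
    out = []
    for window, label in pairs:
        if derivatives:
            window = pp.add_derivative_channels(window)
        try:
            out.append((pp.normalize_window(window), label))
        except pp.ConstantChannelError:
            continue
    attrition["normalized"] = len(out)
    logger.info("pipeline attrition for %s: %s", record.subject_id, attrition)
    return out, attrition


def build_pool(records: list[WaveformRecord], **kwargs) -> WindowSet:
    """Pipeline every record and pool the surviving windows."""
    sets = []
    for record in records:
        pairs, _ = windows_from_record(record, **kwargs)
        if pairs:
            sets.append(WindowSet.from_pairs(pairs))
    return WindowSet.concat(sets)


def rppg_windows_from_trace(trace: RgbTrace, n_beats: int = 7,
                            snr_threshold: float = -7.0,
                            ) -> WindowSet | None:
    """POS-extract, window and label a camera trace.

    The extracted pulse is windowed with the const_beats strategy and each
    window is labelled with the reference BP reading of the nearest minute
    (bedside-monitor resolution).  Returns ``None`` when no window
    survives the SNR gate.
    """
    pulse = pp.pos_extract(trace.rgb, trace.fs)
    record = WaveformRecord(subject_id=trace.subject_id, ppg=pulse,
                            abp=None, fs=trace.fs)
    cfg = WindowingConfig(strategy="const_beats", length_parameter=n_beats)
    pairs = []
    for window, _ in pp.crop_windows(record, cfg):
        window.snr_db = pp.compute_snr(window.samples, 125.0).snr_db
        if window.snr_db < snr_threshold:
            continue
        span = window.n_samples  # resampled; use source time for reference
        t_center = (window.source_offset
                    + 0.5 * n_beats * (60.0 / window.estimated_hr) * trace.fs
                    ) / trace.fs
        ref_i = int(np.argmin(np.abs(trace.ref_times_s - t_center)))
        label = BPLabel(sbp=float(trace.ref_sbp[ref_i]),
                        dbp=float(trace.ref_dbp[ref_i]),
                        median_hr=window.estimated_hr,
                        n_systolic_peaks=n_beats, valid=True)
        try:
            pairs.append((pp.normalize_window(window), label))
        except pp.ConstantChannelError:
            continue
    return WindowSet.from_pairs(pairs) if pairs else None


def _derived_seed(seed: int, *parts: str) -> int:
    digest = hashlib.sha256(":".join([str(seed), *parts]).encode()).digest()
    return int.from_bytes(digest[:4], "little")


def cap_subjects(pool: WindowSet, cap: int = DEFAULT_SUBJECT_CAP,
                 seed: int = 0) -> WindowSet:
    """Limit every subject to at most ``cap`` windows (seeded uniform)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    keep = []
    for sid in pool.subjects():
        idx = np.nonzero(pool.subject == sid)[0]
        if len(idx) > cap:
            rng = np.random.default_rng(_derived_seed(seed, "cap", sid))
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        keep.append(idx)
    return pool.subset(np.concatenate(keep))


@dataclass
class DatasetSplit:
    mode: str                      # non_mixed | mixed
    train: WindowSet
    val: WindowSet
    test: WindowSet
    subject_assignment: dict = field(default_factory=dict)
    per_subject_cap: int = DEFAULT_SUBJECT_CAP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "non_mixed":
            tr, va, te = (set(s.subject) for s in (self.train, self.val, self.test))
            if tr & va or tr & te or va & te:
                raise AssertionError("non-mixed split has overlapping subjects")
        ids = [s.window_ids() for s in (self.train, self.val, self.test)]
        if ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2]:
            raise AssertionError("sample collections overlap")
        for s in (self.train, self.val, self.test):
            counts = np.unique(s.subject, return_counts=True)[1]
            if counts.size and counts.max() > self.per_subject_cap:
                raise AssertionError("per-subject cap exceeded")


def _draw(pool: WindowSet, n: int, rng: np.random.Generator) -> WindowSet:
    if n >= len(pool):
        return pool
    return pool.subset(np.sort(rng.choice(len(pool), size=n, replace=False)))


def split_non_mixed(pool: WindowSet, n_train_subjects: int,
                    n_val_subjects: int, n_test_subjects: int,
                    n_train: int | None = None, n_val: int | None = None,
                    n_test: int | None = None, seed: int = 0,
                    cap: int = DEFAULT_SUBJECT_CAP) -> DatasetSplit:
    """Subject-disjoint split with per-partition sample draws.

    Requests larger than the pool are scaled down proportionally with a
    warning, preserving the requested train:val:test ratios.
    """
    pool = cap_subjects(pool, cap, seed)
    subjects = pool.subjects()
    rng = np.random.default_rng(_derived_seed(seed, "non_mixed"))
    total_req = n_train_subjects + n_val_subjects + n_test_subjects
    if total_req > len(subjects):
        scale = len(subjects) / total_req
        n_train_subjects = max(1, int(n_train_subjects * scale))
        n_val_subjects = max(1, int(n_val_subjects * scale))
        n_test_subjects = max(
            1, min(n_test_subjects,
                   len(subjects) - n_train_subjects - n_val_subjects))
        warnings.warn("subject request exceeds pool; scaled down "
                      f"to {n_train_subjects}/{n_val_subjects}/{n_test_subjects}")
    perm = rng.permutation(subjects)
    groups = {
        "train": set(perm[:n_train_subjects]),
        "val": set(perm[n_train_subjects:n_train_subjects + n_val_subjects]),
        "test": set(perm[n_train_subjects + n_val_subjects:
                         n_train_subjects + n_val_subjects + n_test_subjects]),
    }
    assignment = {}
    for part, sids in groups.items():
        for sid in sids:
            assignment[sid] = part
    for sid in perm[n_train_subjects + n_val_subjects + n_test_subjects:]:
        assignment[sid] = "excluded"
    parts = {}
    for part, requested in (("train", n_train), ("val", n_val), ("test", n_test)):
        mask = np.isin(pool.subject, sorted(groups[part]))
        ws = pool.subset(np.nonzero(mask)[0])
        if requested is not None and requested < len(ws):
            ws = _draw(ws, requested, np.random.default_rng(
                _derived_seed(seed, "draw", part)))
        elif requested is not None and requested > len(ws):
            warnings.warn(f"{part}: requested {requested} samples, "
                          f"only {len(ws)} available")
        parts[part] = ws
    return DatasetSplit(mode="non_mixed", train=parts["train"],
                        val=parts["val"], test=parts["test"],
                        subject_assignment=assignment, per_subject_cap=cap,
                        seed=seed)


def split_mixed(pool: WindowSet, n_subjects: int | None = None,
                fractions: tuple[float, float, float] = (2 / 3, 1 / 6, 1 / 6),
                seed: int = 0, cap: int = DEFAULT_SUBJECT_CAP) -> DatasetSplit:
    """Sample-random split ignoring subject identity (leakage-prone)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pool = cap_subjects(pool, cap, seed)
    rng = np.random.default_rng(_derived_seed(seed, "mixed"))
    subjects = pool.subjects()
    if n_subjects is not None and n_subjects < len(subjects):
        chosen = rng.choice(subjects, size=n_subjects, replace=False)
        pool = pool.subset(np.nonzero(np.isin(pool.subject, chosen))[0])
    perm = rng.permutation(len(pool))
    n = len(perm)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return DatasetSplit(
        mode="mixed",
        train=pool.subset(perm[:n_train]),
        val=pool.subset(perm[n_train:n_train + n_val]),
        test=pool.subset(perm[n_train + n_val:]),
        per_subject_cap=cap, seed=seed)


@dataclass
class PersonalizationPartition:
    """Calibration/test partition of one test subject's windows.

    The subject's windows are ordered by source offset.  The first 20%
    (ceil) is the systematic calibration set; the last 80% is cut at its
    midpoint into a spare pool (usable by the random strategy) and the
    test set.  The test set is identical for both strategies.
    """

    subject_id: str
    strategy: str                  # first_20 | random_20
    calibration: WindowSet
    test: WindowSet
    spare_pool: WindowSet

    def __post_init__(self) -> None:
        if self.calibration.window_ids() & self.test.window_ids():
            raise AssertionError("calibration and test overlap")


def make_personalization_partition(subject_windows: WindowSet,
                                   strategy: str = "first_20",
                                   seed: int = 0) -> PersonalizationPartition:
    if strategy not in ("first_20", "random_20"):
        raise ValueError(f"unknown personalization strategy {strategy!r}")
    n = len(subject_windows)
    if n < 10:
        raise ValueError("need at least 10 windows to personalize")
    sids = np.unique(subject_windows.subject)
    if len(sids) != 1:
        raise ValueError("windows from more than one subject")
    order = np.argsort(subject_windows.offset, kind="stable")
    ws = subject_windows.subset(order)
    n_cal = int(np.ceil(0.2 * n))
    mid = n_cal + (n - n_cal) // 2
    test = ws.subset(np.arange(mid, n))
    if strategy == "first_20":
        calibration = ws.subset(np.arange(n_cal))
        spare = ws.subset(np.arange(n_cal, mid))
    else:
        rng = np.random.default_rng(_derived_seed(seed, "pers", str(sids[0])))
        candidates = np.arange(mid)   # first 20% plus the spare half
        chosen = np.sort(rng.choice(candidates, size=n_cal, replace=False))
        calibration = ws.subset(chosen)
        spare = ws.subset(np.setdiff1d(candidates, chosen))
    return PersonalizationPartition(subject_id=str(sids[0]), strategy=strategy,
                                    calibration=calibration, test=test,
                                    spare_pool=spare)
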