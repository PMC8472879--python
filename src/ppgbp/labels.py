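"""Ground-truth SBP/DBP extraction from ABP segments and plausibility gating.

For each window the reference systolic (diastolic) pressure is the median of
the systolic peak (inter-peak trough) values of the arterial waveform over
the same time span, and the reference heart rate is the median of the
inverse inter-peak intervals.  Labels outside the physiologically plausible
ranges — 75-165 mmHg systolic, 40-80 mmHg diastolic, 50-140 bpm — are
flagged invalid and discarded downstream.  Bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ppgbp.preprocess import SignalWindow

__all__ = [
    "BPLabel",
    "PlausibilityConfig",
    "TooFewPeaksError",
    "detect_abp_extrema",
    "label_window",
    "filter_labelled_windows",
]

REJECT_REASONS = ("sbp_range", "dbp_range", "hr_range", "too_few_peaks", "none")


@dataclass
class PlausibilityConfig:
    sbp_range: tuple[float, float] = (75.0, 165.0)   # mmHg
    dbp_range: tuple[float, float] = (40.0, 80.0)    # mmHg
    hr_range: tuple[float, float] = (50.0, 140.0)    # beats/min

    def __post_init__(self) -> None:
        for lo, hi in (self.sbp_range, self.dbp_range, self.hr_range):
            if lo >= hi:
                raise ValueError("range low must be below high")


@dataclass
class BPLabel:
    sbp: float
    dbp: float
    median_hr: float
    n_systolic_peaks: int
    valid: bool
    reject_reason: str = "none"

    def __post_init__(self) -> None:
        if self.reject_reason not in REJECT_REASONS:
            raise ValueError(f"unknown reject_reason {self.reject_reason!r}")
        if self.valid != (self.reject_reason == "none"):
            raise ValueError("valid flag inconsistent with reject_reason")


class TooFewPeaksError(ValueError):
    """Fewer than two systolic peaks were found in the ABP segment."""


def detect_abp_extrema(abp_segment: np.ndarray, fs: float,
                       hr_hint: float = 75.0):
    """Locate systolic peaks and the diastolic troughs between them.

    Peaks: local maxima at least ``0.5 * (60 / hr_hint)`` s apart with
    prominence of at least 10% of the segment's amplitude range.  Troughs:
    the minimum between each pair of consecutive peaks.  Returns
    ``(peak_values, peak_indices, trough_values, trough_indices)``.
    """
    abp = np.asarray(abp_segment, dtype=float)
    amp = abp.max() - abp.min()
    if amp <= 0.0:
        raise TooFewPeaksError("segment has no oscillation")
    distance = max(1, int(round(0.5 * (60.0 / hr_hint) * fs)))
    peak_idx, _ = find_peaks(abp, distance=distance, prominence=0.1 * amp)
    if len(peak_idx) < 2:
        raise TooFewPeaksError(f"only {len(peak_idx)} systolic peaks found")
    trough_idx = np.array([
        lo + int(np.argmin(abp[lo:hi]))
        for lo, hi in zip(peak_idx[:-1], peak_idx[1:])
    ])
    return abp[peak_idx], peak_idx, abp[trough_idx], trough_idx


def label_window(abp_segment: np.ndarray, fs: float,
                 cfg: PlausibilityConfig | None = None,
                 hr_hint: float = 75.0) -> BPLabel:
    """Median-based SBP/DBP/HR label with plausibility validation.

    Violations are flagged once, in check order SBP -> DBP -> HR.  HR is
    computed from ABP inter-peak intervals so the label never depends on
    PPG quality.
    """
    cfg = cfg or PlausibilityConfig()
    try:
        peaks, peak_idx, troughs, _ = detect_abp_extrema(abp_segment, fs, hr_hint)
    except TooFewPeaksError:
        return BPLabel(sbp=np.nan, dbp=np.nan, median_hr=np.nan,
                       n_systolic_peaks=0, valid=False,
                       reject_reason="too_few_peaks")
    sbp = float(np.median(peaks))
    dbp = float(np.median(troughs))
    intervals_s = np.diff(peak_idx) / fs
    median_hr = float(np.median(60.0 / intervals_s))
    reason = "none"
    if not cfg.sbp_range[0] <= sbp <= cfg.sbp_range[1]:
        reason = "sbp_range"
    elif not cfg.dbp_range[0] <= dbp <= cfg.dbp_range[1]:
        reason = "dbp_range"
    elif not cfg.hr_range[0] <= median_hr <= cfg.hr_range[1]:
        reason = "hr_range"
    return BPLabel(sbp=sbp, dbp=dbp, median_hr=median_hr,
                   n_systolic_peaks=len(peaks), valid=reason == "none",
                   reject_reason=reason)


def filter_labelled_windows(pairs: list[tuple[SignalWindow, BPLabel]],
                            ) -> tuple[list[tuple[SignalWindow, BPLabel]], dict]:
    """Keep only valid (window, label) pairs; report per-reason counts."""
    counts = {r: 0 for r in REJECT_REASONS if r != "none"}
    kept = []
    for window, label in pairs:
        if label.valid:
            kept.append((window, label))
        else:
            counts[label.reject_reason] += 1
    return kept, counts
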