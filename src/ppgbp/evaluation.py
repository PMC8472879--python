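"""Error evaluation: overall and bin-wise MAE, significance tests, grading.

The headline metric is the mean absolute error (MAE) of predicted systolic
and diastolic pressure.  Because a regressor biased towards the mode of
the training distribution can look deceptively good on average, errors are
additionally resolved into 10 mmHg bins of the true BP (half-open,
anchored at the lower plausibility bound, final bin closed).  Distribution
comparisons use a two-sample Kolmogorov-Smirnov test on per-window
absolute errors or a paired t-test on matched repetition cells, both at
alpha = 0.05.  The BHS-style grade reports the fraction of absolute errors
below 10 mmHg against the 85% pass mark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult", "EvaluationReport", "mae", "binwise_mae",
    "compare_error_distributions", "bhs_grade", "build_report",
    "SBP_BIN_RANGE", "DBP_BIN_RANGE",
]

SBP_BIN_RANGE = (75.0, 165.0)
DBP_BIN_RANGE = (40.0, 80.0)
BIN_WIDTH = 10.0
ALPHA = 0.05
BHS_THRESHOLD_MMHG = 10.0
BHS_PASS_FRACTION = 0.85


def mae(predictions: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(MAE_SBP, MAE_DBP) in mmHg for (n, 2) prediction/label arrays."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal shape")
    if len(predictions) == 0:
        raise ValueError("empty input")
    err = np.abs(predictions - labels)
    return float(err[:, 0].mean()), float(err[:, 1].mean())


def binwise_mae(y_true: np.ndarray, y_pred: np.ndarray,
                bin_range: tuple[float, float], bin_width: float = BIN_WIDTH,
                ) -> pd.DataFrame:
    """Per-bin MAE table over the true-label range.

    Bins are ``[low, low+width)`` anchored at ``bin_range[0]``; the final
    bin is closed so the upper bound is included.  Empty bins get count 0
    and MAE ``NaN`` (excluded from any aggregation).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    lo, hi = bin_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    idx = np.floor((y_true - lo) / bin_width).astype(int)
    idx = np.where(y_true == hi, len(edges) - 2, idx)  # close the last bin
    abs_err = np.abs(y_pred - y_true)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "count": int(mask.sum()),
            "mae": float(abs_err[mask].mean()) if mask.any() else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    design: str                 # paired_t | two_sample_ks
    statistic: float
    p_value: float
    alpha: float = ALPHA
    significant: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.significant != (self.p_value < self.alpha):
            raise ValueError("significance flag inconsistent with p-value")


def compare_error_distributions(errors_a: np.ndarray, errors_b: np.ndarray,
                                design: str = "two_sample_ks",
                                ) -> ComparisonResult:
    """Compare two error samples.

    ``two_sample_ks`` compares per-window absolute-error distributions;
    ``paired_t`` requires matched observations (same repetition cells).
    A paired design with constant nonzero difference and zero variance is
    reported as perfectly separated (p = 0) rather than crashing.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if design == "two_sample_ks":
        res = stats.ks_2samp(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        degenerate = False
    elif design == "paired_t":
        if len(a) != len(b):
            raise ValueError("paired design requires equal lengths")
        diff = a - b
        if np.allclose(diff.std(), 0.0):
            if np.allclose(diff, 0.0):
                stat, p, degenerate = 0.0, 1.0, True
            else:
                stat, p, degenerate = np.inf * np.sign(diff.mean()), 0.0, True
        else:
            res = stats.ttest_rel(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
            degenerate = False
    else:
        raise ValueError(f"unknown design {design!r}")
    return ComparisonResult(design=design, statistic=stat, p_value=p,
                            significant=p < ALPHA, degenerate=degenerate)


def bhs_grade(errors: np.ndarray) -> tuple[float, bool]:
    """Fraction of absolute errors below 10 mmHg and the 85% pass flag."""
    errors = np.abs(np.asarray(errors, dtype=float))
    if len(errors) == 0:
        raise ValueError("empty input")
    frac = float(np.mean(errors < BHS_THRESHOLD_MMHG))
    return frac, frac > BHS_PASS_FRACTION


@dataclass
class EvaluationReport:
    """Overall + bin-wise MAE, baseline comparison and grading of one run."""

    overall_mae_sbp: float
    overall_mae_dbp: float
    n_test: int
    bin_width: float
    bins_sbp: list = field(default_factory=list)   # rows of binwise_mae
    bins_dbp: list = field(default_factory=list)
    baseline_mae_sbp: float = np.nan
    baseline_mae_dbp: float = np.nan
    ks_results: list = field(default_factory=list)
    bhs_within_10mmhg_sbp: float = np.nan
    bhs_within_10mmhg_dbp: float = np.nan
    bhs_pass_sbp: bool = False
    bhs_pass_dbp: bool = False
    n_significance_tests: int = 0

    def __post_init__(self) -> None:
        for bins, overall in ((self.bins_sbp, self.overall_mae_sbp),
                              (self.bins_dbp, self.overall_mae_dbp)):
            if bins:
                counts = np.array([b["count"] for b in bins], dtype=float)
                maes = np.array([b["mae"] if b["count"] else 0.0 for b in bins])
                if counts.sum() > 0:
                    agg = float((counts * maes).sum() / counts.sum())
                    if abs(agg - overall) > 1e-9:
                        raise AssertionError(
                            "bin-weighted MAE does not aggregate to overall "
                            f"({agg} vs {overall})")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvaluationReport":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        return cls(**data)

    def bins_frame(self, which: str = "sbp") -> pd.DataFrame:
        return pd.DataFrame(self.bins_sbp if which == "sbp" else self.bins_dbp)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def build_report(predictions: np.ndarray, labels: np.ndarray,
                 baseline_predictions: np.ndarray | None = None,
                 comparisons: list[tuple[str, np.ndarray, np.ndarray]] | None = None,
                 bin_width: float = BIN_WIDTH) -> EvaluationReport:
    """Assemble the full evaluation report for one test set.

    ``comparisons`` is a list of (label, errors_a, errors_b) tuples, each
    tested with the two-sample KS design.  No multiple-testing correction
    is applied; the number of tests is recorded in the report.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    mae_sbp, mae_dbp = mae(predictions, labels)
    bins_sbp = binwise_mae(labels[:, 0], predictions[:, 0], SBP_BIN_RANGE,
                           bin_width)
    bins_dbp = binwise_mae(labels[:, 1], predictions[:, 1], DBP_BIN_RANGE,
                           bin_width)
    abs_err = np.abs(predictions - labels)
    frac_s, pass_s = bhs_grade(abs_err[:, 0])
    frac_d, pass_d = bhs_grade(abs_err[:, 1])
    report = EvaluationReport(
        overall_mae_sbp=mae_sbp, overall_mae_dbp=mae_dbp,
        n_test=len(labels), bin_width=bin_width,
        bins_sbp=bins_sbp.to_dict("records"),
        bins_dbp=bins_dbp.to_dict("records"),
        bhs_within_10mmhg_sbp=frac_s, bhs_within_10mmhg_dbp=frac_d,
        bhs_pass_sbp=pass_s, bhs_pass_dbp=pass_d,
    )
    if baseline_predictions is not None:
        b_sbp, b_dbp = mae(np.asarray(baseline_predictions, dtype=float), labels)
        report.baseline_mae_sbp = b_sbp
        report.baseline_mae_dbp = b_dbp
    if comparisons:
        for name, ea, eb in comparisons:
            res = compare_error_distributions(ea, eb, "two_sample_ks")
            report.ks_results.append({
                "comparison": name, "statistic": res.statistic,
                "p_value": res.p_value, "significant": res.significant})
        report.n_significance_tests = len(comparisons)
    return report
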