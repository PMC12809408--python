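"""Benchmark harness: ROC/AUROC, calibration, confusion, FDR, secretion timing.

AUROC follows the Mann–Whitney formulation (ties counted 1/2). Undefined
precision under zero predicted positives is reported as 1.0 with an explicit
flag, keeping the edge case auditable while matching the convention of
reporting perfect precision when no call is wrong. The time-to-peak statistic
summarizes dynamic secretion traces: baseline-subtracted values, time of the
maximum within the stimulus window, measured from stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(float).ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    return y.astype(int)


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    return float(roc_auc_score(y, s))


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """ROC curve as (fpr, tpr, threshold) triples from (0,0) to (1,1)."""
    y = _check_binary(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=np.float64))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def confusion_and_precision(calls, labels) -> dict:
    """tp/fp/fn/tn counts plus precision and recall.

    Precision with zero predicted positives is reported as 1.0 with
    ``zero_predicted_positives=True``; recall with zero actual positives is
    reported as 0.0 with ``zero_actual_positives=True``.
    """
    y = _check_binary(labels)
    c = _check_binary(calls)
    if c.shape != y.shape:
        raise ValueError("calls and labels must have equal length")
    tp = int(np.sum((c == 1) & (y == 1)))
    fp = int(np.sum((c == 1) & (y == 0)))
    fn = int(np.sum((c == 0) & (y == 1)))
    tn = int(np.sum((c == 0) & (y == 0)))
    zero_pred = (tp + fp) == 0
    zero_actual = (tp + fn) == 0
    precision = 1.0 if zero_pred else tp / (tp + fp)
    recall = 0.0 if zero_actual else tp / (tp + fn)
    return {
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "precision": float(precision),
        "recall": float(recall),
        "zero_predicted_positives": zero_pred,
        "zero_actual_positives": zero_actual,
    }


def calibration_curve(scores, labels, n_bins: int = 10) -> list[dict]:
    """Equal-width reliability bins on [0, 1]; empty bins omitted.

    A score of exactly 1.0 falls in the last bin. Each bin reports its
    midpoint, the mean score, the empirical positive fraction and the count.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if s.size and (s.min() < 0 or s.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    idx = np.minimum((s * n_bins).astype(int), n_bins - 1)
    bins = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        bins.append(
            {
                "bin_mid": (b + 0.5) / n_bins,
                "mean_score": float(s[mask].mean()),
                "frac_positive": float(y[mask].mean()),
                "n": n,
            }
        )
    return bins


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=np.float64).ravel()
    if p.size == 0:
        return p.copy()
    if p.min() < 0 or p.max() > 1 or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SecretionTrace:
    """A dynamic secretion time course with baseline and stimulus windows."""

    times: np.ndarray  # minutes, strictly increasing
    values: np.ndarray
    baseline_window: tuple[float, float]
    stimulus_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, (lo, hi) in (
            ("baseline", self.baseline_window),
            ("stimulus", self.stimulus_window),
        ):
            if lo >= hi:
                raise ValueError(f"{name} window must have positive width")
            if lo < self.times[0] or hi > self.times[-1]:
                raise ValueError(f"{name} window outside the time range")
        if self.baseline_window[1] > self.stimulus_window[0]:
            raise ValueError("baseline window must precede the stimulus window")


class TimeToPeak(NamedTuple):
    minutes: float
    flat: bool


def time_to_peak(trace: SecretionTrace) -> TimeToPeak:
    """Minutes from stimulus onset to the maximum baseline-subtracted value.

    The baseline is the mean over the baseline window; ties and flat traces
    resolve to the earliest stimulus timepoint, the latter flagged.
    """
    t, v = trace.times, trace.values
    b0, b1 = trace.baseline_window
    s0, s1 = trace.stimulus_window
    base_mask = (t >= b0) & (t <= b1)
    if not base_mask.any():
        raise ValueError("no timepoints in the baseline window")
    stim_mask = (t >= s0) & (t <= s1)
    if stim_mask.sum() < 2:
        raise ValueError("stimulus window must contain at least 2 timepoints")
    sub = v - v[base_mask].mean()
    stim_t = t[stim_mask]
    stim_v = sub[stim_mask]
    flat = bool(np.ptp(stim_v) == 0)
    peak_idx = int(np.argmax(stim_v))  # argmax returns the earliest tie
    return TimeToPeak(minutes=float(stim_t[peak_idx] - s0), flat=flat)


def score_correlation(scores, reference) -> dict[str, float]:
    """Pearson R^2 and Spearman rho between two per-sample score vectors."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    r = np.asarray(reference, dtype=np.float64).ravel()
    if s.shape != r.shape:
        raise ValueError("score vectors must have equal length")
    pr = pearsonr(s, r)[0]
    return {"pearson_r2": float(pr**2), "spearman_rho": float(spearmanr(s, r)[0])}


def benchmark_scores(
    scores,
    labels,
    threshold: float = 0.5,
    n_bins: int = 10,
    reference=None,
) -> dict:
    """Full evaluation report for a score vector against binary labels."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    calls = (s > threshold).astype(int)
    report = {
        "auroc": auroc(s, labels),
        "roc_points": roc_points(s, labels),
        "calibration_bins": calibration_curve(np.clip(s, 0, 1), labels, n_bins=n_bins),
        **confusion_and_precision(calls, labels),
        "threshold": float(threshold),
        "n": int(len(s)),
    }
    if reference is not None:
        report["score_correlation"] = score_correlation(s, reference)
    return report


def tidy_sample_table(result, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample table (sid, group, donor, ...) for external model fitting.

    Mixed-effects modeling of SID against donor structure is delegated to
    external statistics tooling; this emits the tidy input it needs.
    """
    table = result.to_frame()
    if metadata is not None:
        table = table.merge(metadata, on="sample_id", how="left")
    return table
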