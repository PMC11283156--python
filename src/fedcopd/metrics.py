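"""Classification metrics: thresholded confusion counts, accuracy/precision/
recall/F1, rank-based ROC/AUC, and normal-theory CIs over repeated runs.

Severe (label 1) is the positive class throughout.  The decision threshold is
0.5 with ties mapped to positive.  Degenerate denominators (no predicted
positives, no actual positives, P+R = 0) yield 0 with a warning rather than an
error so that sweeps with tiny test sets complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


class DegenerateMetricWarning(UserWarning):
    """A metric denominator was zero; the metric was reported as 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class IntervalSummary:
    """Mean and normal-approximation CI of a metric over m repeated runs."""

    metric: str
    m: int
    mean: float
    lower: float
    upper: float


def confusion(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN; prediction is positive iff probability ≥ threshold."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(p):
        raise ValueError("labels and probabilities must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _degenerate(name: str) -> float:
    warnings.warn(
        f"{name}: zero denominator, reporting 0", DegenerateMetricWarning, stacklevel=3
    )
    return 0.0


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN) / (TP+TN+FP+FN)."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP+FP); 0 with a warning when nothing is predicted positive."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    if c.tp + c.fp == 0:
        return _degenerate("precision")
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP+FN); 0 with a warning when there are no actual positives."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    if c.tp + c.fn == 0:
        return _degenerate("recall")
    return c.tp / (c.tp + c.fn)


def f1(c: ConfusionCounts) -> float:
    """2·P·R / (P+R); 0 with a warning when P+R = 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateMetricWarning)
        p, r = precision(c), recall(c)
    if p + r == 0:
        return _degenerate("f1")
    return 2.0 * p * r / (p + r)


def roc_auc(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """AUC by the rank (Mann–Whitney) formulation plus the traced ROC curve.

    Ties are credited 0.5.  The ROC is traced over all unique score
    thresholds in decreasing order and always starts at (0, 0) and ends at
    (1, 1); since ties share a threshold, its trapezoidal area equals the
    rank-based AUC exactly in the absence of ties.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")

    ranks = stats.rankdata(s)  # average ranks handle ties at 0.5 credit
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last point of each tied-threshold run
    last_of_run = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    thresholds = s_sorted[last_of_run]
    tpr = tps[last_of_run] / n_pos
    fpr = fps[last_of_run] / n_neg
    roc = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, thresholds],
            "fpr": np.r_[0.0, fpr],
            "tpr": np.r_[0.0, tpr],
        }
    )
    return float(auc), roc


def metrics_report(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> dict:
    """All five headline metrics (plus the ROC trace) for one prediction set."""
    c = confusion(labels, probabilities, threshold)
    auc, roc = roc_auc(labels, probabilities)
    return {
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
        "f1": f1(c),
        "auc": auc,
        "confusion": c,
        "roc": roc,
    }


def repeated_ci(
    values: list[float] | np.ndarray, level: float = 0.95, metric: str = ""
) -> IntervalSummary:
    """Normal-approximation CI of the mean over m repeated runs:
    mean ± z·sd/√m with the sample standard deviation (ddof=1)."""
    v = np.asarray(values, dtype=float)
    m = len(v)
    if m < 2:
        raise ValueError("need at least two repeated values")
    z = stats.norm.ppf(0.5 + level / 2.0)
    mean = float(v.mean())
    half = float(z * v.std(ddof=1) / np.sqrt(m))
    return IntervalSummary(metric=metric, m=m, mean=mean, lower=mean - half, upper=mean + half)
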