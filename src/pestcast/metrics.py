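"""Chronological splitting and binary-classification metrics.

Accuracy and F1 follow the confusion-count definitions

    ACC = (TP + TN) / (P + N)          F1 = 2 TP / (P + P')

with P = TP + FN actual positives and P' = TP + FP predicted positives; the
F1 form is algebraically identical to the harmonic mean of precision and
recall.  AUC is computed as a rank statistic: with scores ranked ascending
(ties receiving average ranks, which credits half a concordance per tie),

    AUC = (sum of positive ranks - M(M+1)/2) / (M * N)

for M positives and N negatives — the Mann-Whitney concordance probability.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import InsufficientDataError, InvalidArgumentError, \
    UndefinedMetricError

logger = logging.getLogger(__name__)

__all__ = [
    "chronological_split", "confusion_counts", "accuracy_f1", "auc_rank",
    "roc_curve", "EvaluationReport", "evaluate_predictions",
]


def chronological_split(data, train_fraction: float = 0.75):
    """Split a time-ordered sliceable into (first ``train_fraction``, rest).

    The train part is the first ``floor(train_fraction * n)`` items in time
    order; nothing is shuffled.  Works on any object supporting ``len`` and
    slice indexing (arrays, lists, PestDataset, WindowedDataset).
    """
    if not 0.0 < train_fraction < 1.0:
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    n = len(data)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 records to split, got {n}")
    cut = math.floor(train_fraction * n)
    cut = min(max(cut, 1), n - 1)   # both parts non-empty
    return data[:cut], data[cut:]


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.ndim != 1:
        arr = arr.ravel()
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise InvalidArgumentError(f"{name} must be binary 0/1")
    return arr.astype(int)


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """Exact (TP, TN, FP, FN) counts for binary vectors."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise InvalidArgumentError("y_true and y_pred lengths differ")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return tp, tn, fp, fn


def accuracy_f1(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float]:
    """ACC = (TP+TN)/(P+N) and F1 = 2TP/(P+P')."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise InvalidArgumentError("confusion counts sum to zero")
    acc = (tp + tn) / total
    p_actual = tp + fn
    p_pred = tp + fp
    if p_actual + p_pred == 0:
        logger.warning("no actual or predicted positives; defining F1 = 0")
        return acc, 0.0
    return acc, 2.0 * tp / (p_actual + p_pred)


def auc_rank(y_true, scores) -> float:
    """Rank-statistic AUC with average ranks for tied scores."""
    yt = _as_binary(y_true, "y_true")
    s = np.asarray(scores, float).ravel()
    if yt.shape != s.shape:
        raise InvalidArgumentError("y_true and scores lengths differ")
    m = int(yt.sum())
    n_neg = yt.size - m
    if m == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(s)  # ascending, ties -> average rank
    return float((ranks[yt == 1].sum() - m * (m + 1) / 2.0) / (m * n_neg))


def roc_curve(y_true, scores) -> np.ndarray:
    """(FPR, TPR) points at every distinct score threshold.

    Points are anchored at (0, 0) and (1, 1) and are monotone non-decreasing
    in both coordinates; the trapezoidal area under them equals
    :func:`auc_rank` (ties contribute diagonal segments).
    """
    yt = _as_binary(y_true, "y_true")
    s = np.asarray(scores, float).ravel()
    if yt.shape != s.shape:
        raise InvalidArgumentError("y_true and scores lengths differ")
    m = int(yt.sum())
    n_neg = yt.size - m
    if m == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined with a single class")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = yt[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last index of each run of equal scores
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], yt.size - 1]
    points = np.column_stack([fps[distinct] / n_neg, tps[distinct] / m])
    return np.vstack([[0.0, 0.0], points])


@dataclass
class EvaluationReport:
    """Confusion counts and the three summary metrics for one test split."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    f1: float
    auc: float
    roc_points: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "acc": self.acc, "f1": self.f1, "auc": self.auc,
            "confusion": {"tp": self.tp, "tn": self.tn,
                          "fp": self.fp, "fn": self.fn},
            "roc": [[float(a), float(b)] for a, b in self.roc_points],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_predictions(y_true, scores, threshold: float = 0.5
                         ) -> EvaluationReport:
    """Full report from ground truth and predicted probabilities.

    Hard labels use the ``score >= threshold`` convention.
    """
    s = np.asarray(scores, float).ravel()
    y_pred = (s >= threshold).astype(int)
    tp, tn, fp, fn = confusion_counts(y_true, y_pred)
    acc, f1 = accuracy_f1(tp, tn, fp, fn)
    auc = auc_rank(y_true, s)
    roc = roc_curve(y_true, s)
    return EvaluationReport(tp, tn, fp, fn, acc, f1, auc,
                            roc_points=[tuple(p) for p in roc])
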