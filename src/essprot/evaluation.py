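"""Classification metrics and the top-fraction ranking evaluation.

Covers the standard confusion-matrix metrics (accuracy, precision, recall,
F1, specificity, NPV), threshold-free ROC-AUC and average precision, and
the centrality-style protocol in which the highest-scoring fixed fraction
of proteins (19% for yeast, 11% for human, matching each organism's
essential-protein prevalence scale) is declared essential.

Metrics with a zero denominator are reported as NaN markers, never silently
coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "classification_metrics",
    "roc_auc",
    "pr_ap",
    "rank_cutoff_evaluation",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """One evaluation run; undefined ratios are NaN."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    npv: float
    auc: float = math.nan
    ap: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "npv": self.npv,
            "auc": self.auc,
            "ap": self.ap,
        }


def confusion_counts(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not set(np.unique(y)) <= {0, 1} or not set(np.unique(p)) <= {0, 1}:
        raise ValueError("labels and predictions must be binary")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F1, specificity and NPV from a 2x2 tally."""
    if cc.total == 0:
        raise ValueError("empty confusion counts")
    precision = _ratio(cc.tp, cc.tp + cc.fp)
    recall = _ratio(cc.tp, cc.tp + cc.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=_ratio(cc.tp + cc.tn, cc.total),
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=_ratio(cc.tn, cc.tn + cc.fp),
        npv=_ratio(cc.tn, cc.tn + cc.fn),
    )


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (rank statistic; ties averaged)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    _check_two_class(y)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return float(roc_auc_score(y, s))


def pr_ap(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Average precision: step-wise sum over descending-score thresholds."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    _check_two_class(y)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return float(average_precision_score(y, s))


def rank_cutoff_evaluation(
    scores: Sequence[float],
    labels: Sequence[int],
    top_fraction: float,
    ids: Sequence[str] | None = None,
) -> MetricsReport:
    """Declare the top ``floor(fraction * N)`` proteins positive and score them.

    Sorting is by score descending with a stable id tie-break, so the
    evaluation is reproducible under score ties.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n = s.size
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (-s[i], ids[i]))
    k = int(top_fraction * n)
    predictions = np.zeros(n, dtype=int)
    predictions[order[:k]] = 1
    report = classification_metrics(confusion_counts(y, predictions))
    if len(np.unique(y)) == 2:
        report.auc = roc_auc(y, s)
        report.ap = pr_ap(y, s)
    return report
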