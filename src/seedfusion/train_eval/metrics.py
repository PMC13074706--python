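"""Confusion-derived classification metrics and rank-based AUC.

Binary metrics follow the standard confusion identities

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)      Recall = TP / (TP + FN)
    F1        = 2 P R / (P + R)

with the 0/0 convention mapped to 0 (and a logged warning for an empty
positive-prediction set).  Multi-class inputs are macro-averaged per class
in one-vs-rest form.  AUC is the Mann-Whitney statistic: the probability
that a random positive outscores a random negative, ties counting half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricsReport", "classification_metrics",
           "auc_roc", "confusion_from_predictions"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary counts or a K x K multi-class confusion matrix."""
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    matrix: np.ndarray | None = None     # rows = truth, cols = prediction
    class_ids: tuple = ()

    def __post_init__(self):
        if self.matrix is None and min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.matrix is not None and np.any(np.asarray(self.matrix) < 0):
            raise ValueError("matrix entries must be non-negative")

    @property
    def total(self) -> int:
        if self.matrix is not None:
            return int(np.sum(self.matrix))
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    per_class: pd.DataFrame | None = None
    mean: float | None = None       # filled for few-shot summaries
    sd: float | None = None

    def __post_init__(self):
        for name in ("accuracy", "precision", "recall", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} outside [0, 1]: {v}")


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    if tp + fp == 0:
        logger.warning("no positive predictions; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy/precision/recall/F1 from counts (macro over classes)."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    if counts.matrix is None:
        tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
        accuracy = (tp + tn) / (tp + tn + fp + fn)
        precision, recall, f1 = _prf(tp, fp, fn)
        return MetricsReport(accuracy, precision, recall, f1)

    m = np.asarray(counts.matrix, dtype=float)
    k = m.shape[0]
    accuracy = np.trace(m) / m.sum()
    rows = []
    for i in range(k):
        tp = m[i, i]
        fp = m[:, i].sum() - tp
        fn = m[i, :].sum() - tp
        p, r, f = _prf(tp, fp, fn)
        cid = counts.class_ids[i] if counts.class_ids else i
        rows.append({"class_id": cid, "precision": p, "recall": r, "f1": f,
                     "support": int(m[i, :].sum())})
    table = pd.DataFrame(rows)
    return MetricsReport(accuracy=float(accuracy),
                         precision=float(table["precision"].mean()),
                         recall=float(table["recall"].mean()),
                         f1=float(table["f1"].mean()),
                         per_class=table)


def confusion_from_predictions(true_labels, pred_labels,
                               class_ids=None) -> ConfusionCounts:
    if class_ids is None:
        class_ids = sorted(set(true_labels) | set(pred_labels))
    index = {c: i for i, c in enumerate(class_ids)}
    m = np.zeros((len(class_ids), len(class_ids)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        m[index[t], index[p]] += 1
    return ConfusionCounts(matrix=m, class_ids=tuple(class_ids))


def auc_roc(scores, labels) -> float:
    """Mann-Whitney AUC; raises when only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))
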