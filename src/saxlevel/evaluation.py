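"""Evaluation suite: per-class one-vs-rest scores, weighted AUC, SOTD.

All metrics derive from a pooled 5x5 confusion matrix (rows = true level,
columns = predicted level, ordinals oap=0 .. obs=4).  Because the classes
are anatomically ordered, confusing a slice with an *adjacent* level is a
mild error while skipping a level is an obvious one; SOTD (sum of
off-tridiagonal entries, |true - predicted| >= 2) counts exactly the
obvious errors.  A 5->3 merge (ap/mid/bs -> "in") supports comparison
with three-class slice-level classifiers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.metrics import roc_auc_score

from .curation import N_CLASSES, SliceLabel

__all__ = [
    "confusion_matrix",
    "one_vs_rest_scores",
    "accuracy",
    "weighted_auc",
    "sotd",
    "merge_to_three_class",
    "EvalReport",
    "evaluate",
]

_TOKENS = [c.token for c in SliceLabel]


def _as_ordinals(labels: Sequence) -> np.ndarray:
    arr = np.asarray([int(v) for v in labels], dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
        raise ValueError(f"label ordinals must lie in [0, {N_CLASSES - 1}]")
    return arr


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence) -> np.ndarray:
    """5x5 count matrix; entry (i, j) counts true level i predicted as j."""
    t = _as_ordinals(true_labels)
    p = _as_ordinals(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("true and predicted label lists must have equal length")
    if t.size == 0:
        return np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    return _sk_confusion_matrix(t, p, labels=range(N_CLASSES)).astype(np.int64)


def one_vs_rest_scores(cm: np.ndarray, class_index: int) -> tuple[float, float, float]:
    """Precision, recall and F1 for one class against the rest.

    Degenerate denominators (class absent from predictions and/or truth)
    yield 0 with a warning rather than an error.
    """
    cm = np.asarray(cm)
    tp = float(cm[class_index, class_index])
    fp = float(cm[:, class_index].sum() - tp)
    fn = float(cm[class_index, :].sum() - tp)

    def safe(num: float, den: float, what: str) -> float:
        if den == 0.0:
            warnings.warn(
                f"{what} undefined for class {_TOKENS[class_index]!r} "
                "(zero denominator); returning 0",
                RuntimeWarning,
                stacklevel=3,
            )
            return 0.0
        return num / den

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    f1 = safe(2 * precision * recall, precision + recall, "F1")
    return precision, recall, f1


def accuracy(cm: np.ndarray) -> float:
    """Correct predictions over all predictions: trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix has no accuracy")
    return float(np.trace(cm)) / float(total)


def weighted_auc(true_labels: Sequence, probabilities: np.ndarray) -> float:
    """Support-weighted mean of one-vs-rest ROC AUCs.

    Each class present in the truth contributes its one-vs-rest AUC
    weighted by its support; classes absent from the truth are excluded
    with a warning (their AUC is undefined).
    """
    t = _as_ordinals(true_labels)
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.shape != (t.size, N_CLASSES):
        raise ValueError(f"expected probability matrix of shape ({t.size}, {N_CLASSES})")
    present, support = np.unique(t, return_counts=True)
    if present.size < 2:
        raise ValueError("AUC is undefined with fewer than two classes in the truth")
    absent = sorted(set(range(N_CLASSES)) - set(present.tolist()))
    if absent:
        warnings.warn(
            f"classes absent from truth excluded from weighted AUC: "
            f"{[_TOKENS[c] for c in absent]}",
            RuntimeWarning,
            stacklevel=2,
        )
    aucs = [roc_auc_score((t == c).astype(int), probs[:, c]) for c in present]
    return float(np.average(aucs, weights=support))


def sotd(cm: np.ndarray) -> int:
    """Sum of off-tridiagonal entries: counts with |true - predicted| >= 2.

    Zero means every error confuses adjacent slice levels only; the upper
    bound is the total count.
    """
    cm = np.asarray(cm)
    i, j = np.indices(cm.shape)
    return int(cm[np.abs(i - j) >= 2].sum())


def merge_to_three_class(cm: np.ndarray) -> tuple[np.ndarray, float]:
    """Collapse ap/mid/bs into one 'in' level and report the error rate.

    Returns the 3x3 matrix over (oap, in, obs) and ``1 - trace/total``.
    Confusions internal to the merged band vanish, so the merged error
    rate never exceeds the five-class one.
    """
    cm = np.asarray(cm)
    groups = [[0], [1, 2, 3], [4]]
    merged = np.zeros((3, 3), dtype=cm.dtype)
    for gi, rows in enumerate(groups):
        for gj, cols in enumerate(groups):
            merged[gi, gj] = cm[np.ix_(rows, cols)].sum()
    total = merged.sum()
    error_rate = 0.0 if total == 0 else 1.0 - float(np.trace(merged)) / float(total)
    return merged, error_rate


@dataclass
class EvalReport:
    """All test-set metrics for one model."""

    confusion: np.ndarray
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    f1: dict[str, float] = field(default_factory=dict)
    auc_weighted: float = float("nan")
    accuracy: float = float("nan")
    sotd: int = 0
    merged_confusion: np.ndarray | None = None
    merged_error_rate: float = float("nan")

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_weighted": self.auc_weighted,
            "accuracy": self.accuracy,
            "sotd": self.sotd,
            "merged_confusion": None if self.merged_confusion is None
            else self.merged_confusion.tolist(),
            "merged_error_rate": self.merged_error_rate,
            "total": self.total,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def format_table(self, name: str = "model") -> str:
        """Plain-text summary row set: per-class F1, weighted AUC, accuracy, SOTD."""
        lines = [f"== {name} (n={self.total} slices) =="]
        header = "  ".join(f"F1[{t}]" for t in _TOKENS)
        lines.append(f"{header}  AUC*   Acc    SOTD  err3")
        lines.append(
            "  ".join(f"{self.f1[t]:.3f} " for t in _TOKENS)
            + f" {self.auc_weighted:.3f}  {self.accuracy:.3f}  {self.sotd:4d}  "
            + f"{self.merged_error_rate:.3f}"
        )
        lines.append("confusion (rows true oap..obs, cols predicted):")
        for row in self.confusion:
            lines.append("  " + " ".join(f"{v:5d}" for v in row))
        return "\n".join(lines)


def evaluate(
    true_labels: Sequence,
    predicted_labels: Sequence,
    probabilities: np.ndarray | None = None,
) -> EvalReport:
    """Pool all valid test slices into one confusion matrix and score it."""
    cm = confusion_matrix(true_labels, predicted_labels)
    report = EvalReport(confusion=cm)
    for c in SliceLabel:
        p, r, f1 = one_vs_rest_scores(cm, int(c))
        report.precision[c.token] = p
        report.recall[c.token] = r
        report.f1[c.token] = f1
    report.accuracy = accuracy(cm)
    report.sotd = sotd(cm)
    report.merged_confusion, report.merged_error_rate = merge_to_three_class(cm)
    if probabilities is not None:
        report.auc_weighted = weighted_auc(true_labels, probabilities)
    return report
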