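"""Confusion matrix and macro-averaged multi-class metrics.

Reported metrics (all on the 0–100 percent scale):

* accuracy      — trace(CM) / total
* precision_k   — TP / (TP + FP)
* recall_k      — TP / (TP + FN)   (sensitivity)
* f1_k          — harmonic mean of precision_k and recall_k
* specificity_k — TN / (TN + FP)   (per-class true-negative rate)

Per-class quantities are macro-averaged: the unweighted mean over classes, so
rare classes count as much as common ones.  Undefined ratios (0/0, e.g. a
class never predicted and never present) score 0 and are logged.  A
frequency-weighted average is available behind ``average="weighted"``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "confusion", "metrics", "evaluate"]


@dataclass(frozen=True, eq=False)
class MetricsReport:
    accuracy: float
    f1: float
    precision: float
    recall: float
    specificity: float
    per_class: np.ndarray  # K rows x (precision, recall, f1, specificity), in %

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetricsReport):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "per_class": self.per_class.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __str__(self) -> str:
        return (
            f"accuracy {self.accuracy:.2f}%  f1 {self.f1:.2f}%  "
            f"precision {self.precision:.2f}%  recall {self.recall:.2f}%  "
            f"specificity {self.specificity:.2f}%"
        )


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K×K count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    undefined = den == 0
    if np.any(undefined):
        logger.warning("%s undefined (0/0) for classes %s; scoring 0",
                       what, np.flatnonzero(undefined).tolist())
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=~undefined)
    return out


def metrics(cm: np.ndarray, average: str = "macro") -> MetricsReport:
    """Five-way report from a confusion matrix, on the percent scale."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    specificity = _safe_div(tn, tn + fp, "specificity")
    if average == "macro":
        weights = np.full(cm.shape[0], 1.0 / cm.shape[0])
    elif average == "weighted":
        weights = cm.sum(axis=1) / total
    else:
        raise ValueError("average must be 'macro' or 'weighted'")
    per_class = np.column_stack([precision, recall, f1, specificity]) * 100.0
    return MetricsReport(
        accuracy=float(tp.sum() / total * 100.0),
        precision=float(precision @ weights * 100.0),
        recall=float(recall @ weights * 100.0),
        f1=float(f1 @ weights * 100.0),
        specificity=float(specificity @ weights * 100.0),
        per_class=per_class,
    )


def evaluate(classifier, test_set, average: str = "macro"):
    """Single deterministic pass over (image, label) pairs.

    ``classifier`` exposes ``predict(images) -> labels`` and ``n_classes``.
    Returns (confusion matrix, MetricsReport).
    """
    if not test_set:
        raise ValueError("test set is empty")
    images = [x for x, _ in test_set]
    y_true = [y for _, y in test_set]
    y_pred = classifier.predict(images)
    cm = confusion(y_true, y_pred, classifier.n_classes)
    return cm, metrics(cm, average=average)


def save_confusion_csv(cm: np.ndarray, path: str | Path,
                       class_names: list[str] | None = None) -> None:
    names = class_names or [f"class_{i}" for i in range(cm.shape[0])]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred", *names])
        for name, row in zip(names, np.asarray(cm)):
            writer.writerow([name, *row.tolist()])
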