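"""Evaluation outputs: confusion matrix, classification rate, one-vs-rest ROC.

The classification rate is the percentage of evaluated samples whose
predicted class matches the true class (the confusion-matrix trace over its
total); the misclassification rate is its complement.  ROC curves are
computed one-vs-rest per class by sweeping a threshold over the predicted
class probability, with equal scores grouped into a single threshold step;
AUC is the trapezoidal area, which equals the Mann-Whitney concordance
probability (ties counting one half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .types import CLASS_ORDER, ClassLabel

CLASS_VALUES = tuple(c.value for c in CLASS_ORDER)


def confusion_matrix(true_labels, predicted_labels, class_order=CLASS_VALUES) -> np.ndarray:
    """3x3 count matrix, rows = true class, cols = predicted class."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label arrays must have equal length")
    known = set(class_order)
    bad = (set(true_labels) | set(predicted_labels)) - known
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    if true_labels.size == 0:
        return np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    return _sk_confusion(true_labels, predicted_labels, labels=list(class_order)).astype(np.int64)


def classification_rate(cm: np.ndarray) -> float:
    """100 x trace / total, in percent."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("cannot compute a rate from an empty confusion matrix")
    return 100.0 * float(np.trace(cm)) / float(total)


def misclassification_rate(cm: np.ndarray) -> float:
    return 100.0 - classification_rate(cm)


@dataclass(frozen=True)
class ROCCurve:
    """One-vs-rest ROC points (from (0,0) to (1,1)) and trapezoidal AUC."""

    positive_class: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_one_vs_rest(
    scores: np.ndarray, true_labels, positive_class: str | ClassLabel,
    class_order=CLASS_VALUES,
) -> ROCCurve:
    """ROC for one class against the rest, from per-class probability rows.

    ``scores`` is (n, n_classes) in canonical class order (a 1-D array of
    positive-class scores is also accepted).
    """
    positive_class = ClassLabel(positive_class).value
    true_labels = np.asarray(true_labels)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 2:
        scores = scores[:, class_order.index(positive_class)]
    y = (true_labels == positive_class).astype(int)
    if y.sum() == 0:
        raise ValueError(f"positive class {positive_class!r} absent from the truth labels")
    if y.sum() == len(y):
        raise ValueError(f"no negative samples for class {positive_class!r}")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(positive_class=positive_class, fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class EvalReport:
    """Everything reported for one evaluated partition."""

    partition: str
    confusion: np.ndarray
    classification_rate: float
    misclassification_rate: float
    roc: dict[str, ROCCurve] = field(default_factory=dict)
    n_samples: int = 0
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "n_samples": int(self.n_samples),
            "class_order": list(CLASS_VALUES),
            "confusion": self.confusion.tolist(),
            "classification_rate": self.classification_rate,
            "misclassification_rate": self.misclassification_rate,
            "roc": {
                cls: {
                    "fpr": curve.fpr.tolist(),
                    "tpr": curve.tpr.tolist(),
                    "auc": curve.auc,
                }
                for cls, curve in self.roc.items()
            },
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def summary(self) -> str:
        lines = [
            f"partition: {self.partition} (n={self.n_samples})",
            f"classification rate: {self.classification_rate:.1f}%",
            f"misclassification rate: {self.misclassification_rate:.1f}%",
        ]
        for cls, curve in self.roc.items():
            lines.append(f"AUC[{cls}]: {curve.auc:.3f}")
        return "\n".join(lines)


def evaluate_predictions(
    true_labels, probs: np.ndarray, partition: str = "test",
    provenance: dict | None = None,
) -> EvalReport:
    """Build the full report from true labels and per-class probabilities."""
    true_labels = np.asarray(true_labels)
    probs = np.asarray(probs, dtype=float)
    predicted = np.array([CLASS_VALUES[k] for k in probs.argmax(axis=1)])
    cm = confusion_matrix(true_labels, predicted)
    roc = {}
    for cls in CLASS_VALUES:
        if cls in set(true_labels) and (true_labels != cls).any():
            roc[cls] = roc_one_vs_rest(probs, true_labels, cls)
    return EvalReport(
        partition=partition,
        confusion=cm,
        classification_rate=classification_rate(cm),
        misclassification_rate=misclassification_rate(cm),
        roc=roc,
        n_samples=len(true_labels),
        provenance=provenance or {},
    )
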