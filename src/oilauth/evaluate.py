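"""Model scoring: accuracy, confusion matrix, per-class metrics, adjacency.

Beyond the standard classification report, adulteration classes have a
natural metric structure — each class maps to an adulteration
percentage (pure CO = 0, the mixtures at 1..9, pure SO = 100) — so
misclassifications are further attributed to the *ratio distance*
between the true and the predicted class.  Confusing 97:3 with 95:5 is
a 2-point error; calling pure CO a 5 % mixture is a 5-point error.
Band boundaries at 2 and 4 percentage points follow the detection-limit
question the corpus is designed to answer: which adulteration
differences can the classifiers resolve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn import metrics as _skm

from .classify import TrainedClassifier, predict

#: Adjacency bands in percentage points of adulteration-ratio distance.
BANDS = ("<=2", "(2,4]", ">4")


@dataclass(frozen=True)
class ClassMetrics:
    precision: float  # NaN when no sample was predicted as this class
    recall: float     # NaN when the class has no true samples
    f1: float         # NaN when either component is undefined
    support: int


@dataclass(frozen=True)
class EvaluationReport:
    accuracy: float
    confusion: np.ndarray                 # K x K, rows true, cols predicted
    class_order: tuple[str, ...]
    per_class: dict[str, ClassMetrics]
    adjacency: Optional[dict[str, dict]] = None

    def to_dict(self) -> dict:
        def _clean(x: float):
            return None if (isinstance(x, float) and math.isnan(x)) else x

        return {
            "accuracy": self.accuracy,
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "per_class": {
                c: {
                    "precision": _clean(m.precision),
                    "recall": _clean(m.recall),
                    "f1": _clean(m.f1),
                    "support": m.support,
                }
                for c, m in self.per_class.items()
            },
            "adjacency": self.adjacency,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> np.ndarray:
    """K x K count matrix; entry (i, j) = true class i predicted as j."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    known = set(class_order)
    unknown = {l for l in (*true_labels, *predicted_labels) if l not in known}
    if unknown:
        raise ValueError(f"labels not in class_order: {sorted(unknown)}")
    if not true_labels:
        return np.zeros((len(class_order), len(class_order)), dtype=int)
    return _skm.confusion_matrix(
        true_labels, predicted_labels, labels=list(class_order)
    )


def classification_report(
    confusion: np.ndarray, class_order: Sequence[str]
) -> EvaluationReport:
    """Accuracy and per-class precision/recall/F1 from a count matrix.

    Zero-denominator metrics are reported as NaN (undefined), never
    coerced to 0, so macro summaries cannot be silently deflated.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any() or not np.issubdtype(cm.dtype, np.integer):
        raise ValueError("confusion matrix must hold non-negative integers")
    total = int(cm.sum())
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    col_sums = cm.sum(axis=0)
    row_sums = cm.sum(axis=1)
    per_class = {}
    for j, cls in enumerate(class_order):
        prec = cm[j, j] / col_sums[j] if col_sums[j] else float("nan")
        rec = cm[j, j] / row_sums[j] if row_sums[j] else float("nan")
        if math.isnan(prec) or math.isnan(rec) or (prec + rec) == 0:
            f1 = float("nan")
        else:
            f1 = 2 * prec * rec / (prec + rec)
        per_class[cls] = ClassMetrics(float(prec), float(rec), float(f1), int(row_sums[j]))
    return EvaluationReport(accuracy, cm, tuple(class_order), per_class)


def adjacency_analysis(
    confusion: np.ndarray,
    class_order: Sequence[str],
    class_ratio_percent: Mapping[str, float],
) -> dict[str, dict]:
    """Attribute off-diagonal mass to ratio-distance bands.

    Every class must map to an adulteration percentage; each
    misclassified count is assigned to the band containing
    ``|ratio(true) - ratio(pred)|``.  Returns counts and shares (of the
    off-diagonal total) per band.
    """
    cm = np.asarray(confusion)
    unmapped = [c for c in class_order if c not in class_ratio_percent]
    if unmapped:
        raise ValueError(f"classes without a ratio mapping: {unmapped}")
    counts = {b: 0 for b in BANDS}
    for i, ti in enumerate(class_order):
        for j, tj in enumerate(class_order):
            if i == j or cm[i, j] == 0:
                continue
            d = abs(class_ratio_percent[ti] - class_ratio_percent[tj])
            band = "<=2" if d <= 2 else "(2,4]" if d <= 4 else ">4"
            counts[band] += int(cm[i, j])
    off_total = sum(counts.values())
    return {
        band: {
            "count": counts[band],
            "share": counts[band] / off_total if off_total else 0.0,
        }
        for band in BANDS
    }


def evaluate_model(
    model: TrainedClassifier,
    X: np.ndarray,
    y_true: Sequence[str],
    class_ratio_percent: Optional[Mapping[str, float]] = None,
) -> EvaluationReport:
    """Predict and assemble the full report for a labeled feature matrix.

    Works for simulated test splits and for real-world-style mixture
    tables alike; classes absent from ``y_true`` simply have support 0
    (their recall is undefined and they contribute nothing to the
    accuracy denominator).
    """
    y_pred = predict(model, X)
    cm = confusion_matrix(list(y_true), list(y_pred), model.class_order)
    report = classification_report(cm, model.class_order)
    adjacency = None
    if class_ratio_percent is not None:
        adjacency = adjacency_analysis(cm, model.class_order, class_ratio_percent)
    return EvaluationReport(
        report.accuracy, cm, report.class_order, report.per_class, adjacency
    )


def plot_confusion(report: EvaluationReport, ax=None, **imshow_kw):
    """Render the confusion matrix as a heat map (presentation only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(report.confusion, **imshow_kw)
    ax.set_xticks(range(len(report.class_order)), report.class_order, rotation=45)
    ax.set_yticks(range(len(report.class_order)), report.class_order)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.figure.colorbar(im, ax=ax)
    return ax
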