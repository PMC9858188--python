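"""Classification metrics: accuracy/precision/recall/F1, ROC/AUC, PR/AP,
confusion matrices.

Undefined metrics (zero denominator) are reported as NaN with a warning,
never silently as 0.  Curve computations delegate to scikit-learn; AP uses
step interpolation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .errors import InvalidInputError


@dataclass
class ConfusionCounts:
    """Binary confusion counts (tp/fp/tn/fn)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_labels(cls, truth, pred) -> "ConfusionCounts":
        t = np.asarray(truth, bool)
        p = np.asarray(pred, bool)
        if t.shape != p.shape:
            raise InvalidInputError("label lists must have equal length")
        return cls(
            tp=int((t & p).sum()),
            fp=int((~t & p).sum()),
            tn=int((~t & ~p).sum()),
            fn=int((t & ~p).sum()),
        )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def binary_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1) from binary confusion counts.

    accuracy = (TP+TN)/(TP+FP+TN+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); f1 = harmonic mean of precision and recall.
    """
    acc = _safe_div(c.tp + c.tn, c.tp + c.fp + c.tn + c.fn, "accuracy")
    prec = _safe_div(c.tp, c.tp + c.fp, "precision")
    rec = _safe_div(c.tp, c.tp + c.fn, "recall")
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
        warnings.warn("f1 undefined; reporting NaN")
        f1 = float("nan")
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return acc, prec, rec, f1


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise InvalidInputError("both classes must be present")


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, auc): threshold sweep with tied scores grouped,
    area by the trapezoid rule."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    fpr, tpr, _ = skm.roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, float(skm.auc(fpr, tpr))


def pr_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """(precision, recall, ap) with step-interpolated average precision."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    precision, recall, _ = skm.precision_recall_curve(labels, scores)
    ap = float(skm.average_precision_score(labels, scores))
    return precision, recall, ap


def confusion_matrix(truth, pred, classes) -> pd.DataFrame:
    """K x K count matrix, rows = truth, columns = prediction."""
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise InvalidInputError("truth and prediction lengths differ")
    classes = list(classes)
    unknown = (set(truth) | set(pred)) - set(classes)
    if unknown:
        raise InvalidInputError(f"unknown class labels {sorted(map(str, unknown))}")
    m = skm.confusion_matrix(truth, pred, labels=classes)
    return pd.DataFrame(m, index=classes, columns=classes)


def overall_accuracy(matrix: pd.DataFrame) -> float:
    """trace / total of a confusion matrix."""
    total = int(matrix.values.sum())
    return _safe_div(float(np.trace(matrix.values)), total, "accuracy")


def write_curve_csv(path, xs, ys, names: tuple[str, str]) -> None:
    pd.DataFrame({names[0]: xs, names[1]: ys}).to_csv(Path(path), index=False)
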