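"""Classification metrics: per-class one-vs-rest precision/recall/F1.

P = TP / (TP + FP), R = TP / (TP + FN), F1 = 2PR / (P + R); the reported
single numbers are unweighted (macro) means over the K classes, and
accuracy is the confusion-matrix trace over the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "f1_score"]


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); zero when both rates vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class MetricsReport:
    confusion: np.ndarray
    accuracy: float
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int
    train_loss: float | None = None
    test_loss: float | None = None
    train_accuracy: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_f1": self.f1.tolist(),
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


def compute_metrics(y_true, y_pred, num_classes: int = 4) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("cannot compute metrics on empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.min() < 0 or y_true.max() >= num_classes \
            or y_pred.min() < 0 or y_pred.max() >= num_classes:
        raise ValueError(f"labels must be in [0, {num_classes})")
    confusion = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(confusion, (y_true, y_pred), 1)
    tp = np.diag(confusion).astype(np.float64)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    return MetricsReport(
        confusion=confusion,
        accuracy=float(tp.sum() / len(y_true)),
        tp=tp.astype(np.int64), fp=fp.astype(np.int64),
        fn=fn.astype(np.int64),
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        n=int(len(y_true)),
    )
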