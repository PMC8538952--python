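"""Pixel-level evaluation: confusion matrix, precision/recall/F1, mIoU.

Metrics are computed micro-style from a single confusion matrix
accumulated over all evaluated pixels (rows = truth, cols = prediction).
For a class i: TP = C[i,i], FP = column sum − TP, FN = row sum − TP, and

    precision = TP/(TP+FP)   recall = TP/(TP+FN)
    F1 = 2PR/(P+R)           IoU = TP/(TP+FP+FN)
    mIoU = mean over the k+1 classes of IoU

with the 0/0 → 0 convention for classes absent from both masks (an
ignore-empty mode averages IoU over non-empty classes instead).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_io import CLASS_NAMES, LabelMask

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "precision_recall_f1",
    "miou",
    "evaluate",
]

N_CLASSES = len(CLASS_NAMES)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray = field(default_factory=lambda: np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 3×3 with nonnegative counts")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp_fp_fn_tn(self, cls: int):
        tp = int(self.counts[cls, cls])
        fp = int(self.counts[:, cls].sum()) - tp
        fn = int(self.counts[cls, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else 0.0


def confusion(pred: LabelMask, truth: LabelMask) -> ConfusionMatrix:
    """counts[t][p] = number of pixels with truth t predicted p."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth dimensions differ")
    idx = truth.labels.reshape(-1) * N_CLASSES + pred.labels.reshape(-1)
    counts = np.bincount(idx, minlength=N_CLASSES * N_CLASSES).reshape(N_CLASSES, N_CLASSES)
    return ConfusionMatrix(counts)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def precision_recall_f1(cm: ConfusionMatrix, cls: int):
    tp, fp, fn, _ = cm.tp_fp_fn_tn(cls)
    p = _safe_div(tp, tp + fp)
    r = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * p * r, p + r)
    return p, r, f1


def miou(cm: ConfusionMatrix, ignore_empty: bool = False) -> float:
    ious, keep = [], []
    for cls in range(N_CLASSES):
        tp, fp, fn, _ = cm.tp_fp_fn_tn(cls)
        ious.append(_safe_div(tp, tp + fp + fn))
        keep.append(tp + fp + fn > 0)
    if ignore_empty:
        ious = [v for v, k in zip(ious, keep) if k]
        return float(np.mean(ious)) if ious else 0.0
    return float(np.mean(ious))


@dataclass
class MetricsReport:
    precision: tuple
    recall: tuple
    f1: tuple
    iou: tuple
    miou: float
    accuracy: float
    k: int = N_CLASSES - 1

    @property
    def lodging_f1(self) -> float:
        return self.f1[CLASS_NAMES.index("lodging")]

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.f1))

    def to_dict(self) -> dict:
        d = {}
        for i, name in enumerate(CLASS_NAMES):
            d[name] = {
                "precision": self.precision[i],
                "recall": self.recall[i],
                "f1": self.f1[i],
                "iou": self.iou[i],
            }
        d["miou"] = self.miou
        d["accuracy"] = self.accuracy
        d["macro_f1"] = self.macro_f1
        d["lodging_f1"] = self.lodging_f1
        return d


def evaluate(cm: ConfusionMatrix) -> MetricsReport:
    prf = [precision_recall_f1(cm, c) for c in range(N_CLASSES)]
    ious = []
    for c in range(N_CLASSES):
        tp, fp, fn, _ = cm.tp_fp_fn_tn(c)
        ious.append(_safe_div(tp, tp + fp + fn))
    return MetricsReport(
        precision=tuple(p for p, _, _ in prf),
        recall=tuple(r for _, r, _ in prf),
        f1=tuple(f for _, _, f in prf),
        iou=tuple(ious),
        miou=miou(cm),
        accuracy=cm.accuracy,
    )
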