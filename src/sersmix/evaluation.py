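"""Confusion matrices, classification metrics, and 1-D Grad-CAM attribution."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true categories, columns predictions."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the label list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]   # label -> {precision, recall, f1}
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def rounded(self, ndigits: int = 4) -> dict:
        """Report-style dict with values rounded only at print time."""
        return {
            "accuracy": round(self.accuracy, ndigits),
            "macro_precision": round(self.macro_precision, ndigits),
            "macro_recall": round(self.macro_recall, ndigits),
            "macro_f1": round(self.macro_f1, ndigits),
            "per_class": {
                lab: {k: round(v, ndigits) for k, v in vals.items()}
                for lab, vals in self.per_class.items()
            },
        }


def confusion(y_true: Sequence[str], y_pred: Sequence[str],
              labels: Sequence[str]) -> ConfusionMatrix:
    """Count matrix over the declared ordered category list."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("cannot build a confusion matrix from no samples")
    unknown = set(y_true) | set(y_pred)
    unknown -= set(labels)
    if unknown:
        raise ValueError(f"unknown category token(s) {sorted(unknown)}")
    counts = _sk_confusion_matrix(list(y_true), list(y_pred), labels=list(labels))
    return ConfusionMatrix(tuple(labels), counts)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F1.

    precision_c = diag/colsum, recall_c = diag/rowsum, F1 their harmonic
    mean; macro values are unweighted means over classes.  A zero denominator
    yields a 0 metric with a warning.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    diag = np.diag(counts).astype(float)
    colsum = counts.sum(axis=0).astype(float)
    rowsum = counts.sum(axis=1).astype(float)
    per_class: dict[str, dict[str, float]] = {}
    precs, recs, f1s = [], [], []
    for i, lab in enumerate(cm.labels):
        if colsum[i] == 0 or rowsum[i] == 0:
            warnings.warn(f"class {lab}: zero denominator, metric set to 0")
        prec = diag[i] / colsum[i] if colsum[i] > 0 else 0.0
        rec = diag[i] / rowsum[i] if rowsum[i] > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class[lab] = {"precision": prec, "recall": rec, "f1": f1}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return MetricsReport(
        accuracy=float(diag.sum() / total),
        per_class=per_class,
        macro_precision=float(np.mean(precs)),
        macro_recall=float(np.mean(recs)),
        macro_f1=float(np.mean(f1s)),
    )


def grad_cam(model, x: np.ndarray, target_class: int) -> np.ndarray:
    """1-D Grad-CAM attribution for one preprocessed spectrum.

    Gradients of the (margin-free) target-class cosine score are
    back-propagated to the final convolutional stage of the encoder; channel
    weights are the length-averaged gradients, the map is the ReLU of the
    weighted activation sum, linearly upsampled to the input length and
    max-normalised to [0, 1].
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    model.set_mode(train=False)
    a = model.feature_map(x)                       # (1, C, L')
    pooled = model.gap.forward(a)
    f = model.proj.forward(pooled)
    logits = model.cls_head.forward(f)             # inference logits, no margin
    if not (0 <= target_class < logits.shape[1]):
        raise ValueError("target_class out of range")
    dlogits = np.zeros_like(logits)
    dlogits[:, target_class] = 1.0
    df = model.cls_head.backward(dlogits)
    da = model.gap.backward(model.proj.backward(df))
    weights = da.mean(axis=2)                      # (1, C) channel importance
    cam = np.maximum(0.0, (weights[:, :, None] * a).sum(axis=1))[0]
    L = x.shape[1]
    if cam.size != L:
        pos = np.linspace(0, 1, cam.size)
        cam = np.interp(np.linspace(0, 1, L), pos, cam)
    peak = cam.max()
    if peak == 0:
        warnings.warn("Grad-CAM map is identically zero for this input/class")
        return cam
    return cam / peak
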