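"""Segmentation and four-class typing metrics.

Pixel-level segmentation quality is summarised by accuracy, precision,
recall and F1 over (TP, FP, FN, TN) counts with placenta as the positive
class. Typing quality over the four invasion grades is summarised from a
4x4 confusion matrix (rows = true type, cols = predicted type) by

* ``aacc_macro`` — the mean over classes of per-class one-vs-rest
  accuracy (TP_i + TN_i) / total,
* ``asen`` — macro sensitivity, mean of per-class recall TP_i/(TP_i+FN_i),
* ``aspe`` — macro specificity, mean of per-class TN_i/(FP_i+TN_i),
* ``overall_accuracy`` — trace / total.

Both accuracy notions are reported: on the reference confusion matrix the
published headline accuracy (0.877) equals trace/total, while the macro
one-vs-rest average of the same matrix is ~0.939; the two disagree in
general and neither is silently substituted for the other.

Reported metrics round to 3 decimals, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

N_CLASSES = 4


@dataclass(frozen=True)
class PixelCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def pixel_counts(pred_mask: np.ndarray, true_mask: np.ndarray) -> PixelCounts:
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {true.shape}")
    for arr, name in ((pred, "pred"), (true, "true")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    p = pred.astype(bool)
    t = true.astype(bool)
    return PixelCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()), tn=int((~p & ~t).sum()),
    )


def seg_metrics(pred_mask: np.ndarray, true_mask: np.ndarray) -> dict[str, float]:
    """Accuracy, precision, recall, F1 of a binary segmentation.

    Zero-denominator conventions: PRE = 0 when no positives are predicted,
    REC = 0 when no positives exist, F1 = 0 when PRE + REC = 0.
    """
    c = pixel_counts(pred_mask, true_mask)
    acc = (c.tp + c.tn) / c.total
    pre = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    rec = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return {"acc": acc, "pre": pre, "rec": rec, "f1": f1}


def confusion_matrix(true_labels, pred_labels) -> np.ndarray:
    """4x4 integer confusion matrix, C[i, j] = #(true == i, pred == j)."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label lists must have equal length")
    if t.size and (t.min() < 0 or t.max() >= N_CLASSES or p.min() < 0 or p.max() >= N_CLASSES):
        raise ValueError("labels must lie in {0,1,2,3}")
    c = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(c, (t, p), 1)
    return c


def per_class_counts(c: np.ndarray) -> list[PixelCounts]:
    """One-vs-rest (TP, FP, FN, TN) per class from a confusion matrix."""
    c = np.asarray(c)
    total = int(c.sum())
    out = []
    for i in range(N_CLASSES):
        tp = int(c[i, i])
        fn = int(c[i].sum()) - tp
        fp = int(c[:, i].sum()) - tp
        out.append(PixelCounts(tp=tp, fp=fp, fn=fn, tn=total - tp - fn - fp))
    return out


def typing_metrics(c: np.ndarray) -> dict[str, float]:
    """Macro accuracy/sensitivity/specificity plus overall accuracy.

    Classes absent from the data (empty row) are excluded from the
    sensitivity average; the divisor shrinks accordingly.
    """
    c = np.asarray(c)
    if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
        raise ValueError("expected a non-negative 4x4 confusion matrix")
    total = int(c.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    counts = per_class_counts(c)
    accs, sens, spes = [], [], []
    for k in counts:
        accs.append((k.tp + k.tn) / total)
        if k.tp + k.fn:
            sens.append(k.tp / (k.tp + k.fn))
        if k.fp + k.tn:
            spes.append(k.tn / (k.fp + k.tn))
    return {
        "aacc_macro": float(np.mean(accs)),
        "asen": float(np.mean(sens)),
        "aspe": float(np.mean(spes)),
        "overall_accuracy": np.trace(c) / total,
    }


def macro_auc(true_labels, prob_matrix) -> float:
    """One-vs-rest AUC averaged over classes present in the data.

    Classes with no positive or no negative cases are skipped (the AUC is
    undefined for them).
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(prob_matrix, dtype=float)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    aucs = []
    for i in range(N_CLASSES):
        pos = t == i
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos.astype(int), p[:, i]))
    if not aucs:
        raise ValueError("no class has both positives and negatives")
    return float(np.mean(aucs))


def round3(x: float) -> float:
    """Round to 3 decimals, half away from zero (presentation convention)."""
    return float(np.floor(abs(x) * 1000 + 0.5) / 1000 * np.sign(x))


def format_confusion(c: np.ndarray, class_names=None) -> str:
    """Aligned text table of a 4x4 confusion matrix."""
    names = class_names or ["no_invasion", "accreta", "increta", "percreta"]
    width = max(len(n) for n in names) + 2
    lines = [" " * width + "".join(f"{n:>{width}}" for n in names)]
    for i, row in enumerate(np.asarray(c)):
        lines.append(f"{names[i]:>{width}}" + "".join(f"{v:>{width}d}" for v in row))
    return "\n".join(lines)
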