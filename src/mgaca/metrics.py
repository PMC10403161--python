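"""Pixel-level evaluation metrics and training losses.

All ratio metrics are computed from micro-aggregated pixel confusion counts
over the evaluated set: accuracy, precision, recall, F1, intersection over
union (IoU) and the Dice coefficient score (DCS), with

    IoU = TP / (TP + FP + FN)        DCS = 2 TP / (2 TP + FP + FN)

so DCS = 2 IoU / (1 + IoU) identically. The Dice training loss is the soft
(probabilistic) complement 1 - (2 sum(t p) + eps) / (sum t + sum p + eps), and
the combined loss is mean binary cross-entropy plus Dice loss with unit
weights. Degenerate 0/0 ratios resolve to 1 for the overlap scores (empty
truth matched by empty prediction is a perfect match) and to 0 for
precision/recall.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DICE_EPS = 1e-6
BCE_CLIP = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = 0.5

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    iou: float
    dcs: float
    n_pixels: int

    def as_percent(self) -> dict:
        return {k: round(100.0 * getattr(self, k), 2)
                for k in ("accuracy", "iou", "dcs", "precision", "recall", "f1")}


def _stack(arrays):
    arrays = [np.asarray(a) for a in arrays] if isinstance(arrays, (list, tuple)) \
        else [np.asarray(arrays)]
    return arrays


def confusion_counts(truth, probs, threshold: float = 0.5) -> ConfusionCounts:
    """Micro-aggregated pixel confusion counts at the given threshold."""
    truths, preds = _stack(truth), _stack(probs)
    if len(truths) != len(preds):
        raise ValueError(f"{len(truths)} truth masks vs {len(preds)} predictions")
    tp = fp = fn = tn = 0
    for i, (t, p) in enumerate(zip(truths, preds)):
        t = np.asarray(t)
        p = np.asarray(p)
        if p.ndim == t.ndim + 1 and p.shape[-1] == 1:
            p = p[..., 0]
        if t.shape != p.shape:
            raise ValueError(f"pair {i}: truth {t.shape} vs prediction {p.shape}")
        tb = t > 0.5
        pb = p >= threshold
        tp += int(np.count_nonzero(tb & pb))
        fp += int(np.count_nonzero(~tb & pb))
        fn += int(np.count_nonzero(tb & ~pb))
        tn += int(np.count_nonzero(~tb & ~pb))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, threshold=threshold)


def _ratio(num, den, empty_value):
    return num / den if den else empty_value


def pixel_metrics(counts: ConfusionCounts) -> MetricReport:
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = _ratio(tp, tp + fp, 0.0)
    recall = _ratio(tp, tp + fn, 0.0)
    return MetricReport(
        accuracy=_ratio(tp + tn, counts.total, 1.0),
        precision=precision,
        recall=recall,
        f1=_ratio(2 * precision * recall, precision + recall, 0.0),
        iou=_ratio(tp, tp + fp + fn, 1.0),
        dcs=_ratio(2 * tp, 2 * tp + fp + fn, 1.0),
        n_pixels=counts.total,
    )


def _flatten_pair(truth, probs):
    truths, preds = _stack(truth), _stack(probs)
    ts, ps = [], []
    for t, p in zip(truths, preds):
        t = np.asarray(t, dtype=np.float64)
        p = np.asarray(p, dtype=np.float64)
        if p.ndim == t.ndim + 1 and p.shape[-1] == 1:
            p = p[..., 0]
        if t.shape != p.shape:
            raise ValueError(f"truth {t.shape} vs prediction {p.shape}")
        ts.append(t.ravel())
        ps.append(p.ravel())
    return np.concatenate(ts), np.concatenate(ps)


def dice_loss(truth, probs, eps: float = DICE_EPS) -> float:
    """Soft Dice loss on probabilities; 0 = perfect overlap, 1 = none."""
    t, p = _flatten_pair(truth, probs)
    inter = float((t * p).sum())
    return 1.0 - (2.0 * inter + eps) / (float(t.sum()) + float(p.sum()) + eps)


def bce_loss(truth, probs, clip: float = BCE_CLIP) -> float:
    """Mean binary cross-entropy with probability clipping before the logs."""
    t, p = _flatten_pair(truth, probs)
    p = np.clip(p, clip, 1.0 - clip)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def bce_dice_loss(truth, probs, eps: float = DICE_EPS,
                  clip: float = BCE_CLIP) -> float:
    """Unit-weight sum of mean BCE and soft Dice loss."""
    return bce_loss(truth, probs, clip=clip) + dice_loss(truth, probs, eps=eps)


def evaluate(truth, probs, threshold: float = 0.5) -> dict:
    """Full metric report plus losses, keyed like the published score tables."""
    report = pixel_metrics(confusion_counts(truth, probs, threshold))
    out = report.as_percent()
    out["bce_dice_loss"] = round(bce_dice_loss(truth, probs), 4)
    out["dice_loss"] = round(dice_loss(truth, probs), 4)
    out["n_pixels"] = report.n_pixels
    return out
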