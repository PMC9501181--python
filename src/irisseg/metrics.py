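"""Dice loss and segmentation evaluation statistics (MIOU, F1, NICE2).

For a binary prediction/ground-truth pair with pixel counts TP, FP, FN, TN:

    IoU   = TP / (TP + FP + FN)
    F1    = 2 TP / (2 TP + FP + FN)
    NICE2 = 1/2 * ( FN / (FN + TP) + FP / (FP + TN) )

MIOU is the per-image IoU averaged over the n evaluated images; F1 and
NICE2 are likewise computed per image and averaged (a pooled-pixel
aggregation is also available).  All three lie in [0, 1]; lower NICE2 is
better.  The training loss is the smoothed soft Dice

    L = 1 - (2 * sum(p * g) + eps) / (sum(p) + sum(g) + eps),  eps = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import DimensionError

__all__ = ["ConfusionCounts", "MetricsReport", "dice_loss",
           "confusion_counts", "segmentation_metrics"]

DICE_EPS = 1.0


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-image pixel confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def iou(self) -> float:
        denom = self.tp + self.fp + self.fn
        return self.tp / denom if denom else 1.0  # empty gt, empty prediction

    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 1.0

    def nice2(self) -> float:
        fn_rate = self.fn / (self.fn + self.tp) if (self.fn + self.tp) else 0.0
        fp_rate = self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0
        return 0.5 * (fn_rate + fp_rate)


@dataclass
class MetricsReport:
    """Aggregate segmentation quality over ``n`` images."""

    miou: float
    f1: float
    nice2: float
    n: int

    def to_dict(self) -> dict:
        return {"miou": self.miou, "f1": self.f1, "nice2": self.nice2,
                "n": self.n}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def dice_loss(pred_prob, gt) -> Tensor | float:
    """Smoothed soft Dice loss between probabilities and a binary mask.

    ``pred_prob`` may be an autodiff :class:`Tensor` (differentiable path,
    used for training) or a plain array; ``gt`` is a binary array of the
    same shape.
    """
    gt_arr = np.asarray(gt.data if isinstance(gt, Tensor) else gt)
    if isinstance(pred_prob, Tensor):
        if pred_prob.shape != gt_arr.shape:
            raise DimensionError(
                f"prediction shape {pred_prob.shape} != mask shape {gt_arr.shape}")
        g = Tensor(gt_arr.astype(pred_prob.dtype))
        inter = (pred_prob * g).sum()
        denom = pred_prob.sum() + g.sum()
        return 1.0 - (2.0 * inter + DICE_EPS) * ((denom + DICE_EPS) ** -1.0)
    p = np.asarray(pred_prob, dtype=np.float64)
    if p.shape != gt_arr.shape:
        raise DimensionError(
            f"prediction shape {p.shape} != mask shape {gt_arr.shape}")
    inter = float((p * gt_arr).sum())
    denom = float(p.sum() + gt_arr.sum())
    return 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Pixelwise confusion counts between two binary masks."""
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise DimensionError(f"mask shapes differ: {p.shape} vs {g.shape}")
    for name, m in (("pred", p), ("gt", g)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary (values {vals})")
    p = p.astype(bool)
    g = g.astype(bool)
    return ConfusionCounts(
        tp=int((p & g).sum()), fp=int((p & ~g).sum()),
        fn=int((~p & g).sum()), tn=int((~p & ~g).sum()))


def segmentation_metrics(counts_per_image, aggregate: str = "per_image"
                         ) -> MetricsReport:
    """Aggregate confusion counts into a :class:`MetricsReport`.

    ``aggregate='per_image'`` computes IoU/F1/NICE2 per image and averages;
    ``'pooled'`` sums the counts over all images first.
    """
    counts = list(counts_per_image)
    if not counts:
        raise ValueError("need at least one image")
    if aggregate == "per_image":
        return MetricsReport(
            miou=float(np.mean([c.iou() for c in counts])),
            f1=float(np.mean([c.f1() for c in counts])),
            nice2=float(np.mean([c.nice2() for c in counts])),
            n=len(counts))
    if aggregate == "pooled":
        pooled = ConfusionCounts(
            tp=sum(c.tp for c in counts), fp=sum(c.fp for c in counts),
            fn=sum(c.fn for c in counts), tn=sum(c.tn for c in counts))
        return MetricsReport(miou=pooled.iou(), f1=pooled.f1(),
                             nice2=pooled.nice2(), n=len(counts))
    raise ValueError(f"unknown aggregate mode: {aggregate!r}")
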