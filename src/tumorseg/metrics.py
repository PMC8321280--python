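"""Segmentation evaluation metrics between a predicted and a reference mask.

All metrics derive from the per-pixel confusion counts: TP tumor pixels
correctly detected, FP normal pixels called tumor, FN tumor pixels missed,
TN normal pixels correctly left out. Percent-valued metrics (Acc, Sn, Sp)
are stored as fractions in [0, 1] and rendered as percent only in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imgio import as_mask

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "extra_fraction",
    "overlap_fraction",
    "dice",
    "full_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """The eight-metric evaluation panel.

    acc
        Pixel accuracy, (TP+TN)/N.
    iou
        Intersection over union (Jaccard), TP/(TP+FP+FN).
    dss
        Dice similarity score, 2TP/(2TP+FP+FN); equals 2·iou/(1+iou).
    sn, sp
        Sensitivity TP/(TP+FN) and specificity TN/(TN+FP).
    ef
        Extra fraction FP/(TP+FN) — false detections normalized by
        reference size; lower is better, may exceed 1.
    of
        Overlap fraction TP/(TP+FN), numerically identical to sn.
    psnr
        Peak signal-to-noise ratio in dB between the masks encoded as
        0/255 images (MAXI=255); infinite for identical masks.
    """

    acc: float
    iou: float
    dss: float
    sn: float
    sp: float
    ef: float
    of: float
    psnr: float


def confusion(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN between two same-shape binary masks."""
    p, r = as_mask(pred), as_mask(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = int(np.count_nonzero(~p & ~r))
    return ConfusionCounts(tp, fp, fn, tn)


def extra_fraction(c: ConfusionCounts) -> float:
    """FP normalized by reference size, FP/(TP+FN); undefined on empty reference."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("extra fraction undefined for an empty reference mask")
    return c.fp / (c.tp + c.fn)


def overlap_fraction(c: ConfusionCounts) -> float:
    """TP/(TP+FN), identical in value to sensitivity; undefined on empty reference."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("overlap fraction undefined for an empty reference mask")
    return c.tp / (c.tp + c.fn)


def dice(c: ConfusionCounts) -> float:
    """Dice similarity 2TP/(2TP+FP+FN); two empty masks agree perfectly (1.0)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def _psnr(pred: np.ndarray, ref: np.ndarray) -> float:
    a = np.where(pred, 255.0, 0.0)
    b = np.where(ref, 255.0, 0.0)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / mse)


def full_report(pred: np.ndarray, ref: np.ndarray) -> MetricReport:
    """All eight metrics between a predicted and a reference mask.

    Ratios with a zero denominator (e.g. sensitivity against an empty
    reference) are reported as 0.0 so that degenerate candidates score
    worst rather than erroring out of a batch.
    """
    p, r = as_mask(pred), as_mask(ref)
    c = confusion(p, r)
    n = c.total

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    return MetricReport(
        acc=ratio(c.tp + c.tn, n),
        iou=ratio(c.tp, c.tp + c.fp + c.fn) if (c.tp + c.fp + c.fn) else 1.0,
        dss=dice(c),
        sn=ratio(c.tp, c.tp + c.fn),
        sp=ratio(c.tn, c.tn + c.fp),
        ef=ratio(c.fp, c.tp + c.fn),
        of=ratio(c.tp, c.tp + c.fn),
        psnr=_psnr(p, r),
    )
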