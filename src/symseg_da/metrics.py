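"""Segmentation metrics from pixel confusion counts.

PA   = (TP+TN)/(TP+FP+FN+TN)    pixel accuracy
DSC  = 2TP/(FP+2TP+FN)          Dice similarity coefficient
TPR  = TP/(TP+FN)               sensitivity
TNR  = TN/(TN+FP)               specificity

Conventions for degenerate images (documented, configurable):
empty ground truth and empty prediction -> DSC = TPR = 1; empty ground
truth with a nonempty prediction -> DSC = 0 and TPR undefined (excluded
from per-image means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "confusion_counts",
    "pixel_accuracy",
    "dice_coefficient",
    "tpr",
    "tnr",
    "binarize",
    "evaluate_pairs",
    "pair_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class SegMetrics:
    pa: float
    dsc: float
    tpr: float
    tnr: float
    n_images: int
    aggregation: str

    def __post_init__(self):
        for name in ("pa", "dsc", "tpr", "tnr"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.aggregation not in ("per_image_mean", "pooled"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} is not binary (values {vals[:8]}); binarize first")
    return a.astype(bool)


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a {0,1} mask."""
    return (np.asarray(probs) >= threshold).astype(np.uint8)


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    pred = _check_binary(pred_mask, "pred_mask")
    gt = _check_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return ConfusionCounts(tp, tn, fp, fn)


def pixel_accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("pixel_accuracy undefined for zero pixels")
    return (c.tp + c.tn) / c.total


def dice_coefficient(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    denom = c.fp + 2 * c.tp + c.fn
    if denom == 0:
        # no positives anywhere: empty GT matched by empty prediction
        return empty_value
    return 2 * c.tp / denom


def tpr(c: ConfusionCounts, empty_value: float = np.nan) -> float:
    if c.tp + c.fn == 0:
        return empty_value
    return c.tp / (c.tp + c.fn)


def tnr(c: ConfusionCounts, empty_value: float = np.nan) -> float:
    if c.tn + c.fp == 0:
        return empty_value
    return c.tn / (c.tn + c.fp)


def _metrics_from_counts(c: ConfusionCounts, n_images: int, aggregation: str) -> SegMetrics:
    return SegMetrics(
        pa=pixel_accuracy(c),
        dsc=dice_coefficient(c),
        tpr=tpr(c, empty_value=1.0),
        tnr=tnr(c, empty_value=1.0),
        n_images=n_images,
        aggregation=aggregation,
    )


def evaluate_pairs(preds: Sequence[np.ndarray], gts: Sequence[np.ndarray],
                   aggregation: str = "per_image_mean") -> SegMetrics:
    """Aggregate metrics over prediction/ground-truth mask pairs.

    ``per_image_mean`` averages per-image metrics (undefined per-image
    TPR/TNR values are excluded from their means); ``pooled`` sums the
    confusion counts first.
    """
    if len(preds) == 0:
        raise ValueError("evaluate_pairs needs at least one mask pair")
    if len(preds) != len(gts):
        raise ValueError(f"got {len(preds)} predictions but {len(gts)} ground truths")
    counts = [confusion_counts(p, g) for p, g in zip(preds, gts)]
    if aggregation == "pooled":
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        return _metrics_from_counts(total, len(counts), "pooled")
    if aggregation != "per_image_mean":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    pas = [pixel_accuracy(c) for c in counts]
    dscs = []
    for c in counts:
        if c.tp + c.fn == 0 and c.fp > 0:
            dscs.append(0.0)  # empty GT, nonempty prediction
        else:
            dscs.append(dice_coefficient(c))
    tprs = [tpr(c) for c in counts]
    tnrs = [tnr(c) for c in counts]
    tprs = [v for v in tprs if not np.isnan(v)]
    tnrs = [v for v in tnrs if not np.isnan(v)]
    return SegMetrics(
        pa=float(np.mean(pas)),
        dsc=float(np.mean(dscs)),
        tpr=float(np.mean(tprs)) if tprs else 1.0,
        tnr=float(np.mean(tnrs)) if tnrs else 1.0,
        n_images=len(counts),
        aggregation="per_image_mean",
    )


def pair_table(rows: List[dict]) -> pd.DataFrame:
    """Cross-domain result table: one row per (source, target) pair plus an
    Average row (mean of the pair rows)."""
    if not rows:
        raise ValueError("pair_table needs at least one row")
    df = pd.DataFrame(rows, columns=["source", "target", "pa", "dsc", "tpr", "tnr"])
    avg = df[["pa", "dsc", "tpr", "tnr"]].mean()
    avg_row = pd.DataFrame([{"source": "Average", "target": "", **avg.to_dict()}])
    return pd.concat([df, avg_row], ignore_index=True)
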