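"""Segmentation evaluation: per-class confusion counts, Dice similarity,
sensitivity / specificity / accuracy, normalized zone areas, and cross-sample
agreement (regression slope and Bland-Altman limits).

All metrics are one-vs-rest per class and computed over tissue pixels only;
the image background (no tissue) is never counted in any confusion cell, so
it cannot inflate specificity or accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import (LABEL_BACKGROUND, LABEL_CORE, LABEL_HEALTHY,
                           LABEL_NAMES, LABEL_RIM, LabelMap)

__all__ = [
    "ClassMetrics",
    "AreaSummary",
    "AgreementStats",
    "confusion",
    "dice",
    "metrics_table",
    "normalized_areas",
    "agreement",
]


@dataclass
class ClassMetrics:
    """One-vs-rest confusion counts and the derived metrics for one class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def dsc(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        if denom == 0:
            return 1.0  # both GT and A empty for this class
        return 2 * self.tp / denom

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else np.nan

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else np.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else np.nan


@dataclass
class AreaSummary:
    """Per-class area as a fraction of total tissue area."""

    fractions: dict[int, float]

    def __getitem__(self, label: int) -> float:
        return self.fractions[label]


@dataclass
class AgreementStats:
    """Through-origin regression slope plus Bland-Altman agreement stats."""

    slope: float
    bias: float
    loa_low: float
    loa_high: float
    n_outside: int


def _check_pair(gt: LabelMap, pred: LabelMap) -> np.ndarray:
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    if not np.array_equal(gt.mask, pred.mask):
        raise ValueError("ground truth and prediction have different masks")
    return gt.mask


def confusion(gt: LabelMap, pred: LabelMap, target_class: int) -> ClassMetrics:
    """One-vs-rest confusion counts for a class, over tissue pixels only."""
    mask = _check_pair(gt, pred)
    g = gt.labels[mask] == target_class
    a = pred.labels[mask] == target_class
    tp = int(np.sum(g & a))
    fp = int(np.sum(~g & a))
    fn = int(np.sum(g & ~a))
    tn = int(np.sum(~g & ~a))
    return ClassMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def dice(gt: LabelMap, pred: LabelMap, target_class: int) -> float:
    """Dice similarity coefficient 2|GT ∩ A| / (|GT| + |A|) for one class.

    1 when both sets are empty, 0 when exactly one is.
    """
    return confusion(gt, pred, target_class).dsc


def metrics_table(pairs, classes: tuple[int, ...] = (LABEL_CORE, LABEL_RIM),
                  with_summary: bool = True) -> pd.DataFrame:
    """Tidy per-sample, per-class metrics table (DSC, Sn, Sp, Acc).

    ``pairs`` is a (gt, pred) tuple or a list of such tuples (a batch of
    samples).  With a batch and ``with_summary``, mean and SD rows are
    appended per class.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], LabelMap):
        pairs = [pairs]
    rows = []
    for i, (gt, pred) in enumerate(pairs, start=1):
        for cls in classes:
            cm = confusion(gt, pred, cls)
            rows.append({
                "sample": str(i), "class": LABEL_NAMES[cls],
                "dsc": cm.dsc, "sensitivity": cm.sensitivity,
                "specificity": cm.specificity, "accuracy": cm.accuracy,
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
            })
    df = pd.DataFrame(rows)
    if with_summary and len(pairs) > 1:
        metric_cols = ["dsc", "sensitivity", "specificity", "accuracy"]
        for cls in classes:
            sub = df[df["class"] == LABEL_NAMES[cls]]
            for stat, fn in (("mean", np.mean), ("sd", lambda v: np.std(v, ddof=1))):
                row = {"sample": stat, "class": LABEL_NAMES[cls]}
                row.update({c: fn(sub[c].to_numpy()) for c in metric_cols})
                df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    return df


def normalized_areas(labels: LabelMap,
                     classes: tuple[int, ...] = (LABEL_CORE, LABEL_RIM,
                                                 LABEL_HEALTHY)) -> AreaSummary:
    """Per-class pixel count over total tissue pixel count."""
    total = int(labels.mask.sum())
    if total == 0:
        raise ValueError("no tissue pixels in label map")
    return AreaSummary(fractions={
        cls: float(np.sum(labels.labels == cls)) / total for cls in classes})


def agreement(gt_areas, pred_areas) -> AgreementStats:
    """Agreement of paired area fractions across samples.

    Slope is the least-squares regression of pred on gt through the origin
    (slope = sum(pred*gt) / sum(gt^2)); a perfect segmentation gives unity.
    Bland-Altman bias is mean(pred - gt) with limits at bias +/- 1.96 SD of
    the differences; ``n_outside`` counts points beyond the limits.
    """
    gt = np.asarray(gt_areas, dtype=float)
    pred = np.asarray(pred_areas, dtype=float)
    if gt.shape != pred.shape:
        raise ValueError("area lists must have equal length")
    if gt.size < 2:
        raise ValueError("need at least 2 paired samples")
    denom = float(np.sum(gt**2))
    if denom == 0:
        raise ValueError("ground-truth areas are all zero")
    slope = float(np.sum(pred * gt) / denom)
    diff = pred - gt
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    n_outside = int(np.sum((diff < loa_low) | (diff > loa_high)))
    return AgreementStats(slope=slope, bias=bias, loa_low=loa_low,
                          loa_high=loa_high, n_outside=n_outside)
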