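"""Dice loss and segmentation evaluation metrics.

The training objective is the soft dice loss

    loss = 1 - (2 * sum(g * s) + smooth) / (sum(g) + sum(s) + smooth)

with the sums running over every pixel of every item in the batch, ``g`` the
binary ground truth and ``s`` the predicted foreground probability.  The
``smooth`` term (default 1.0 during training) guards against 0/0 on empty
masks; with ``smooth=0`` and a binary prediction, ``1 - loss`` is exactly
the dice similarity coefficient.

Evaluation reports six pixel-classification metrics per image — DSC, IoU,
accuracy, recall, precision, specificity — plus their mean, sample (n-1)
standard deviation, and boxplot five-number summaries with the 1.5 x IQR
outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Tensor

__all__ = ["dice_loss", "confusion", "compute_metrics", "aggregate",
           "ConfusionCounts", "MetricsReport", "METRIC_NAMES"]

METRIC_NAMES = ("dsc", "iou", "accuracy", "recall", "precision", "specificity")


def dice_loss(pred, target, smooth: float = 1.0):
    """Soft dice loss; differentiable when ``pred`` is an autodiff Tensor.

    ``pred`` holds foreground probabilities in [0,1]; ``target`` is binary.
    Returns a scalar Tensor for Tensor input, a float otherwise.
    """
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    is_tensor = isinstance(pred, Tensor)
    t = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=np.float64)
    p_shape = pred.shape if is_tensor else np.asarray(pred).shape
    if tuple(p_shape) != t.shape:
        raise ValueError(f"prediction shape {tuple(p_shape)} != target shape {t.shape}")
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("target must be binary")
    if is_tensor:
        inter = (pred * t).sum()
        denom = pred.sum() + float(t.sum())
        return 1.0 - (2.0 * inter + smooth) * ((denom + smooth) ** -1.0)
    p = np.asarray(pred, dtype=np.float64)
    return float(1.0 - (2.0 * (p * t).sum() + smooth) / (p.sum() + t.sum() + smooth))


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise confusion counts for one image."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask, target_mask) -> ConfusionCounts:
    """Standard pixel-wise confusion counts of two binary masks."""
    p = np.asarray(pred_mask)
    t = np.asarray(target_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    for name, a in (("pred_mask", p), ("target_mask", t)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()), tn=int((~p & ~t).sum()))


def _ratio(num: int, den: int, target_empty: bool) -> float:
    # 0/0: perfect agreement on an empty class scores 1, a miss scores 0
    if den == 0:
        return 1.0 if target_empty else 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The six segmentation metrics from confusion counts.

    DSC and IoU satisfy DSC = 2*IoU / (1 + IoU) identically.
    """
    target_empty = (c.tp + c.fn) == 0
    pred_empty = (c.tp + c.fp) == 0
    return {
        "dsc": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, target_empty and pred_empty),
        "iou": _ratio(c.tp, c.tp + c.fp + c.fn, target_empty and pred_empty),
        "accuracy": _ratio(c.tp + c.tn, c.total, False),
        "recall": _ratio(c.tp, c.tp + c.fn, target_empty and pred_empty),
        "precision": _ratio(c.tp, c.tp + c.fp, target_empty),
        "specificity": _ratio(c.tn, c.tn + c.fp, (c.tn + c.fp) == 0),
    }


@dataclass
class MetricsReport:
    """Per-image metrics with mean +/- SD and boxplot summaries."""

    per_image: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    boxplot: dict[str, dict]

    def summary(self) -> str:
        lines = ["metric        mean      sd"]
        for m in METRIC_NAMES:
            lines.append(f"{m:<12}{self.mean[m]:>8.4f}{self.sd[m]:>8.4f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        table = self.per_image.copy()
        table.loc["mean"] = self.mean
        table.loc["sd"] = self.sd
        table.to_csv(path)

    def to_dict(self) -> dict:
        return {
            "per_image": self.per_image.to_dict(orient="list"),
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "boxplot": self.boxplot,
        }


def five_number(values: np.ndarray) -> dict:
    """min, Q1, median, Q3, max plus 1.5 x IQR outliers."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    return {"min": float(values.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(values.max()),
            "outliers": [float(v) for v in outliers]}


def aggregate(records: list[dict[str, float]], ids=None) -> MetricsReport:
    """Aggregate per-image metric records into a report (mean, sample SD,
    five-number boxplot summaries)."""
    if not records:
        raise ValueError("records must be non-empty")
    table = pd.DataFrame(records, columns=list(METRIC_NAMES))
    if ids is not None:
        table.index = list(ids)
    mean = table.mean()
    sd = table.std(ddof=1).fillna(0.0) if len(table) > 1 else pd.Series(0.0, index=table.columns)
    box = {m: five_number(table[m].to_numpy()) for m in METRIC_NAMES}
    return MetricsReport(per_image=table, mean=mean, sd=sd, boxplot=box)
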