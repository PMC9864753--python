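"""Model / Results interface over the segmentation pipeline.

``LVSegmentationModel`` holds the data and architecture choice;
``fit()`` runs the training loop and returns a ``SegmentationFit`` carrying
the trained network, the per-epoch history, and evaluation helpers, with a
``summary()`` table in the mean +/- SD style used for segmentation studies.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .metrics import METRIC_NAMES, MetricsReport
from .network import ArchConfig, BilateralSegNet, DESK_ARCH, PAPER_ARCH
from .phantom import EchoSample
from .training import (TrainConfig, TrainRecord, default_config, desk_config,
                       evaluate, load_checkpoint, train)

__all__ = ["LVSegmentationModel", "SegmentationFit"]

_ARCH_PRESETS = {"desk": DESK_ARCH, "paper": PAPER_ARCH}
_CFG_PRESETS = {"desk": desk_config, "paper": default_config}


class LVSegmentationModel:
    """A left-ventricle segmenter to be fitted to image/mask pairs.

    Parameters
    ----------
    train_samples, val_samples : lists of :class:`EchoSample`.
    arch : an :class:`ArchConfig`, or a preset name ("desk" or "paper").
    seed : initializes the network weights.
    """

    def __init__(self, train_samples: list[EchoSample],
                 val_samples: list[EchoSample] | None = None,
                 arch: ArchConfig | str = "desk", seed: int = 0):
        if isinstance(arch, str):
            try:
                arch = _ARCH_PRESETS[arch]
            except KeyError:
                raise ValueError(f"unknown preset {arch!r}; use 'desk' or 'paper'")
        self.train_samples = list(train_samples)
        self.val_samples = list(val_samples) if val_samples else []
        self.arch = arch
        self.seed = seed
        self.net = BilateralSegNet(arch, seed=seed)

    def fit(self, cfg: TrainConfig | None = None, max_steps: int | None = None,
            checkpoint_path: str | Path | None = None, **overrides) -> "SegmentationFit":
        """Train with SGD + momentum on dice loss and return the results."""
        if cfg is None:
            preset = "desk" if self.arch.backbone_depth == "tiny" else "paper"
            cfg = _CFG_PRESETS[preset](seed=self.seed)
        if overrides:
            cfg = cfg.replace(**overrides)
        record = train(self.net, self.train_samples, self.val_samples, cfg,
                       checkpoint_path=checkpoint_path, max_steps=max_steps)
        return SegmentationFit(self.net, record, cfg)


class SegmentationFit:
    """Results of a fitted segmentation model."""

    def __init__(self, net: BilateralSegNet, record: TrainRecord, cfg: TrainConfig):
        self.net = net
        self.record = record
        self.cfg = cfg

    @classmethod
    def from_checkpoint(cls, path, cfg: TrainConfig | None = None) -> "SegmentationFit":
        return cls(load_checkpoint(path), TrainRecord(), cfg or default_config())

    def predict(self, image: np.ndarray, threshold: float | None = None):
        return self.net.predict(image, threshold or self.cfg.threshold)

    def evaluate(self, samples: list[EchoSample],
                 threshold: float | None = None, ids=None) -> MetricsReport:
        return evaluate(self.net, samples, threshold or self.cfg.threshold, ids=ids)

    def summary(self, eval_report: MetricsReport | None = None) -> str:
        """Human-readable fit summary (training history and, optionally,
        a six-metric evaluation table)."""
        r = self.record
        lines = ["Left-ventricle segmentation fit",
                 "=" * 34,
                 f"optimizer steps      {r.steps}",
                 f"epochs completed     {len(r.train_loss)}",
                 f"final train loss     {r.train_loss[-1]:.4f}" if r.train_loss else
                 "final train loss     n/a",
                 f"best epoch           {r.best_epoch + 1}"]
        if r.val_dsc:
            lines.append(f"best validation DSC  {max(r.val_dsc):.4f}")
        if eval_report is not None:
            lines.append("")
            lines.append("evaluation (mean +/- SD over images)")
            for m in METRIC_NAMES:
                lines.append(f"  {m:<12}{eval_report.mean[m]:.4f} +/- {eval_report.sd[m]:.4f}")
        return "\n".join(lines)
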