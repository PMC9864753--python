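"""Training loop (SGD + momentum on dice loss) and end-to-end evaluation.

Defaults follow the full-scale training recipe: stochastic gradient
descent with momentum 0.9, initial learning rate 1e-4, weight decay 0.001,
50 epochs, batch size 32, reshuffle every epoch, 512 x 512 inputs.  The
model with the best validation DSC across epochs is kept.  A desk-scale
profile (small backbone, 128 px images, batch 4, a larger learning rate)
covers CPU-bound work; it shares every line of code with the full profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .metrics import aggregate, compute_metrics, confusion, dice_loss
from .network import ArchConfig, BilateralSegNet, DESK_ARCH, PAPER_ARCH
from .nn import SGD, Tensor
from .phantom import EchoSample, read_manifest
from .dataio import load_sample

__all__ = ["TrainConfig", "TrainRecord", "default_config", "desk_config",
           "train", "evaluate", "save_checkpoint", "load_checkpoint",
           "samples_from_manifest", "TrainingError"]


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults: the full-scale recipe)."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    shuffle_each_epoch: bool = True
    seed: int = 0
    image_size: int = 512
    device: str = "cpu"
    loss_smooth: float = 1.0
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.device != "cpu":
            raise ValueError("only device='cpu' is supported")

    def replace(self, **overrides) -> "TrainConfig":
        return replace(self, **overrides)


def default_config(**overrides) -> TrainConfig:
    """The full-scale training configuration; keyword overrides allowed."""
    return TrainConfig().replace(**overrides)


def desk_config(**overrides) -> TrainConfig:
    """CPU-scale profile: 128 px images, batch 4, a learning rate sized for
    the small network (the full-scale rate of 1e-4 barely moves it in the
    few hundred steps a desk run takes)."""
    base = TrainConfig(learning_rate=0.05, weight_decay=1e-4, epochs=50,
                       batch_size=4, image_size=128)
    return base.replace(**overrides)


@dataclass
class TrainRecord:
    """Per-epoch history plus the best-validation checkpoint."""

    train_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    checkpoint_path: str | None = None
    steps: int = 0


def _as_batch(samples: list[EchoSample], idx) -> tuple[Tensor, np.ndarray]:
    # pad to the P7 stride (128) exactly as inference does; padded mask
    # pixels are background, so the loss target stays consistent
    from .backbone import pad_to_multiple
    images = np.stack([pad_to_multiple(samples[i].image, 128)[0] for i in idx])[:, None]
    masks = np.stack([pad_to_multiple(samples[i].mask, 128)[0]
                      for i in idx])[:, None].astype(np.float64)
    return Tensor(images), masks


def _mean_val_dsc(net: BilateralSegNet, samples: list[EchoSample], threshold: float) -> float:
    scores = []
    for s in samples:
        out = net.predict(s.image, threshold)
        scores.append(compute_metrics(confusion(out.binary_mask, s.mask))["dsc"])
    return float(np.mean(scores)) if scores else float("nan")


def train(net: BilateralSegNet, train_samples: list[EchoSample],
          val_samples: list[EchoSample] | None, cfg: TrainConfig,
          checkpoint_path: str | Path | None = None,
          max_steps: int | None = None) -> TrainRecord:
    """Optimize ``net`` with SGD+momentum on dice loss.

    Shuffling is reseeded deterministically from ``cfg.seed`` each epoch;
    the epoch with the highest validation DSC (train loss when there is no
    validation set) defines the returned best checkpoint.
    """
    if not train_samples:
        raise ValueError("training split must be non-empty")
    val_samples = val_samples or []
    opt = SGD(net.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    record = TrainRecord()
    n = len(train_samples)
    best_score = -math.inf
    best_state = None
    net.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            if max_steps is not None and record.steps >= max_steps:
                break
            idx = order[start:start + cfg.batch_size]
            x, target = _as_batch(train_samples, idx)
            prob = net(x)
            loss = dice_loss(prob, target, smooth=cfg.loss_smooth)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch + 1}")
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            record.steps += 1
        if not losses:
            break
        record.train_loss.append(float(np.mean(losses)))
        if val_samples:
            vdsc = _mean_val_dsc(net, val_samples, cfg.threshold)
            net.train()
            record.val_dsc.append(vdsc)
            score = vdsc
        else:
            score = -record.train_loss[-1]
        if score > best_score:
            best_score = score
            best_epoch_state = net.state_dict()
            best_state = best_epoch_state
            record.best_epoch = epoch
        if max_steps is not None and record.steps >= max_steps:
            break
    if best_state is not None:
        net.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(net, checkpoint_path)
        record.checkpoint_path = str(checkpoint_path)
    return record


def evaluate(net: BilateralSegNet, samples: list[EchoSample],
             threshold: float = 0.5, ids=None):
    """Segment every sample, score it with the six metrics, aggregate."""
    if not samples:
        raise ValueError("evaluation set must be non-empty")
    records = []
    for s in samples:
        out = net.predict(s.image, threshold)
        records.append(compute_metrics(confusion(out.binary_mask, s.mask)))
    return aggregate(records, ids=ids)


# ----------------------------------------------------------- checkpointing


def save_checkpoint(net: BilateralSegNet, path: str | Path) -> None:
    path = Path(path)
    state = net.state_dict()
    state["__arch__"] = np.frombuffer(
        json.dumps(net.arch.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> BilateralSegNet:
    p = Path(path)
    if not p.exists():  # np.savez appends .npz
        p = Path(f"{path}.npz")
    with np.load(p) as data:
        arch = ArchConfig(**json.loads(bytes(data["__arch__"]).decode()))
        net = BilateralSegNet(arch)
        net.load_state_dict({k: data[k] for k in data.files if k != "__arch__"})
    return net


def samples_from_manifest(manifest: str | Path, ids=None,
                          target_size: int | None = None) -> list[EchoSample]:
    """Load (a subset of) a generated corpus; ``ids`` are manifest row
    indices.  Missing files raise an I/O error naming the offending ids."""
    pairs = read_manifest(manifest)
    if ids is None:
        ids = range(len(pairs))
    missing = [i for i in ids if i >= len(pairs) or not pairs[i][0].exists()
               or not pairs[i][1].exists()]
    if missing:
        raise IOError(f"missing image/mask files for ids: {missing}")
    return [load_sample(pairs[i][0], pairs[i][1], target_size) for i in ids]
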