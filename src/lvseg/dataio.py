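"""Reading, writing, resizing and splitting image/mask corpora.

Conventions (fixed once, used everywhere): row-major arrays, origin at the
top-left, pixel-centre sampling for resizes.  Images resize bilinearly and
are scaled to [0, 1]; masks resize with nearest-neighbour and are
re-binarized by thresholding at 127 (8-bit) so they stay strictly {0, 1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import EchoSample, save_png

__all__ = ["DatasetSplit", "load_sample", "save_sample", "split_dataset",
           "write_split", "read_split"]


class FormatError(ValueError):
    """Raised when an image/mask pair violates the format contract."""


def _round_half_down(x: float) -> int:
    # nearest integer, ties toward zero: test/val never gain from a tie
    return int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class DatasetSplit:
    """A disjoint train/test/validation partition of sample ids.

    Test and validation sizes are the fractions rounded to the nearest
    integer (ties down); every remaining id goes to train.
    """

    train: tuple
    test: tuple
    validation: tuple
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        all_ids = list(self.train) + list(self.test) + list(self.validation)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split parts must be disjoint")


def split_dataset(ids, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> DatasetSplit:
    """Deterministic seeded shuffle + partition of ``ids``.

    With 6,000 ids and fractions (0.70, 0.15, 0.15) this yields
    4,200 / 900 / 900 train / test / validation samples.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(ids)
    n_test = _round_half_down(fractions[1] * n)
    n_val = _round_half_down(fractions[2] * n)
    if n_test + n_val > n:
        raise ValueError("test + validation fractions leave no training data")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    test = tuple(shuffled[:n_test])
    validation = tuple(shuffled[n_test:n_test + n_val])
    train = tuple(shuffled[n_test + n_val:])
    return DatasetSplit(train=train, test=test, validation=validation,
                        fractions=tuple(fractions), seed=seed)


def load_sample(image_path, mask_path, target_size: int | None = None) -> EchoSample:
    """Load an image/mask pair, scale the image to [0,1], binarize the mask,
    and (optionally) resize both to ``target_size`` x ``target_size``."""
    img = Image.open(image_path).convert("L")
    msk = Image.open(mask_path).convert("L")
    if img.size != msk.size:
        raise FormatError(
            f"image {img.size} and mask {msk.size} differ in size before resize")
    mask_raw = np.asarray(msk)
    if len(np.unique(mask_raw)) > 2:
        raise FormatError(f"mask {mask_path} is not two-valued")
    binary = mask_raw > 127
    if target_size is not None and img.size != (target_size, target_size):
        img = img.resize((target_size, target_size), Image.BILINEAR)
        msk = Image.fromarray(binary.astype(np.uint8) * 255).resize(
            (target_size, target_size), Image.NEAREST)
        binary = np.asarray(msk) > 127
    image = np.asarray(img, dtype=np.float64) / 255.0
    return EchoSample(image=image, mask=binary.astype(np.uint8),
                      meta={"image_path": str(image_path), "mask_path": str(mask_path)})


def save_sample(sample: EchoSample, image_path, mask_path) -> None:
    save_png(Path(image_path), sample.image, binary=False)
    save_png(Path(mask_path), sample.mask, binary=True)


def write_split(split: DatasetSplit, path) -> None:
    """Three-section plain-text split file."""
    with open(path, "w") as fh:
        fh.write(f"# fractions {split.fractions[0]} {split.fractions[1]} "
                 f"{split.fractions[2]} seed {split.seed}\n")
        for section in ("train", "test", "validation"):
            fh.write(f"[{section}]\n")
            for sid in getattr(split, section):
                fh.write(f"{sid}\n")


def read_split(path) -> DatasetSplit:
    sections = {"train": [], "test": [], "validation": []}
    fractions, seed = (0.70, 0.15, 0.15), 0
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                fractions = tuple(float(x) for x in parts[2:5])
                seed = int(parts[6])
            elif line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
            elif current is not None:
                sections[current].append(line)
    return DatasetSplit(train=tuple(sections["train"]), test=tuple(sections["test"]),
                        validation=tuple(sections["validation"]),
                        fractions=fractions, seed=seed)
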