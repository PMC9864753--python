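"""Residual backbone, feature pyramid, and the two merged feature streams.

The backbone is a residual network producing activations C1..C5 at strides
2..32.  A top-down feature pyramid turns C2..C5 into uniform-channel levels
P2..P5 (strides 4..32); two extra levels P6 and P7 (strides 64, 128) come
from stride-2 convolutions.  P2..P5 are then merged (upsample to the finest
grid + element-wise sum) into the *low-level* stream at stride 4, and
P5..P7 into the *high-level* stream at stride 32; those two streams feed
the spatial and channel attention units respectively.

Two presets exist: a ResNet-50-like bottleneck backbone (the full-scale
configuration) and a small basic-block variant ("tiny", one block per
stage) whose arithmetic is identical but which trains in seconds on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor, concat, upsample_nearest

__all__ = ["FeatureMap", "PyramidFeatures", "BilevelFeatures",
           "ResidualBackbone", "FeaturePyramid", "merge_levels",
           "pad_to_multiple", "PYRAMID_STRIDES"]

PYRAMID_STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32, "P6": 64, "P7": 128}


@dataclass
class FeatureMap:
    """An activation grid with its downsampling factor relative to the input."""

    values: Tensor  # (N, C, H, W)
    stride: int

    @property
    def channels(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, array: np.ndarray, stride: int) -> "FeatureMap":
        """Wrap an H x W x C numpy array as a single-item feature map."""
        return cls(Tensor(np.moveaxis(np.asarray(array, dtype=np.float64), -1, 0)[None]),
                   stride)

    def to_array(self) -> np.ndarray:
        """First batch item as H x W x C."""
        return np.moveaxis(self.values.data[0], 0, -1)


@dataclass
class PyramidFeatures:
    """Uniform-channel levels P2..P7 at strides 4..128."""

    levels: dict[str, FeatureMap]

    def __post_init__(self):
        if set(self.levels) != set(PYRAMID_STRIDES):
            raise ValueError(f"pyramid must contain exactly {sorted(PYRAMID_STRIDES)}")
        widths = {fm.channels for fm in self.levels.values()}
        if len(widths) != 1:
            raise ValueError(f"pyramid levels disagree on channel count: {widths}")
        for name, fm in self.levels.items():
            if fm.stride != PYRAMID_STRIDES[name]:
                raise ValueError(f"{name} has stride {fm.stride}, expected {PYRAMID_STRIDES[name]}")

    def __getitem__(self, name: str) -> FeatureMap:
        return self.levels[name]


@dataclass
class BilevelFeatures:
    """The merged low-level (stride 4) and high-level (stride 32) streams."""

    low: FeatureMap
    high: FeatureMap

    def __post_init__(self):
        if self.low.stride != 4:
            raise ValueError(f"low stream must be stride 4, got {self.low.stride}")
        if self.high.stride != 32:
            raise ValueError(f"high stream must be stride 32, got {self.high.stride}")


def pad_to_multiple(image: np.ndarray, multiple: int = 128):
    """Symmetric zero-pad so both sides divide ``multiple``.

    Returns (padded, (top, left, height, width)) so predictions can be
    cropped back to the original frame.
    """
    h, w = image.shape[:2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    top, left = ph // 2, pw // 2
    padded = np.pad(image, ((top, ph - top), (left, pw - left)))
    return padded, (top, left, h, w)


class _BasicBlock(Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.downsample = None
        if stride != 1 or cin != cout:
            self.downsample = Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.bn_down = BatchNorm2d(cout)

    def forward(self, x):
        identity = x if self.downsample is None else self.bn_down(self.downsample(x))
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + identity).relu()


class _Bottleneck(Module):
    def __init__(self, cin, cmid, cout, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(cin, cmid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cmid)
        self.conv2 = Conv2d(cmid, cmid, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cmid)
        self.conv3 = Conv2d(cmid, cout, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(cout)
        self.downsample = None
        if stride != 1 or cin != cout:
            self.downsample = Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.bn_down = BatchNorm2d(cout)

    def forward(self, x):
        identity = x if self.downsample is None else self.bn_down(self.downsample(x))
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + identity).relu()


class ResidualBackbone(Module):
    """Residual feature extractor emitting C1..C5 at strides 2..32.

    ``depth="resnet50"`` uses bottleneck stages (3,4,6,3) with the classic
    widths scaled by ``width_mult``; ``depth="tiny"`` uses one basic block
    per stage.  Stage C2 downsamples with a stride-2 convolution in its
    first block (in place of the classical max-pool).
    """

    def __init__(self, depth: str = "tiny", base_width: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = base_width
        self.depth = depth
        if depth == "tiny":
            self.stem = Conv2d(1, w, 3, stride=2, padding=1, bias=False, rng=rng)
            self.stem_bn = BatchNorm2d(w)
            widths = [w, 2 * w, 4 * w, 8 * w]
            cin = w
            self.stages = []
            for cout in widths:
                self.stages.append([_BasicBlock(cin, cout, stride=2, rng=rng)])
                cin = cout
            self.channels = {"C1": w, "C2": widths[0], "C3": widths[1],
                             "C4": widths[2], "C5": widths[3]}
        elif depth == "resnet50":
            self.stem = Conv2d(1, w, 7, stride=2, padding=3, bias=False, rng=rng)
            self.stem_bn = BatchNorm2d(w)
            counts = (3, 4, 6, 3)
            self.stages = []
            cin = w
            outs = []
            for i, n_blocks in enumerate(counts):
                cmid = w * 2 ** i
                cout = 4 * cmid
                blocks = [_Bottleneck(cin, cmid, cout, stride=2, rng=rng)]
                blocks += [_Bottleneck(cout, cmid, cout, stride=1, rng=rng)
                           for _ in range(n_blocks - 1)]
                self.stages.append(blocks)
                cin = cout
                outs.append(cout)
            self.channels = {"C1": w, "C2": outs[0], "C3": outs[1],
                             "C4": outs[2], "C5": outs[3]}
        else:
            raise ValueError(f"unknown backbone depth: {depth!r}")
        # flatten stage blocks so Module traversal sees them
        self._blocks = [b for stage in self.stages for b in stage]

    def forward(self, x: Tensor) -> dict[str, FeatureMap]:
        """x: (N, 1, H, W) with H, W multiples of 32 at least."""
        if x.shape[1] != 1:
            raise ValueError(f"backbone expects grayscale input, got {x.shape[1]} channels")
        out = self.stem_bn(self.stem(x)).relu()
        feats = {"C1": FeatureMap(out, 2)}
        stride = 2
        for k, stage in enumerate(self.stages, start=2):
            for block in stage:
                out = block(out)
            stride *= 2
            feats[f"C{k}"] = FeatureMap(out, stride)
        return feats


class FeaturePyramid(Module):
    """Top-down pyramid: lateral 1x1 projections of C2..C5, nearest x2
    top-down upsampling with element-wise addition, 3x3 smoothing for
    P2..P5; P6 and P7 from stride-2 3x3 convolutions."""

    def __init__(self, backbone_channels: dict[str, int], pyramid_width: int = 256,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        pw = pyramid_width
        self.pyramid_width = pw
        self.laterals = [Conv2d(backbone_channels[f"C{k}"], pw, 1, rng=rng)
                         for k in (2, 3, 4, 5)]
        self.smooth = [Conv2d(pw, pw, 3, padding=1, rng=rng) for _ in range(4)]
        self.p6_conv = Conv2d(pw, pw, 3, stride=2, padding=1, rng=rng)
        self.p7_conv = Conv2d(pw, pw, 3, stride=2, padding=1, rng=rng)

    def forward(self, backbone_out: dict[str, FeatureMap]) -> PyramidFeatures:
        lat = []
        for i, k in enumerate((2, 3, 4, 5)):
            fm = backbone_out[f"C{k}"]
            if fm.stride != 2 ** k:
                raise ValueError(f"C{k} has stride {fm.stride}, expected {2 ** k}")
            lat.append(self.laterals[i](fm.values))
        # top-down: start from the C5 projection, upsample x2, add laterally
        merged = [None] * 4
        merged[3] = lat[3]
        for i in (2, 1, 0):
            merged[i] = lat[i] + upsample_nearest(merged[i + 1], 2)
        levels = {}
        for i, name in enumerate(("P2", "P3", "P4", "P5")):
            levels[name] = FeatureMap(self.smooth[i](merged[i]), PYRAMID_STRIDES[name])
        p6 = self.p6_conv(lat[3])
        levels["P6"] = FeatureMap(p6, 64)
        levels["P7"] = FeatureMap(self.p7_conv(p6), 128)
        return PyramidFeatures(levels)


def merge_levels(pyramid: PyramidFeatures, mode: str = "sum") -> BilevelFeatures:
    """Merge P2..P5 into the low-level stream (stride 4) and P5..P7 into
    the high-level stream (stride 32).

    ``mode="sum"`` upsamples every level to the finest grid of its group
    (nearest neighbour) and adds element-wise, preserving the channel
    count; ``mode="concat"`` concatenates instead (4x / 3x the channels).
    """
    def combine(names, target_stride):
        ups = []
        for name in names:
            fm = pyramid[name]
            factor = fm.stride // target_stride
            ups.append(upsample_nearest(fm.values, factor) if factor > 1 else fm.values)
        if mode == "sum":
            out = ups[0]
            for u in ups[1:]:
                out = out + u
        elif mode == "concat":
            out = concat(ups, axis=1)
        else:
            raise ValueError(f"unknown merge mode: {mode!r}")
        return FeatureMap(out, target_stride)

    return BilevelFeatures(low=combine(("P2", "P3", "P4", "P5"), 4),
                           high=combine(("P5", "P6", "P7"), 32))
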