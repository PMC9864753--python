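"""Feature integration unit and mask-prediction head.

The refined high-level stream (channel attention output, stride 32) is
summarized by global average pooling into a per-channel descriptor; a 1x1
convolution and a sigmoid turn it into the high-level indicator F_H, one
gate per channel, which guides the low-level stream.  The refined
low-level stream (spatial attention output, stride 4) is normalized and
projected by batch norm + 1x1 convolution into F_L.  The integrated map is

    O_s = up(C'_T) + F_H * F_L

with the high-level stream nearest-upsampled to the stride-4 grid and F_H
broadcast over positions.  A 1x1 prediction head maps O_s to a foreground
logit, a sigmoid and a bilinear x4 upsample give a full-resolution
probability map, padding is removed, and thresholding (>=, default 0.5)
gives the binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor, upsample_bilinear, upsample_nearest

__all__ = ["FeatureIntegrationUnit", "PredictionHead", "SegmentationOutput",
           "fiu_high_indicator", "fiu_low_adjust", "integrate", "predict_mask"]


@dataclass
class SegmentationOutput:
    """Full-resolution probability map and its thresholded binary mask."""

    probability_map: np.ndarray
    binary_mask: np.ndarray
    threshold: float = 0.5


class FeatureIntegrationUnit(Module):
    """Merge the refined high- and low-level streams into one stride-4 map."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv_high = Conv2d(channels, channels, 1, rng=rng)
        self.bn_low = BatchNorm2d(channels)
        self.conv_low = Conv2d(channels, channels, 1, rng=rng)
        self.channels = channels

    def high_indicator(self, high_refined: Tensor) -> Tensor:
        """F_H: sigmoid(1x1 conv(global average pool)) -> (N, C, 1, 1)."""
        pooled = high_refined.mean(axis=(2, 3), keepdims=True)
        return self.conv_high(pooled).sigmoid()

    def low_adjust(self, low_refined: Tensor) -> Tensor:
        """F_L: 1x1 conv(batch norm(low stream)); same spatial size."""
        return self.conv_low(self.bn_low(low_refined))

    def forward(self, high_refined: Tensor, low_refined: Tensor) -> Tensor:
        if high_refined.shape[1] != self.channels or low_refined.shape[1] != self.channels:
            raise ValueError("channel count does not match the integration unit")
        f_h = self.high_indicator(high_refined)
        f_l = self.low_adjust(low_refined)
        factor = low_refined.shape[2] // high_refined.shape[2]
        return upsample_nearest(high_refined, factor) + f_h * f_l


class PredictionHead(Module):
    """1x1 convolution to one channel, sigmoid, bilinear x4 upsampling."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(channels, 1, 1, rng=rng)

    def forward(self, integrated: Tensor) -> Tensor:
        prob = self.conv(integrated).sigmoid()
        return upsample_bilinear(prob, 4)


def _crop(prob: np.ndarray, pad_info) -> np.ndarray:
    if pad_info is None:
        return prob
    top, left, h, w = pad_info
    return prob[top:top + h, left:left + w]


def threshold_probabilities(prob: np.ndarray, threshold: float = 0.5,
                            pad_info=None) -> SegmentationOutput:
    """Crop away padding and binarize with the >= rule (ties go foreground)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    prob = _crop(np.asarray(prob, dtype=np.float64), pad_info)
    return SegmentationOutput(probability_map=prob,
                              binary_mask=(prob >= threshold).astype(np.uint8),
                              threshold=threshold)


# ------------------------------------------------------- functional surface


def fiu_high_indicator(high_refined: np.ndarray, weight: np.ndarray,
                       bias: np.ndarray | None = None) -> np.ndarray:
    """F_H on an H x W x C array with a (C, C) 1x1-conv weight matrix."""
    x = np.asarray(high_refined, dtype=np.float64)
    weight = np.asarray(weight, dtype=np.float64)
    pooled = x.mean(axis=(0, 1))
    out = weight @ pooled
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-out))


def fiu_low_adjust(low_refined: np.ndarray, weight: np.ndarray,
                   bias: np.ndarray | None = None) -> np.ndarray:
    """F_L on an H x W x C array (batch norm frozen to identity):
    per-position 1x1 convolution with a (C_out, C) weight matrix."""
    x = np.asarray(low_refined, dtype=np.float64)
    weight = np.asarray(weight, dtype=np.float64)
    out = x @ weight.T
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float64)
    return out


def integrate(high_refined: np.ndarray, f_h: np.ndarray, f_l: np.ndarray,
              factor: int = 8) -> np.ndarray:
    """O_s = up(high) + F_H * F_L on H x W x C arrays (nearest upsampling)."""
    high = np.asarray(high_refined, dtype=np.float64)
    f_h = np.asarray(f_h, dtype=np.float64).ravel()
    f_l = np.asarray(f_l, dtype=np.float64)
    if f_h.size != f_l.shape[-1] or high.shape[-1] != f_l.shape[-1]:
        raise ValueError("channel counts of high stream, F_H and F_L must agree")
    up = high.repeat(factor, axis=0).repeat(factor, axis=1)
    if up.shape[:2] != f_l.shape[:2]:
        raise ValueError(f"upsampled high stream {up.shape[:2]} does not match "
                         f"F_L {f_l.shape[:2]}")
    return up + f_h * f_l


def predict_mask(o_s: np.ndarray, weight: np.ndarray, bias: float = 0.0,
                 threshold: float = 0.5, pad_info=None) -> SegmentationOutput:
    """Head on an H x W x C integrated map: 1x1 conv to one channel,
    sigmoid, bilinear x4 upsample, unpad, threshold."""
    x = np.asarray(o_s, dtype=np.float64)
    logits = x @ np.asarray(weight, dtype=np.float64).ravel() + bias
    t = Tensor(logits[None, None])
    prob = upsample_bilinear(t.sigmoid(), 4).data[0, 0]
    return threshold_probabilities(prob, threshold, pad_info)
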