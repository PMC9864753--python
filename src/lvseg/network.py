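"""The bilateral segmentation network, end to end.

Input image -> residual backbone (C1..C5) -> feature pyramid (P2..P7) ->
merged low/high streams -> spatial & channel attention units (in parallel)
-> feature integration unit -> 1x1 prediction head -> full-resolution
probability map.  Images are symmetrically zero-padded to a multiple of
128 (the stride of P7) before the forward pass and predictions are cropped
back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .attention import ChannelFeatureUnit, SpatialFeatureUnit
from .backbone import (FeaturePyramid, ResidualBackbone, merge_levels,
                       pad_to_multiple)
from .fusion import (FeatureIntegrationUnit, PredictionHead, SegmentationOutput,
                     threshold_probabilities)
from .nn import Module, Tensor

__all__ = ["ArchConfig", "BilateralSegNet", "DESK_ARCH", "PAPER_ARCH"]


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters.

    ``backbone_depth`` is "resnet50" (bottleneck stages 3-4-6-3) or "tiny"
    (one basic block per stage); ``pyramid_width`` is the uniform FPN
    channel count; ``merge_mode`` is "sum" or "concat"; ``sfu_kernel`` the
    spatial-attention kernel size; ``cfu_reduction`` the channel-MLP
    bottleneck ratio; ``cfu_shared`` shares the MLP between the pooling
    branches.
    """

    backbone_depth: str = "resnet50"
    base_width: int = 64
    pyramid_width: int = 256
    merge_mode: str = "sum"
    sfu_kernel: int = 7
    cfu_reduction: int = 16
    cfu_shared: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


# full-scale profile and a small profile that trains on a CPU in seconds
PAPER_ARCH = ArchConfig()
DESK_ARCH = ArchConfig(backbone_depth="tiny", base_width=16, pyramid_width=32,
                       cfu_reduction=4)


class BilateralSegNet(Module):
    """Backbone + FPN + SFU/CFU + FIU + prediction head."""

    def __init__(self, arch: ArchConfig = DESK_ARCH, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.backbone = ResidualBackbone(arch.backbone_depth, arch.base_width, rng=rng)
        self.fpn = FeaturePyramid(self.backbone.channels, arch.pyramid_width, rng=rng)
        stream_width = arch.pyramid_width
        if arch.merge_mode == "concat":
            # low stream concatenates 4 levels, high stream 3; use the max
            raise ValueError("concat merging requires per-stream widths; "
                             "use merge_mode='sum' for the assembled network")
        self.sfu = SpatialFeatureUnit(arch.sfu_kernel, rng=rng)
        self.cfu = ChannelFeatureUnit(stream_width, arch.cfu_reduction,
                                      arch.cfu_shared, rng=rng)
        self.fiu = FeatureIntegrationUnit(stream_width, rng=rng)
        self.head = PredictionHead(stream_width, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) with H, W multiples of 128 -> (N, 1, H, W)
        foreground probabilities."""
        feats = self.backbone(x)
        pyramid = self.fpn(feats)
        streams = merge_levels(pyramid, self.arch.merge_mode)
        low_refined = self.sfu(streams.low.values)
        high_refined = self.cfu(streams.high.values)
        integrated = self.fiu(high_refined, low_refined)
        return self.head(integrated)

    # ------------------------------------------------------------ inference
    def predict(self, image: np.ndarray, threshold: float = 0.5) -> SegmentationOutput:
        """Segment one grayscale image (values in [0,1], any size)."""
        image = np.asarray(image, dtype=np.float64)
        padded, pad_info = pad_to_multiple(image, 128)
        was_training = self.training
        self.eval()
        try:
            prob = self.forward(Tensor(padded[None, None])).data[0, 0]
        finally:
            self.train(was_training)
        return threshold_probabilities(prob, threshold, pad_info)
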