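"""Spatial and channel feature-refinement units.

Two parallel attention blocks refine the merged feature streams:

* the **spatial feature unit** (SFU) pools the low-level stream along the
  channel axis (mean and max), concatenates the two maps, applies a k x k
  convolution, batch normalization and a sigmoid to produce a per-position
  gate in (0,1), and multiplies the input by it (broadcast over channels);
* the **channel feature unit** (CFU) pools the high-level stream over the
  spatial axes (mean and max), pushes both descriptors through one shared
  one-hidden-layer MLP (C -> C/r -> C, ReLU hidden), sums the two outputs
  element-wise, applies a sigmoid to get a per-channel gate in (0,1), and
  multiplies the input by it (broadcast over positions).

The module classes run inside the autodiff graph; the plain functions at
the bottom expose the same arithmetic on numpy arrays (H x W x C layout)
for direct use and verification.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, Linear, Module, Tensor, concat

__all__ = ["SpatialFeatureUnit", "ChannelFeatureUnit",
           "spatial_pool", "spatial_attention", "refine_spatial",
           "channel_pool", "channel_attention", "refine_channel"]


class SpatialFeatureUnit(Module):
    """Per-position attention on the low-level stream."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2, rng=rng)
        self.bn = BatchNorm2d(1)

    def attention(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.amax(axis=1, keepdims=True)
        return self.bn(self.conv(concat([avg, mx], axis=1))).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention(x)


class ChannelFeatureUnit(Module):
    """Per-channel attention on the high-level stream.

    The MLP is shared between the average- and max-pooled descriptors by
    default (``shared=False`` gives each branch its own weights).
    """

    def __init__(self, channels: int, reduction: int = 16, shared: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ({reduction})")
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        if shared:
            self.fc1_max, self.fc2_max = self.fc1, self.fc2
        else:
            self.fc1_max = Linear(channels, hidden, rng=rng)
            self.fc2_max = Linear(hidden, channels, rng=rng)
        self.shared = shared
        self.channels = channels

    def _children(self):
        # avoid double-visiting shared branch modules
        yield "fc1", self.fc1
        yield "fc2", self.fc2
        if not self.shared:
            yield "fc1_max", self.fc1_max
            yield "fc2_max", self.fc2_max

    def attention(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3), keepdims=False).reshape(n, c)
        mx = x.amax(axis=(2, 3), keepdims=False).reshape(n, c)
        out = self.fc2(self.fc1(avg).relu()) + self.fc2_max(self.fc1_max(mx).relu())
        return out.sigmoid().reshape(n, c, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention(x)


# ------------------------------------------------------- functional surface
# numpy in, numpy out; arrays are H x W x C (single image)


def _to_nchw(x: np.ndarray) -> Tensor:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected an H x W x C array")
    return Tensor(np.moveaxis(x, -1, 0)[None])


def spatial_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and max over the channel axis -> two H x W maps."""
    t = _to_nchw(x)
    return t.mean(axis=1).data[0], t.amax(axis=1).data[0]


def spatial_attention(avg_map: np.ndarray, max_map: np.ndarray,
                      weight: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """sigmoid(conv(concat(avg, max))) with batch norm frozen to identity.

    ``weight`` is a (1, 2, k, k) kernel with odd k; returns an H x W map
    strictly inside (0, 1).
    """
    if avg_map.shape != max_map.shape:
        raise ValueError("pooled maps must share a shape")
    weight = np.asarray(weight, dtype=np.float64)
    k = weight.shape[-1]
    stacked = Tensor(np.stack([avg_map, max_map])[None])
    from .nn import conv2d
    out = conv2d(stacked, Tensor(weight), Tensor(np.atleast_1d(bias)), padding=k // 2)
    return out.sigmoid().data[0, 0]


def refine_spatial(x: np.ndarray, att: np.ndarray) -> np.ndarray:
    """Multiply an H x W x C feature by an H x W attention map."""
    x = np.asarray(x, dtype=np.float64)
    att = np.asarray(att, dtype=np.float64)
    if x.shape[:2] != att.shape:
        raise ValueError(f"spatial sizes differ: {x.shape[:2]} vs {att.shape}")
    return x * att[..., None]


def channel_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and max over all spatial positions -> two length-C vectors."""
    t = _to_nchw(x)
    return (t.mean(axis=(2, 3)).data[0].ravel(),
            t.amax(axis=(2, 3)).data[0].ravel())


def channel_attention(avg_vec: np.ndarray, max_vec: np.ndarray,
                      mlp_weights: tuple) -> np.ndarray:
    """sigmoid(MLP(avg) + MLP(max)) with a shared (W1, b1, W2, b2) MLP."""
    avg_vec = np.asarray(avg_vec, dtype=np.float64)
    max_vec = np.asarray(max_vec, dtype=np.float64)
    if avg_vec.shape != max_vec.shape:
        raise ValueError("pooled vectors must share a length")
    w1, b1, w2, b2 = (np.asarray(a, dtype=np.float64) for a in mlp_weights)

    def mlp(v):
        return np.maximum(v @ w1 + b1, 0.0) @ w2 + b2

    return 1.0 / (1.0 + np.exp(-(mlp(avg_vec) + mlp(max_vec))))


def refine_channel(x: np.ndarray, att: np.ndarray) -> np.ndarray:
    """Multiply an H x W x C feature by a length-C attention vector."""
    x = np.asarray(x, dtype=np.float64)
    att = np.asarray(att, dtype=np.float64).ravel()
    if x.shape[-1] != att.size:
        raise ValueError(f"channel counts differ: {x.shape[-1]} vs {att.size}")
    return x * att
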