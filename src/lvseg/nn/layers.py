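"""Neural-network layers built on the autodiff tensor.

Modules mirror the familiar torch-style contract: ``parameters()`` /
``named_parameters()`` collect trainable tensors recursively, ``train()`` /
``eval()`` toggle batch-norm behaviour, and ``state_dict`` /
``load_state_dict`` serialize parameters plus running statistics as plain
numpy arrays (saved with ``np.savez``).
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, conv2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear"]


class Module:
    def __init__(self):
        self.training = True

    # ----------------------------------------------------------- traversal
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name.startswith("buf_") and isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # --------------------------------------------------------- persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, array in state.items():
            if name in own:
                own[name].data[...] = array
            elif name in bufs:
                bufs[name][...] = array
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"state dict is missing entries: {sorted(missing)}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """k x k cross-correlation with He-normal weight initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale,
                                           (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization: batch statistics while training, running
    statistics at inference (exponential average, momentum 0.1)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones((1, channels, 1, 1)))
        self.bias = Parameter(np.zeros((1, channels, 1, 1)))
        self.buf_running_mean = np.zeros((1, channels, 1, 1))
        self.buf_running_var = np.ones((1, channels, 1, 1))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mu
            var = (centred ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            xhat = centred * ((var + self.eps) ** -0.5)
            m = self.momentum
            self.buf_running_mean *= 1 - m
            self.buf_running_mean += m * mu.data
            self.buf_running_var *= 1 - m
            self.buf_running_var += m * var.data
        else:
            xhat = (x - self.buf_running_mean) * ((self.buf_running_var + self.eps) ** -0.5)
        return self.weight * xhat + self.bias


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
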