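"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape: every operation returns a new :class:`Tensor`
holding its result, the parent tensors, and a closure that accumulates
gradients into the parents.  ``Tensor.backward()`` topologically sorts the
graph and runs the closures.  Only the operations the segmentation network
needs are implemented: elementwise arithmetic with broadcasting, matmul,
reductions (sum / mean / max over axes), relu, sigmoid, channel
concatenation, 2-D convolution (im2col), and nearest / bilinear upsampling.

Arrays are float64 throughout; feature maps use the NCHW layout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "upsample_nearest",
    "upsample_bilinear",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big networks
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, self._lift(other)

        def backward(g):
            a._accumulate(_sum_to_shape(g, a.data.shape))
            b._accumulate(_sum_to_shape(g, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._node(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._lift(other)

        def backward(g):
            a._accumulate(_sum_to_shape(g * b.data, a.data.shape))
            b._accumulate(_sum_to_shape(g * a.data, b.data.shape))

        return Tensor._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        out_data = a.data ** e

        def backward(g):
            a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._node(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, self._lift(other)

        def backward(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return Tensor._node(a.data @ b.data, (a, b), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return Tensor._node(a.data.reshape(*shape), (a,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis, keepdims: bool = False):
        """Max over ``axis``; ties share the gradient equally."""
        a = self
        mx = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == mx).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        out = mx if keepdims else np.squeeze(mx, axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(mask * g)

        return Tensor._node(out, (a,), backward)

    # ------------------------------------------------------------ activations
    def relu(self):
        a = self
        pos = a.data > 0

        def backward(g):
            a._accumulate(g * pos)

        return Tensor._node(np.where(pos, a.data, 0.0), (a,), backward)

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * y * (1.0 - y))

        return Tensor._node(y, (a,), backward)


class Parameter(Tensor):
    """A trainable tensor (distinguished so modules can collect them)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------- ops


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    parts = [Tensor._lift(t) for t in tensors]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accumulate(g[tuple(sl)])

    return Tensor._node(np.concatenate([p.data for p in parts], axis=axis), parts, backward)


def _sliding_cols(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N*Ho*Wo, C*kh*kw) patch matrix."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride, :, :]  # N,C,Ho,Wo,kh,kw
    n, c, ho, wo = view.shape[:4]
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (N,C,H,W), w (Cout,Cin,kh,kw), b (Cout,)."""
    n, cin, h, wdt = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input has {cin}, kernel expects {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _sliding_cols(xp, kh, kw, stride)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if b is not None:
            b._accumulate(gcols.sum(axis=0))
        w._accumulate((gcols.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            dcols = gcols @ wmat  # (N*Ho*Wo, C*kh*kw)
            dcols = dcols.reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcols[:, :, i, j]
            hp, wp = xp.shape[2], xp.shape[3]
            x._accumulate(dxp[:, :, padding:hp - padding or None, padding:wp - padding or None])

    return Tensor._node(out, parents, backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    a = x
    f = int(factor)
    out = a.data.repeat(f, axis=2).repeat(f, axis=3)

    def backward(g):
        n, c, h, w = a.data.shape
        a._accumulate(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))

    return Tensor._node(out, (a,), backward)


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor (half-pixel-centre convention)."""
    a = x
    n, c, h, w = a.data.shape
    f = int(factor)
    ho, wo = h * f, w * f

    def axis_weights(size_in, size_out):
        src = (np.arange(size_out) + 0.5) / f - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, size_in - 1)
        hi = np.clip(lo + 1, 0, size_in - 1)
        t = np.clip(src - np.floor(src), 0.0, 1.0)
        t[src < 0] = 0.0
        return lo, hi, t

    r0, r1, tr = axis_weights(h, ho)
    c0, c1, tc = axis_weights(w, wo)
    wr0, wr1 = (1 - tr)[:, None], tr[:, None]
    wc0, wc1 = (1 - tc)[None, :], tc[None, :]

    d = a.data
    out = (
        d[:, :, r0][:, :, :, c0] * (wr0 * wc0)
        + d[:, :, r0][:, :, :, c1] * (wr0 * wc1)
        + d[:, :, r1][:, :, :, c0] * (wr1 * wc0)
        + d[:, :, r1][:, :, :, c1] * (wr1 * wc1)
    )

    def backward(g):
        dx = np.zeros_like(a.data)
        for rows, wrow in ((r0, wr0), (r1, wr1)):
            for cols_, wcol in ((c0, wc0), (c1, wc1)):
                contrib = g * (wrow * wcol)
                # scatter-add along both axes
                tmp = np.zeros((n, c, h, wo))
                np.add.at(tmp, (slice(None), slice(None), rows), contrib)
                np.add.at(dx.transpose(0, 1, 3, 2), (slice(None), slice(None), cols_),
                          tmp.transpose(0, 1, 3, 2))
        a._accumulate(dx)

    return Tensor._node(out, (a,), backward)
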