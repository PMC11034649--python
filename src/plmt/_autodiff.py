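"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the 2D encoder-decoder segmentation
network and its losses need: broadcasting arithmetic, matmul, exp/log,
reductions, reshape/concat, ReLU/sigmoid/softmax, 3x3 same-padding
convolution (im2col), 2x2 max pooling and 2x nearest-neighbour upsampling.
Gradients accumulate into ``Tensor.grad``; ``backward`` runs a topological
sweep from a scalar loss. float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 expanded by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        if not self.requires_grad:
            return Tensor(-self.data)

        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, True, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * out_data / other.data, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    def __pow__(self, p: float):
        out_data = self.data ** p
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor(out_data, True, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __matmul__ = matmul

    # -- elementwise nonlinearity ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor(out_data, True, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accum(g / self.data)

        return Tensor(out_data, True, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        if not self.requires_grad:
            return Tensor(out_data)
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor(out_data, True, (self,), bwd)

    def sigmoid(self):
        # numerically stable piecewise form
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, True, (self,), bwd)

    def softmax(self, axis: int = 1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum((g - dot) * out_data)

        return Tensor(out_data, True, (self,), bwd)

    # -- reductions and shaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).astype(np.float32))

        return Tensor(out_data, True, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        if not self.requires_grad:
            return Tensor(out_data)
        orig = self.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor(out_data, True, (self,), bwd)

    @staticmethod
    def concat(tensors: list, axis: int = 1) -> "Tensor":
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        req = any(t.requires_grad for t in tensors)
        if not req:
            return Tensor(out_data)
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(a, b)
                    t._accum(g[tuple(idx)])

        return Tensor(out_data, True, tuple(tensors), bwd)

    def gather_channel(self, index: np.ndarray) -> "Tensor":
        """Pick out[b,h,w] = self[b, index[b,h,w], h, w] (class gather)."""
        b, c, h, w = self.shape
        bi, hi, wi = np.ogrid[:b, :h, :w]
        out_data = self.data[bi, index, hi, wi]
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (bi, index, hi, wi), g)
            self._accum(full)

        return Tensor(out_data, True, (self,), bwd)

    # -- spatial ops -----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", ksize: int) -> "Tensor":
        """Same-padding stride-1 2D convolution; weight (Cout, Cin*k*k)."""
        b, cin, h, w = self.shape
        pad = ksize // 2
        if pad:
            xp = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        else:
            xp = self.data
        # cols: (B, Cin*k*k, H*W)
        cols = np.empty((b, cin, ksize, ksize, h, w), dtype=np.float32)
        for i in range(ksize):
            for j in range(ksize):
                cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
        cols2 = cols.reshape(b, cin * ksize * ksize, h * w)
        out_data = (weight.data @ cols2).reshape(b, -1, h, w)
        out_data += bias.data.reshape(1, -1, 1, 1)
        req = self.requires_grad or weight.requires_grad or bias.requires_grad
        if not req:
            return Tensor(out_data)

        def bwd(g):
            gout = g.reshape(b, g.shape[1], h * w)
            if bias.requires_grad:
                bias._accum(gout.sum(axis=(0, 2)))
            if weight.requires_grad:
                weight._accum(np.einsum("bop,bkp->ok", gout, cols2,
                                        optimize=True).astype(np.float32))
            if self.requires_grad:
                gcols = (weight.data.T @ gout).reshape(b, cin, ksize, ksize, h, w)
                gp = np.zeros_like(xp)
                for i in range(ksize):
                    for j in range(ksize):
                        gp[:, :, i:i + h, j:j + w] += gcols[:, :, i, j]
                if pad:
                    gp = gp[:, :, pad:-pad, pad:-pad]
                self._accum(gp)

        return Tensor(out_data, True, (self, weight, bias), bwd)

    def maxpool2(self) -> "Tensor":
        b, c, h, w = self.shape
        blocks = self.data.reshape(b, c, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            gflat = np.zeros((b, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gfull = gflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gfull.reshape(b, c, h, w))

        return Tensor(out_data, True, (self,), bwd)

    def upsample2(self) -> "Tensor":
        """Nearest-neighbour 2x upsampling."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)
        if not self.requires_grad:
            return Tensor(out_data)
        b, c, h, w = self.shape

        def bwd(g):
            self._accum(g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor(out_data, True, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused batch normalization over (batch, H, W) per channel.

    Returns (out, batch_mean, batch_var); the statistics are plain arrays
    for the caller's running-average bookkeeping.
    """
    axes = (0, 2, 3)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = np.square(x.data - mu).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    if not req:
        return Tensor(out_data), mu, var

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes, keepdims=True))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv * (dxhat - m1 - xhat * m2))

    return Tensor(out_data, True, (x, gamma, beta), bwd), mu, var
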