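"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar loss walks the tape
in reverse topological order and accumulates gradients into every tensor
created with ``requires_grad=True``.

The op set is exactly what the encoder-decoder networks need: elementwise
arithmetic, matmul, 2-D convolution (im2col), batch normalisation, nearest
2x upsampling, ReLU/Tanh/softmax, log/clip, reductions, concat and reshape.
Everything is NCHW and float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    # explicit float64 arrays/scalars keep their precision (high-accuracy
    # checks); everything else, including python scalars, becomes float32
    if getattr(x, "dtype", None) == np.float64:
        return np.asarray(x)
    return np.asarray(x, dtype=_F32)


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep at 4 encoder stages
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def square(self):
        a = self

        def bw(g):
            a._accum(g * (2.0 * a.data))

        return Tensor._make(a.data * a.data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bw)

    # -- activations -------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), bw)

    def softmax(self, axis: int = 1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

        return Tensor._make(out_data, (a,), bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).astype(a.data.dtype))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum((np.broadcast_to(gg, a.shape) / n).astype(a.data.dtype))

        return Tensor._make(a.data.mean(axis=axis, keepdims=keepdims), (a,), bw)

    # -- shape ops ---------------------------------------------------------

    def __getitem__(self, key):
        a = self

        def bw(g):
            dx = np.zeros_like(a.data)
            dx[key] = g
            a._accum(dx)

        return Tensor._make(a.data[key], (a,), bw)

    def reshape(self, *shape):
        a = self
        old = a.shape

        def bw(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bw)

    def matmul(self, other: "Tensor"):
        a, b = self, other

        def bw(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bw)

    def upsample2x(self):
        """Nearest-neighbour 2x spatial upsampling of an NCHW tensor."""
        a = self
        out_data = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def bw(g):
            n, c, h2, w2 = g.shape
            a._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

        return Tensor._make(out_data, (a,), bw)

    # -- convolution -------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation, NCHW input, OIHW weight."""
        a, w = self, weight
        x = a.data
        n, c, h, ww = x.shape
        f, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        if kh == 1 and kw == 1 and stride == 1 and padding == 0:
            return self._conv1x1(w, bias)
        if padding:
            xp = np.zeros((n, c, h + 2 * padding, ww + 2 * padding),
                          dtype=x.dtype)
            xp[:, :, padding:padding + h, padding:padding + ww] = x
            x = xp
        oh = (x.shape[2] - kh) // stride + 1
        ow = (x.shape[3] - kw) // stride + 1
        cols = _im2col(x, kh, kw, stride, oh, ow)       # (n, c*kh*kw, oh*ow)
        wmat = w.data.reshape(f, c * kh * kw)
        out_data = np.matmul(wmat, cols)                 # (n, f, oh*ow)
        out_data = out_data.reshape(n, f, oh, ow)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, f, 1, 1)

        parents = (a, w) if bias is None else (a, w, bias)

        def bw(g):
            gmat = np.ascontiguousarray(g).reshape(n, f, oh * ow)
            w._accum(np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
                     .reshape(w.shape))
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            dcols = np.matmul(wmat.T, gmat)              # (n, c*kh*kw, oh*ow)
            dx = _col2im(dcols, x.shape, kh, kw, stride, oh, ow)
            if padding:
                dx = dx[:, :, padding:-padding, padding:-padding]
            a._accum(dx)

        return Tensor._make(out_data, parents, bw)

    def _conv1x1(self, w: "Tensor", bias: "Tensor | None"):
        """Pointwise convolution as a single matmul over flattened pixels."""
        a = self
        x = a.data
        n, c, h, ww = x.shape
        f = w.shape[0]
        xmat = np.ascontiguousarray(x).reshape(n, c, h * ww)
        wmat = w.data.reshape(f, c)
        out_data = np.matmul(wmat, xmat).reshape(n, f, h, ww)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, f, 1, 1)

        parents = (a, w) if bias is None else (a, w, bias)

        def bw(g):
            gmat = np.ascontiguousarray(g).reshape(n, f, h * ww)
            w._accum(np.matmul(gmat, xmat.transpose(0, 2, 1)).sum(axis=0)
                     .reshape(w.shape))
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            a._accum(np.matmul(wmat.T, gmat).reshape(x.shape))

        return Tensor._make(out_data, parents, bw)

    # -- batch norm --------------------------------------------------------

    def batchnorm(self, gamma: "Tensor", beta: "Tensor",
                  running_mean: np.ndarray, running_var: np.ndarray,
                  training: bool, momentum: float = 0.1, eps: float = 1e-5):
        """Per-channel batch normalisation of an NCHW tensor.

        In training mode uses batch statistics and updates the running
        buffers in place; in eval mode uses the running buffers.
        """
        a = self
        x = a.data
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var
        else:
            mu, var = running_mean, running_var
        inv_std = 1.0 / np.sqrt(var + eps)
        scale = (gamma.data * inv_std).astype(_F32)
        shift = (beta.data - mu * scale).astype(_F32)
        out_data = x * scale[None, :, None, None] + shift[None, :, None, None]

        def bw(g):
            xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            beta._accum(g.sum(axis=(0, 2, 3)))
            gx = g * gamma.data[None, :, None, None]
            if training:
                m = x.shape[0] * x.shape[2] * x.shape[3]
                s1 = gx.sum(axis=(0, 2, 3))
                s2 = (gx * xhat).sum(axis=(0, 2, 3))
                dx = (gx - (s1[None, :, None, None]
                            + xhat * s2[None, :, None, None]) / m) \
                    * inv_std[None, :, None, None]
            else:
                dx = gx * inv_std[None, :, None, None]
            a._accum(dx.astype(_F32))

        return Tensor._make(out_data.astype(_F32), (a, gamma, beta), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis (channel axis by default)."""
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), bw)


# -- im2col helpers ---------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int,
            oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x.shape
    out = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i, j] = x[:, :, i:i + stride * oh:stride,
                                j:j + stride * ow:stride]
    return out.reshape(n, c * kh * kw, oh * ow)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int,
            stride: int, oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x_shape
    dx = np.zeros(x_shape, dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                cols[:, :, i, j]
    return dx


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over broadcast axes so it matches the parent shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g
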