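"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the primitives the ECG architectures need:
broadcasting arithmetic, matmul, pointwise nonlinearities, reductions,
shape ops, concatenation, basic slicing, and strided 1-D/2-D convolution.
Gradients flow through a dynamically built tape; ``Tensor.backward`` runs a
topological sweep and accumulates into ``.grad``.

All primitives are numerically validated against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "conv1d",
    "conv2d",
    "softmax",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading added axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- tape machinery -------------------------------------------------------
    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return _binop(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        return _binop(
            self, other, np.multiply, lambda g, a, b: (g * b.data, g * a.data)
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other, self.dtype) * self ** -1.0

    def __pow__(self, expo: float):
        out = _node(np.power(self.data, expo), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * expo * np.power(self.data, expo - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other, self.dtype)
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * y)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / self.data
        )
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - y * y)
        )
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * y * (1.0 - y)
        )
        return out

    def relu(self):
        mask = self.data > 0
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo
        out = _node(np.maximum(self.data, lo), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.data.shape)
        )
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.transpose(inv)
        )
        return out

    def __getitem__(self, key):
        out = _node(self.data[key], (self,))

        def bw(g):
            # only basic (slice/int) indexing is used on the tape
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            full[key] += g
            self._accumulate(full)

        out._backward = bw
        return out


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad for p in out._parents)
    if not out.requires_grad:
        out._parents = ()
    return out


def _binop(a: Tensor, b, fwd, grads) -> Tensor:
    b = _as_tensor(b, a.dtype)
    out = _node(fwd(a.data, b.data), (a, b))

    def bw(g):
        ga, gb = grads(g, a, b)
        if a.requires_grad:
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = bw
    return out


def _axis_size(shape, axis) -> int:
    if isinstance(axis, int):
        return shape[axis]
    n = 1
    for a in axis:
        n *= shape[a]
    return n


# -- multi-tensor / structured ops --------------------------------------------


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = _as_tensor(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else axis + t.ndim + 1, 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + (-np.max(x.data, axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + (-np.max(x.data, axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0) -> Tensor:
    """Strided 2-D convolution (cross-correlation), NCHW layout.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    kh, kw = w.shape[2], w.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # (N, C, Ho, Wo, kh, kw)
    y = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(xp)
            Ho, Wo = g.shape[2], g.shape[3]
            for i in range(kh):
                for j in range(kw):
                    # contribution of kernel tap (i, j) to input positions
                    gx[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                    )
            if ph or pw:
                gx = gx[:, :, ph : gx.shape[2] - ph or None, pw : gx.shape[3] - pw or None]
            x._accumulate(gx)

    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0) -> Tensor:
    """Strided 1-D convolution, NCL layout, via the 2-D kernel."""
    x4 = x.reshape(x.shape[0], x.shape[1], 1, x.shape[2])
    w4 = w.reshape(w.shape[0], w.shape[1], 1, w.shape[2])
    y = conv2d(x4, w4, b, stride=(1, stride), padding=(0, padding))
    return y.reshape(y.shape[0], y.shape[1], y.shape[3])
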