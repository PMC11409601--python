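"""Neural-network layers on top of the autodiff engine.

Includes the building blocks of the ECG architectures: linear maps, strided
1-D/2-D convolutions, LSTM cells, plain and conditional batch normalization,
layer normalization, and multi-head self-attention (full and axial).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d, conv2d, softmax

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        seen = set()
        for mod in [self, *self.modules()]:
            for v in mod.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Parameter) and id(item) not in seen:
                            seen.add(id(item))
                            params.append(item)
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def _buffer_slots(self):
        for mod in [self, *self.modules()]:
            for name in getattr(mod, "_buffers", ()):
                yield mod, name

    def state_dict(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        arrays.extend(np.array(getattr(m, n)) for m, n in self._buffer_slots())
        return arrays

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        buffers = list(self._buffer_slots())
        if len(params) + len(buffers) != len(state):
            raise ValueError("state_dict length mismatch")
        for p, arr in zip(params, state):
            p.data = np.array(arr, dtype=p.data.dtype)
        for (mod, name), arr in zip(buffers, state[len(params):]):
            setattr(mod, name, np.array(arr))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _rng(seed=None):
    return np.random.default_rng(seed)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reseed the parameter-initialization stream (determinism contract)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


def _kaiming(shape, fan_in):
    return _INIT_RNG.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


def normal_param(shape, std: float = 0.02) -> "Parameter":
    """A Parameter drawn from N(0, std) on the init stream (pos embeddings)."""
    return Parameter(std * _INIT_RNG.normal(size=shape))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.w = Parameter(_kaiming((in_features, out_features), in_features))
        self.b = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Conv1d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.w = Parameter(_kaiming((cout, cin, kernel), cin * kernel))
        self.b = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, bias=True):
        super().__init__()
        k = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.stride, self.padding = stride, padding
        self.w = Parameter(_kaiming((cout, cin, *k), cin * k[0] * k[1]))
        self.b = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class LSTM(Module):
    """Single-layer LSTM; input (N, T, F) -> (outputs (N, T, H), last h (N, H))."""

    def __init__(self, input_size: int, hidden_size: int):
        super().__init__()
        self.hidden_size = hidden_size
        self.w_ih = Parameter(_kaiming((input_size, 4 * hidden_size), input_size))
        self.w_hh = Parameter(_kaiming((hidden_size, 4 * hidden_size), hidden_size))
        self.bias = Parameter(np.zeros(4 * hidden_size))

    def forward(self, x: Tensor):
        n, t, _ = x.shape
        h_dim = self.hidden_size
        h = Tensor(np.zeros((n, h_dim), dtype=x.dtype))
        c = Tensor(np.zeros((n, h_dim), dtype=x.dtype))
        outs = []
        for step in range(t):
            xt = x[:, step, :]
            gates = xt @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, :h_dim].sigmoid()
            f = gates[:, h_dim : 2 * h_dim].sigmoid()
            g = gates[:, 2 * h_dim : 3 * h_dim].tanh()
            o = gates[:, 3 * h_dim :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(n, 1, h_dim))
        return concat(outs, axis=1), h


class BatchNorm(Module):
    """Batch normalization over (batch, *spatial) per channel; NC... layout."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 affine: bool = True):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels)) if affine else None
        self.beta = Parameter(np.zeros(channels)) if affine else None
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def _normalize(self, x: Tensor) -> Tensor:
        axes = (0, *range(2, x.ndim))
        shape = [1, x.shape[1]] + [1] * (x.ndim - 2)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            return (x - mu) / (var + self.eps) ** 0.5
        mu = Tensor(self.running_mean.reshape(shape))
        var = Tensor(self.running_var.reshape(shape))
        return (x - mu) / (var + self.eps) ** 0.5

    def forward(self, x: Tensor) -> Tensor:
        xhat = self._normalize(x)
        if self.gamma is None:
            return xhat
        shape = [1, x.shape[1]] + [1] * (x.ndim - 2)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ConditionalBatchNorm(Module):
    """Batch norm whose per-channel scale and shift are affine in a latent vector.

    The conditioning path predicts (delta_gamma, beta) per sample, so two
    different latent vectors modulate the same normalized feature map
    differently — this is how the time-domain encoding reaches the
    spectrogram branch.
    """

    def __init__(self, channels: int, latent_dim: int):
        super().__init__()
        self.channels = channels
        self.bn = BatchNorm(channels, affine=False)
        self.film = Linear(latent_dim, 2 * channels)
        # identity at init: conditioning starts as plain batch norm
        self.film.w.data[:] = 0.0

    def forward(self, x: Tensor, latent: Tensor) -> Tensor:
        xhat = self.bn(x)
        gb = self.film(latent)  # (N, 2C)
        shape = [x.shape[0], self.channels] + [1] * (x.ndim - 2)
        gamma = (1.0 + gb[:, : self.channels]).reshape(shape)
        beta = gb[:, self.channels :].reshape(shape)
        return xhat * gamma + beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps) ** 0.5 * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (N, T, D)."""

    def __init__(self, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads, self.dim = heads, dim
        self.qkv = Linear(dim, 3 * dim)
        self.proj = Linear(dim, dim)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, dh = self.heads, d // self.heads
        qkv = self.qkv(x)  # (N, T, 3D)
        q = qkv[:, :, :d].reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, d : 2 * d].reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * d :].reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.proj(ctx)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block (attention + feed-forward)."""

    def __init__(self, dim: int, heads: int, ff_mult: int = 2):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_mult * dim)
        self.ff2 = Linear(ff_mult * dim, dim)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


class RAdam:
    """Rectified Adam: Adam with variance rectification during warm-up.

    Falls back to an un-adapted (momentum-only) step while the variance
    estimate is untrustworthy, then switches to rectified adaptive steps.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self):
        self.t += 1
        t = self.t
        b1t, b2t = self.b1 ** t, self.b2 ** t
        rho = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            m_hat = m / (1.0 - b1t)
            if rho > 4.0:
                v_hat = np.sqrt(v / (1.0 - b2t))
                r = np.sqrt(
                    ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
                )
                p.data -= (self.lr * r * m_hat / (v_hat + self.eps)).astype(p.data.dtype)
            else:
                p.data -= (self.lr * m_hat).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
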