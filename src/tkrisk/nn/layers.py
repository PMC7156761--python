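"""Layers with forward/backward passes, parameter objects and Adam.

All layers operate channels-last on arrays of shape ``(N, *spatial, C)``
with 2 or 3 spatial axes, in float32. ``forward(x, train=...)`` caches what
``backward(grad)`` needs; ``backward`` accumulates parameter gradients and
returns the input gradient.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base layer; ``trainable = False`` freezes its parameters."""

    trainable: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _as_tuple(v, nd: int) -> tuple[int, ...]:
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v),) * nd


class Conv(Module):
    """N-d convolution (cross-correlation) with stride and zero padding.

    Computed as a sum over kernel offsets of strided input slices matrix-
    multiplied by the per-offset channel-mixing matrix; for the small
    kernels used here this avoids materializing an im2col buffer. Weights
    are stored flat as ``(in_ch * prod(kernel), out_ch)`` ordered
    ``(C, *kernel)``.
    """

    def __init__(self, in_ch, out_ch, kernel, nd, stride=1, padding=0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.nd = nd
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = _as_tuple(kernel, nd)
        self.stride = _as_tuple(stride, nd)
        self.padding = _as_tuple(padding, nd)
        fan_in = in_ch * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)  # He init for rectifier networks
        self.weight = Param(rng.normal(0.0, scale, size=(fan_in, out_ch)))
        self.bias = Param(np.zeros(out_ch))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _offset_slices(self, out_spatial):
        for offset in itertools.product(*(range(k) for k in self.kernel)):
            sl = tuple(
                slice(o, o + s * (p - 1) + 1, s)
                for o, s, p in zip(offset, self.stride, out_spatial)
            )
            yield offset, (slice(None),) + sl + (slice(None),)

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if not any(self.padding):
            return x
        padded = tuple(s + 2 * p for s, p in zip(x.shape[1:-1], self.padding))
        xp = np.zeros(x.shape[:1] + padded + x.shape[-1:], dtype=x.dtype)
        core = (slice(None),) + tuple(
            slice(p, p + s) for p, s in zip(self.padding, x.shape[1:-1])
        ) + (slice(None),)
        xp[core] = x
        return xp

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[-1]}")
        xp = self._pad(np.asarray(x, dtype=DTYPE))
        out_spatial = tuple(
            (sp - k) // s + 1
            for sp, k, s in zip(xp.shape[1:-1], self.kernel, self.stride)
        )
        self._out_spatial = out_spatial
        self._xp = xp
        wk = self.weight.value.reshape(
            (self.in_ch,) + self.kernel + (self.out_ch,)
        )
        acc = np.zeros(xp.shape[:1] + out_spatial + (self.out_ch,), dtype=DTYPE)
        for offset, sl in self._offset_slices(out_spatial):
            w = wk[(slice(None),) + offset]  # (C, F)
            acc += xp[sl] @ w
        acc += self.bias.value
        return acc

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        g = np.ascontiguousarray(grad, dtype=DTYPE)
        self.bias.grad += g.reshape(-1, self.out_ch).sum(axis=0)
        wk = self.weight.value.reshape(
            (self.in_ch,) + self.kernel + (self.out_ch,)
        )
        dwk = self.weight.grad.reshape(
            (self.in_ch,) + self.kernel + (self.out_ch,)
        )
        gmat = g.reshape(-1, self.out_ch)
        dxp = np.zeros_like(xp)
        for offset, sl in self._offset_slices(self._out_spatial):
            xs = np.ascontiguousarray(xp[sl]).reshape(-1, self.in_ch)
            dwk[(slice(None),) + offset] += xs.T @ gmat
            w = wk[(slice(None),) + offset]
            dxp[sl] += (gmat @ w.T).reshape(g.shape[:-1] + (self.in_ch,))
        self._xp = None
        if not any(self.padding):
            return dxp
        crop = (slice(None),) + tuple(
            slice(p, sp - p) for p, sp in zip(self.padding, xp.shape[1:-1])
        ) + (slice(None),)
        return np.ascontiguousarray(dxp[crop])


class BatchNorm(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.n_ch = n_ch
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch, dtype=DTYPE)
        self.running_var = np.ones(n_ch, dtype=DTYPE)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(DTYPE)
        xhat = (x - mean) / std
        self._cache = (xhat, std, axes, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std, axes, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not train:
            self._cache = None
            return g / std
        m = grad.size / self.n_ch
        out = (g - g.mean(axis=axes) - xhat * (g * xhat).sum(axis=axes) / m) / std
        self._cache = None
        return out


class LeakyReLU(Module):
    trainable = False

    def __init__(self, negative_slope: float = 0.01):
        self.slope = DTYPE(negative_slope)

    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        out = np.where(self._mask, grad, self.slope * grad)
        self._mask = None
        return out


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Rate is mutable (searched)."""

    trainable = False

    def __init__(self, rate: float = 0.0, rng: np.random.Generator | None = None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class AvgPool2(Module):
    """Non-overlapping 2x stride-2 average pooling with ceil-mode padding.

    Odd spatial sizes are zero-padded on the high side; averages divide by
    the true (unpadded) element count so edge cells are unbiased.
    """

    trainable = False

    def forward(self, x, train=False):
        nd = x.ndim - 2
        spatial = x.shape[1:-1]
        pads = [(0, 0)] + [(0, s % 2) for s in spatial] + [(0, 0)]
        xp = np.pad(x, pads) if any(s % 2 for s in spatial) else x
        out_sp = tuple((s + 1) // 2 for s in spatial)
        shape = x.shape[:1] + tuple(d for s in out_sp for d in (s, 2)) + x.shape[-1:]
        blocks = xp.reshape(shape)
        sum_axes = tuple(2 + 2 * i for i in range(nd))
        sums = blocks.sum(axis=sum_axes)
        counts = np.ones(out_sp + (1,), dtype=DTYPE)
        for ax, s in enumerate(spatial):
            if s % 2:
                sl = [slice(None)] * (nd + 1)
                sl[ax] = slice(-1, None)
                counts[tuple(sl)] *= 0.5  # truncated edge cell holds half the voxels
        counts = counts * (2**nd)
        self._cache = (spatial, counts)
        return sums / counts

    def backward(self, grad):
        spatial, counts = self._cache
        g = grad / counts
        for ax in range(len(spatial)):
            g = np.repeat(g, 2, axis=1 + ax)
        crop = (slice(None),) + tuple(slice(0, s) for s in spatial) + (slice(None),)
        self._cache = None
        return np.ascontiguousarray(g[crop])


class GlobalAvgPool(Module):
    trainable = False

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=tuple(range(1, x.ndim - 1)))

    def backward(self, grad):
        shape = self._shape
        scale = DTYPE(np.prod(shape[1:-1]))
        g = grad.reshape(shape[:1] + (1,) * (len(shape) - 2) + shape[-1:])
        out = np.broadcast_to(g / scale, shape)
        self._shape = None
        return np.ascontiguousarray(out)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Param(np.zeros(out_features))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.weight.value + self.bias.value

    def backward(self, grad):
        grad = np.asarray(grad, dtype=DTYPE)
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        out = grad @ self.weight.value.T
        self._x = None
        return out


class Sequential(Module):
    def __init__(self, modules: Sequence[Module]):
        self.modules = list(modules)

    def params(self):
        return [p for m in self.modules for p in m.params()]

    def forward(self, x, train=False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, grad):
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


class DenseBlock(Module):
    """Stack of layers whose outputs are concatenated on the channel axis.

    Each inner layer maps the running concatenation to ``growth_rate`` new
    feature channels.
    """

    def __init__(self, layers: Sequence[Sequential]):
        self.layers = list(layers)

    def params(self):
        return [p for m in self.layers for p in m.params()]

    def forward(self, x, train=False):
        feats = [np.asarray(x, dtype=DTYPE)]
        for layer in self.layers:
            inp = np.concatenate(feats, axis=-1) if len(feats) > 1 else feats[0]
            feats.append(layer.forward(inp, train=train))
        self._widths = [f.shape[-1] for f in feats]
        return np.concatenate(feats, axis=-1)

    def backward(self, grad):
        widths = self._widths
        cuts = np.cumsum(widths)[:-1]
        grads = [np.ascontiguousarray(g) for g in np.split(grad, cuts, axis=-1)]
        for layer in reversed(self.layers):
            g_new = grads.pop()
            g_inp = layer.backward(g_new)
            inner_cuts = np.cumsum(widths[: len(grads)])[:-1]
            for i, piece in enumerate(np.split(g_inp, inner_cuts, axis=-1)):
                grads[i] = grads[i] + piece
        self._widths = None
        return grads[0]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z.astype(np.float64))
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: tuple[float, float]
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy; returns (loss, dL/dlogits).

    ``class_weights`` is ``(w_case, w_control)`` applied to samples of class
    1 and 0 respectively; the loss is the mean of weighted per-sample terms,
    so (0.5, 0.5) equals half the unweighted loss.
    """
    n = logits.shape[0]
    y = np.asarray(y)
    p = softmax(logits)
    w = np.where(y == 1, class_weights[0], class_weights[1])
    eps = 1e-12
    loss = float(-(w * np.log(p[np.arange(n), y] + eps)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad.astype(DTYPE)


class Adam:
    """Adam over the trainable parameters of a module list."""

    def __init__(self, modules: Sequence[Module], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.modules = list(modules)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        for mod in self.modules:
            if not mod.trainable:
                continue
            for p in mod.params():
                key = id(p)
                if key not in self._state:
                    self._state[key] = (np.zeros_like(p.value), np.zeros_like(p.value))
                m, v = self._state[key]
                m[...] = self.b1 * m + (1 - self.b1) * p.grad
                v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def zero_grad(self) -> None:
        for mod in self.modules:
            for p in mod.params():
                p.grad[...] = 0.0
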