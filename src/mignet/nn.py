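"""Minimal neural-net primitives on autograd/numpy.

The decoder is implemented functionally: parameters live in nested
dicts/lists of numpy arrays, forward passes are pure functions of
(params, inputs), and gradients come from reverse-mode ``autograd``.
This module holds the shared pieces: initializers, activations, stable
softmax, and an Adam optimizer with the PyTorch-style L2 weight decay
(decay added to the gradient before the moment updates).
"""

from __future__ import annotations

from typing import Callable

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.misc.flatten import flatten

__all__ = ["glorot", "elu", "leaky_relu", "softmax", "log_softmax", "get_activation",
           "conv1d_taps", "Adam"]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ELU as a single fused primitive: one elementwise pass forward, one backward,
# instead of the where/exp/minimum chain autograd would otherwise trace.
@primitive
def elu(x, alpha: float = 1.0):
    x = np.asarray(x)
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


defvjp(elu, lambda ans, x, alpha=1.0: lambda g: np.where(np.asarray(x) > 0, g, g * (ans + alpha)))


def _pad_time(x: np.ndarray, pad: int) -> np.ndarray:
    widths = [(0, 0)] * (x.ndim - 1) + [(pad, pad)]
    return np.pad(x, widths)


@primitive
def conv1d_taps(x, W):
    """Same-padded 1-D convolution along the last axis, fused for autograd.

    x: (..., D_in, T); W: (D_out, D_in, k) with k odd -> (..., D_out, T).
    One batched matmul per kernel tap; the whole convolution (and each of
    its VJPs) is a single node in the autograd graph.
    """
    k = W.shape[-1]
    T = x.shape[-1]
    xp = _pad_time(np.asarray(x), k // 2)
    out = np.zeros(x.shape[:-2] + (W.shape[0], T), dtype=xp.dtype)
    for tap in range(k):
        out += np.matmul(W[:, :, tap], xp[..., tap : tap + T])
    return out


def _conv1d_vjp_x(ans, x, W):
    # gradient w.r.t. the input is the same convolution with the kernel
    # transposed over channels and flipped in time
    def vjp(g):
        V = np.ascontiguousarray(np.transpose(W, (1, 0, 2))[:, :, ::-1])
        return conv1d_taps(np.asarray(g), V)

    return vjp


def _conv1d_vjp_W(ans, x, W):
    def vjp(g):
        k = W.shape[-1]
        T = x.shape[-1]
        xp = _pad_time(np.asarray(x), k // 2)
        g3 = np.reshape(np.asarray(g), (-1,) + g.shape[-2:])        # (N, D_out, T)
        x3 = np.reshape(xp, (-1,) + xp.shape[-2:])                  # (N, D_in, T+2p)
        dW = np.empty(W.shape, dtype=W.dtype)
        for tap in range(k):
            xs = np.swapaxes(x3[..., tap : tap + T], 1, 2)          # (N, T, D_in)
            dW[:, :, tap] = np.matmul(g3, xs).sum(axis=0)
        return dW

    return vjp


defvjp(conv1d_taps, _conv1d_vjp_x, _conv1d_vjp_W)


@primitive
def leaky_relu(x, slope: float = 0.2):
    x = np.asarray(x)
    return np.where(x > 0, x, slope * x)


defvjp(leaky_relu, lambda ans, x, slope=0.2: lambda g: np.where(np.asarray(x) > 0, g, slope * g))


@primitive
def attention_pool(stacked, logits):
    """Convex combination over the last axis with softmax(logits) weights.

    pooled[..., ] = sum_f softmax(logits)[..., f] * stacked[..., f].
    Fused so the training path touches the big (..., F) arrays a minimal
    number of times; use :func:`softmax` separately when the weights
    themselves are wanted.
    """
    s = _softmax_np(np.asarray(logits))
    return np.sum(s * np.asarray(stacked), axis=-1)


def _attention_pool_vjp_stacked(ans, stacked, logits):
    def vjp(g):
        s = _softmax_np(np.asarray(logits))
        return g[..., None] * s

    return vjp


def _attention_pool_vjp_logits(ans, stacked, logits):
    def vjp(g):
        s = _softmax_np(np.asarray(logits))
        return g[..., None] * s * (np.asarray(stacked) - ans[..., None])

    return vjp


defvjp(attention_pool, _attention_pool_vjp_stacked, _attention_pool_vjp_logits)


def _softmax_np(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= np.sum(z, axis=axis, keepdims=True)
    return z


def identity(x):
    return x


_ACTIVATIONS: dict[str, Callable] = {"elu": elu, "identity": identity,
                                     "relu": lambda x: anp.maximum(x, 0.0),
                                     "tanh": anp.tanh}


def get_activation(name: str) -> Callable:
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; options {sorted(_ACTIVATIONS)}") from None


@primitive
def softmax(x, axis: int = -1):
    return _softmax_np(np.asarray(x), axis=axis)


defvjp(softmax, lambda ans, x, axis=-1: lambda g: ans * (g - np.sum(g * ans, axis=axis, keepdims=True)))


def log_softmax(x, axis: int = -1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    return z - anp.log(anp.sum(anp.exp(z), axis=axis, keepdims=True))


def tree_astype(tree, dtype):
    """Cast every ndarray leaf of a nested dict/list/tuple parameter tree."""
    if isinstance(tree, dict):
        return {k: tree_astype(v, dtype) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_astype(v, dtype) for v in tree)
    return np.asarray(tree).astype(dtype)


class Adam:
    """Adam on a flattened parameter tree; ``weight_decay`` is the classic
    L2-coupled variant (added to the gradient, as in torch.optim.Adam)."""

    def __init__(self, params, lr: float = 0.01, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        flat, self._unflatten = flatten(params)
        self.theta = flat.astype(float)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = np.zeros_like(self.theta)
        self.v = np.zeros_like(self.theta)
        self.t = 0

    @property
    def params(self):
        return self._unflatten(self.theta)

    def step(self, grads) -> None:
        g, _ = flatten(grads)
        if self.weight_decay:
            g = g + self.weight_decay * self.theta
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        self.theta = self.theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)
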