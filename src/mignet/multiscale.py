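"""Multi-scale temporal-convolution frequency-feature extractor.

Three stacks of 1-D convolutions run along the time axis of each EEG
segment, with kernel sizes 3, 7 and 15 samples by default. At 160 Hz a
short kernel responds to fast (high-frequency) structure and a long kernel
to slower rhythms, so the three stacks act as learned filters over
overlapping frequency ranges. Each stack has three layers,

    H_j^l = sigma(H_j^{l-1} * W_j^l + b_j^l),

with "same" padding (time length preserved), weights shared across the 64
electrode channels (each electrode is filtered independently and
identically), and a residual connection that adds the first layer's output
to the third layer's pre-activation:

    H_j^3' = sigma(preact_3 + H_j^1).

The per-scale outputs are concatenated along the feature axis and fused by
an attention-weighted average pool: a small shared MLP maps each
(channel, time) feature vector to logits, a softmax over the *feature*
axis turns them into convex weights, and the pooled map

    X_MFF[c, t] = sum_f w[c, t, f] * X_conv[c, t, f]

keeps one number per channel and time point — the attention-selected blend
of the frequency features.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn import attention_pool, conv1d_taps, get_activation, glorot, softmax

__all__ = ["MFFConfig", "init_mff_params", "conv1d_same", "scale_branch",
           "channel_attention_pool", "mff_forward"]


@dataclass(frozen=True)
class MFFConfig:
    """Hyperparameters of the multi-scale extractor.

    ``kernel_sizes`` are taps per scale (odd, for unambiguous same-padding);
    ``depths[j][l]`` is the output depth of layer l of scale j. With the
    residual on, each scale's first and third depths must match.
    """

    kernel_sizes: tuple[int, ...] = (3, 7, 15)
    depths: tuple[tuple[int, int, int], ...] = ((3, 3, 3), (3, 3, 3), (3, 3, 3))
    activation: str = "elu"
    residual: bool = True
    attention_hidden: int = 16

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != len(self.depths):
            raise ValueError("one depth triple per kernel size required")
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel size {k} must be odd and >= 1 (same padding)")
        if self.residual:
            for d in self.depths:
                if d[0] != d[2]:
                    raise ValueError(f"residual needs matching first/third depths, got {d}")

    @property
    def n_features(self) -> int:
        """Total feature depth after concatenation (sum of last-layer depths)."""
        return sum(d[-1] for d in self.depths)


def init_mff_params(cfg: MFFConfig, rng: np.random.Generator) -> dict:
    """Glorot-uniform weights, zero biases, seeded by ``rng``."""
    scales = []
    for k, depths in zip(cfg.kernel_sizes, cfg.depths):
        layers = []
        d_in = 1  # raw signal enters with depth 1
        for d_out in depths:
            layers.append({
                "W": glorot(rng, (d_out, d_in, k), fan_in=d_in * k, fan_out=d_out * k),
                "b": np.zeros(d_out),
            })
            d_in = d_out
        scales.append(layers)
    F, H = cfg.n_features, cfg.attention_hidden
    att = {
        "W1": glorot(rng, (F, H), F, H), "b1": np.zeros(H),
        "W2": glorot(rng, (H, F), H, F), "b2": np.zeros(F),
    }
    return {"scales": scales, "attention": att}


def conv1d_same(x, W, b):
    """1-D convolution along the last axis with same padding.

    x: (..., D_in, T); W: (D_out, D_in, k); b: (D_out,) -> (..., D_out, T).
    """
    return conv1d_taps(x, W) + b[..., None]


def scale_branch(x, layers, cfg: MFFConfig, j: int):
    """One scale's 3-layer stack with the residual tap.

    x: (..., C, T) raw segment(s); returns (..., C, T, D_j3).
    """
    act = get_activation(cfg.activation)
    h = x[..., :, None, :]  # depth axis of size 1
    h1 = None
    for l, layer in enumerate(layers):
        pre = conv1d_same(h, layer["W"], layer["b"])
        if l == len(layers) - 1 and cfg.residual and h1 is not None:
            pre = pre + h1
        h = act(pre)
        if l == 0:
            h1 = h
    return anp.moveaxis(h, -2, -1)  # (..., C, T, D)


def channel_attention_pool(stacked, att_params, cfg: MFFConfig, need_weights: bool = True):
    """Attention-weighted average pool over the feature axis.

    stacked: (..., C, T, F) -> (pooled (..., C, T), weights (..., C, T, F));
    weights are a softmax over F at every (channel, time) position. With
    ``need_weights=False`` the weights are folded into a fused pooling op
    (training fast path) and ``None`` is returned in their place.
    """
    if isinstance(stacked, np.ndarray) and not np.all(np.isfinite(stacked)):
        raise ValueError("non-finite values in stacked features")
    act = get_activation(cfg.activation)
    shape = stacked.shape
    flat = anp.reshape(stacked, (-1, shape[-1]))  # one big GEMM per MLP layer
    hidden = act(anp.matmul(flat, att_params["W1"]) + att_params["b1"])
    logits = anp.reshape(anp.matmul(hidden, att_params["W2"]) + att_params["b2"], shape)
    pooled = attention_pool(stacked, logits)
    weights = softmax(logits, axis=-1) if need_weights else None
    return pooled, weights


def mff_forward(x, params, cfg: MFFConfig, need_weights: bool = True):
    """Full extractor: x (..., C, T) -> (X_MFF (..., C, T), X_conv, weights)."""
    branches = [
        scale_branch(x, layers, cfg, j) for j, layers in enumerate(params["scales"])
    ]
    x_conv = anp.concatenate(branches, axis=-1)
    pooled, weights = channel_attention_pool(x_conv, params["attention"], cfg, need_weights)
    return pooled, x_conv, weights
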