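"""Dynamic graph attention over electrode nodes.

Electrodes are graph nodes; the pooled frequency features of a segment
(one row of X_MFF per electrode) are the initial node features. A
three-layer multi-head graph attention network propagates features along
the weighted adjacency P, which starts at the inverse-distance prior E
and is refreshed every few training epochs from learned feature
similarity:

    K_uv = xi / (||G_u^3 - G_v^3||_2^delta + xi)      (similarity in (0, 1])
    P_uv = E_uv * K_uv^gamma                          (update rule)

Because 0 < K <= 1 and gamma >= 0, the update can only *shrink* prior
edges: 0 <= P <= E elementwise, and an edge absent from the distance
prior can never appear. That is the anchoring mechanism — electrode
geometry decides which connections are possible, the data decides which
survive.

Inside each attention layer, P enters as an additive log-bias on the
attention logits (equivalently, a multiplicative reweighting of the
unnormalized attention), so attention stays a proper distribution over
each node's neighborhood N(u) = {v : P_uv > 0} plus an explicit
self-loop whose bias is log(1) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from .montage import PriorAdjacency
from .nn import get_activation, glorot, leaky_relu, softmax

__all__ = ["GATConfig", "AdjacencyState", "init_gat_params", "gat_layer",
           "feature_similarity", "update_adjacency", "classify_logits", "gat_forward"]

_LOG_EPS = 1e-12


@dataclass(frozen=True)
class GATConfig:
    """Graph-attention and graph-update hyperparameters.

    gamma, delta, xi control the similarity update (defaults 1, 2, 0.5);
    the adjacency is refreshed every ``update_period`` training epochs.
    """

    n_layers: int = 3
    heads: int = 4
    hidden_dims: tuple[int, ...] = (32, 32, 32)
    gamma: float = 1.0
    delta: float = 2.0
    xi: float = 0.5
    update_period: int = 10
    leaky_slope: float = 0.2
    activation: str = "elu"

    def __post_init__(self) -> None:
        if len(self.hidden_dims) != self.n_layers:
            raise ValueError("need one hidden dim per layer")
        if min(self.heads, self.n_layers, self.update_period) < 1:
            raise ValueError("heads, n_layers, update_period must be positive")
        if self.delta <= 0 or self.xi <= 0 or self.gamma < 0:
            raise ValueError("require delta > 0, xi > 0, gamma >= 0")


@dataclass
class AdjacencyState:
    """The fixed prior E plus the current learned adjacency P."""

    prior: PriorAdjacency
    P: np.ndarray = field(default=None)  # type: ignore[assignment]
    update_count: int = 0
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.P is None:
            self.P = self.prior.E.copy()

    @property
    def E(self) -> np.ndarray:
        return self.prior.E

    def check_anchoring(self, atol: float = 1e-12) -> None:
        """Assert 0 <= P <= E, symmetry and zero diagonal; raises otherwise."""
        P, E = self.P, self.E
        if not np.allclose(P, P.T):
            raise AssertionError("P lost symmetry")
        if np.any(np.diag(P) != 0):
            raise AssertionError("P diagonal must stay 0")
        if np.any(P < -atol) or np.any(P - E > atol):
            raise AssertionError("anchoring violated: P outside [0, E]")


def init_gat_params(cfg: GATConfig, in_dim: int, n_classes: int, n_nodes: int,
                    rng: np.random.Generator) -> dict:
    """Per-layer multi-head weights plus the flatten-softmax classifier head."""
    layers = []
    d_in = in_dim
    for d_out in cfg.hidden_dims:
        layers.append({
            "W": glorot(rng, (cfg.heads, d_in, d_out), d_in, d_out),
            "a_src": glorot(rng, (cfg.heads, d_out), d_out, 1),
            "a_dst": glorot(rng, (cfg.heads, d_out), d_out, 1),
            "W_O": glorot(rng, (cfg.heads * d_out, d_out), cfg.heads * d_out, d_out),
        })
        d_in = d_out
    d_flat = n_nodes * cfg.hidden_dims[-1]
    head = {"W": glorot(rng, (d_flat, n_classes), d_flat, n_classes),
            "b": np.zeros(n_classes)}
    return {"layers": layers, "head": head}


def _attention_bias(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive bias log(P) off-diagonal, 0 on the self-loop; -inf mask elsewhere."""
    C = P.shape[0]
    eye = np.eye(C, dtype=bool)
    allowed = (P > 0) | eye
    bias = np.where(eye, 0.0, np.log(np.maximum(P, _LOG_EPS)))
    bias = np.where(allowed, bias, -np.inf)
    return bias, allowed


def gat_layer(G, P: np.ndarray, layer_params, cfg: GATConfig, return_attention: bool = False):
    """One multi-head graph attention layer.

    G: (..., C, F_in) node features; P: (C, C) current adjacency (constant
    w.r.t. gradients). Per head q the logit for edge (u, v) is
    LeakyReLU(a_src . (W^q G_u) + a_dst . (W^q G_v)) + log P_uv, softmaxed
    over v in N(u); head outputs pass sigma, are concatenated and projected
    by W_O.
    """
    act = get_activation(cfg.activation)
    bias, _ = _attention_bias(P)
    bias = bias.astype(layer_params["W"].dtype)  # keep float32 paths float32
    h = anp.matmul(G[..., None, :, :], layer_params["W"])               # (..., Q, C, D)
    e_src = anp.matmul(h, layer_params["a_src"][:, :, None])[..., 0]    # (..., Q, C)
    e_dst = anp.matmul(h, layer_params["a_dst"][:, :, None])[..., 0]
    logits = leaky_relu(e_src[..., :, None] + e_dst[..., None, :], cfg.leaky_slope)
    logits = logits + bias                                              # (..., Q, C, C)
    alpha = softmax(logits, axis=-1)
    agg = anp.matmul(alpha, h)                                          # (..., Q, C, D)
    heads_out = act(agg)                                                # sigma per head
    moved = anp.swapaxes(heads_out, -3, -2)                             # (..., C, Q, D)
    concat = anp.reshape(moved, moved.shape[:-2] + (-1,))
    out = anp.matmul(concat, layer_params["W_O"])
    if return_attention:
        return out, alpha
    return out


def gat_forward(G, P: np.ndarray, params: dict, cfg: GATConfig):
    """Stack of attention layers; returns the layer-3 node features G^3."""
    h = G
    for layer_params in params["layers"]:
        h = gat_layer(h, P, layer_params, cfg)
    return h


def classify_logits(G_final, head_params):
    """Flatten node features and map to class logits with a single linear layer."""
    flat = anp.reshape(G_final, G_final.shape[:-2] + (-1,))
    return anp.matmul(flat, head_params["W"]) + head_params["b"]


def classify(G_final, head_params):
    """Class probabilities (softmax over the linear head's logits)."""
    return softmax(classify_logits(G_final, head_params), axis=-1)


def feature_similarity(G3: np.ndarray, delta: float, xi: float) -> np.ndarray:
    """Similarity K from layer-3 node features: K_uv = xi / (||G_u - G_v||^delta + xi).

    Symmetric, K_uu = 1, values in (0, 1], strictly decreasing in distance.
    """
    if delta <= 0 or xi <= 0:
        raise ValueError("delta and xi must be positive")
    G3 = np.asarray(G3, dtype=float)
    if not np.all(np.isfinite(G3)):
        raise ValueError("non-finite node features")
    diff = G3[:, None, :] - G3[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    return xi / (dist**delta + xi)


def update_adjacency(state: AdjacencyState, G3_mean: np.ndarray, cfg: GATConfig) -> AdjacencyState:
    """Refresh P from the epoch-mean layer-3 features: P = E * K^gamma (in place).

    Appends the new P to ``state.history`` and increments ``update_count``.
    """
    if G3_mean is None:
        raise ValueError("no layer-3 feature statistics available yet (run a forward pass)")
    K = feature_similarity(G3_mean, cfg.delta, cfg.xi)
    P = state.E * K**cfg.gamma
    np.fill_diagonal(P, 0.0)
    state.P = P
    state.update_count += 1
    state.history.append(P.copy())
    state.check_anchoring()
    return state
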