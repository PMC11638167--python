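"""The full decoder: multi-scale extractor -> dynamic graph attention -> softmax.

A segment x (C x T) is filtered by the multi-scale temporal-convolution
module into pooled frequency features X_MFF (C x T); each electrode's row
becomes the initial feature vector of its graph node; three multi-head
graph attention layers propagate features along the current adjacency P;
the final node features are flattened into a single linear softmax head
over the four imagery classes.

The model object owns the parameter tree and the adjacency state; forward
passes are pure functions of (params, x, P) so that autograd can
differentiate the training loss end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np

from . import graph as G
from . import multiscale as M
from .montage import MontageLayout, PriorAdjacency, build_prior_adjacency
from .nn import log_softmax, softmax

__all__ = ["ModelConfig", "MotorImageryDecoder"]


@dataclass(frozen=True)
class ModelConfig:
    """Everything that defines the architecture for a C x T input."""

    n_channels: int = 64
    n_times: int = 160
    n_classes: int = 4
    mff: M.MFFConfig = field(default_factory=M.MFFConfig)
    gat: G.GATConfig = field(default_factory=G.GATConfig)


class MotorImageryDecoder:
    """Parameter container + forward passes for the EEG graph decoder."""

    def __init__(self, layout: MontageLayout, config: ModelConfig | None = None,
                 seed: int = 0, prior: PriorAdjacency | None = None,
                 dtype: np.dtype | type = np.float64):
        self.layout = layout
        self.config = config or ModelConfig(n_channels=layout.n_channels)
        if layout.n_channels != self.config.n_channels:
            raise ValueError("montage channel count does not match model config")
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params = {
            "mff": M.init_mff_params(self.config.mff, rng),
            "gat": G.init_gat_params(self.config.gat, in_dim=self.config.n_times,
                                     n_classes=self.config.n_classes,
                                     n_nodes=self.config.n_channels, rng=rng),
        }
        if self.dtype != np.float64:  # single precision roughly halves CPU training time
            from .nn import tree_astype

            self.params = tree_astype(self.params, self.dtype)
        self.adjacency = G.AdjacencyState(prior=prior or build_prior_adjacency(layout))

    # -- functional forward passes -------------------------------------------------

    def forward(self, params, x, P=None, return_stages: bool = False):
        """Class logits for x of shape (..., C, T); optionally intermediate stages."""
        P = self.adjacency.P if P is None else P
        if isinstance(x, np.ndarray) and x.dtype != self.dtype:
            x = x.astype(self.dtype)
        x_mff, x_conv, att = M.mff_forward(x, params["mff"], self.config.mff,
                                           need_weights=return_stages)
        g3 = G.gat_forward(x_mff, P, params["gat"], self.config.gat)
        logits = G.classify_logits(g3, params["gat"]["head"])
        if return_stages:
            return logits, {"x_mff": x_mff, "x_conv": x_conv, "attention": att, "g3": g3}
        return logits

    def loss(self, params, x, y, P=None):
        """Mean cross-entropy of a labeled batch."""
        logp = log_softmax(self.forward(params, x, P), axis=-1)
        return -anp.mean(logp[anp.arange(len(y)), y])

    # -- convenience inference -----------------------------------------------------

    def predict_proba(self, x) -> np.ndarray:
        return np.asarray(softmax(self.forward(self.params, np.asarray(x)), axis=-1))

    def predict(self, x) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=-1)

    def stage_features(self, x, stage: str) -> np.ndarray:
        """Flattened per-segment features after the named stage.

        ``stage`` is "multiscale" (pooled X_MFF maps) or "graph" (layer-3
        node features).
        """
        _, stages = self.forward(self.params, np.asarray(x), return_stages=True)
        key = {"multiscale": "x_mff", "graph": "g3"}.get(stage)
        if key is None:
            raise ValueError(f"unknown stage {stage!r}; expected 'multiscale' or 'graph'")
        feats = np.asarray(stages[key])
        return feats.reshape(feats.shape[0], -1)

    # -- checkpointing ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config repr + parameters + adjacency state."""
        from autograd.misc.flatten import flatten

        flat, _ = flatten(self.params)
        np.savez_compressed(
            path, theta=flat, P=self.adjacency.P, E=self.adjacency.E,
            update_count=self.adjacency.update_count,
            history=np.asarray(self.adjacency.history) if self.adjacency.history
            else np.zeros((0,) + self.adjacency.P.shape),
            config=np.array(repr(self.config)),
        )

    def load_params(self, path: str | Path) -> None:
        from autograd.misc.flatten import flatten

        with np.load(path, allow_pickle=False) as z:
            flat, unflatten = flatten(self.params)
            if z["theta"].shape != flat.shape:
                raise ValueError("checkpoint parameter count does not match this model")
            self.params = unflatten(z["theta"])
            self.adjacency.P = z["P"]
            self.adjacency.update_count = int(z["update_count"])
            self.adjacency.history = [h.copy() for h in z["history"]]
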