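"""Interpretability exports: t-SNE of stage features, adjacency snapshots.

Two questions these outputs answer:

* does each processing stage increase class separability? — t-SNE embeds
  the flattened features after the multi-scale stage and after the graph
  stage into 2-D for plotting, and a silhouette score computed on the
  high-dimensional features gives the quantitative counterpart;
* which electrode connections survive training? — adjacency snapshots
  taken at each update are exported as CSV matrices plus BrainNet-Viewer
  ``.node`` / ``.edge`` text files, thresholded at a percentile so discrete
  edges can be drawn on a scalp template.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .data import EEGSegment, segments_to_arrays
from .model import MotorImageryDecoder
from .montage import MontageLayout

__all__ = ["tsne_features", "stage_silhouette", "export_adjacency_series",
           "export_adjacency_snapshot"]

STAGES = ("multiscale", "graph")


@dataclass(frozen=True)
class TSNEResult:
    embedding: np.ndarray  # (N, 2)
    labels: np.ndarray     # (N,)
    silhouette: float      # on the high-dimensional stage features
    stage: str


def _stage_matrix(model: MotorImageryDecoder, segments: Sequence[EEGSegment],
                  stage: str, batch_size: int = 128) -> tuple[np.ndarray, np.ndarray]:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    arrays = segments_to_arrays(segments)
    X, y = arrays["data"], arrays["labels"]
    feats = [model.stage_features(X[i : i + batch_size], stage)
             for i in range(0, len(X), batch_size)]
    return np.concatenate(feats), y


def stage_silhouette(model: MotorImageryDecoder, segments: Sequence[EEGSegment],
                     stage: str) -> float:
    """Silhouette score of class labels on the named stage's features."""
    F, y = _stage_matrix(model, segments, stage)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes for a silhouette score")
    return float(silhouette_score(F, y))


def tsne_features(model: MotorImageryDecoder, segments: Sequence[EEGSegment],
                  stage: str, seed: int = 0, perplexity: float = 30.0) -> TSNEResult:
    """2-D t-SNE embedding of stage features, plus their silhouette score."""
    F, y = _stage_matrix(model, segments, stage)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes present")
    perplexity = min(perplexity, (len(F) - 1) / 3)  # t-SNE constraint for small N
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(F)
    sil = float(silhouette_score(F, y))
    return TSNEResult(embedding=emb, labels=y, silhouette=sil, stage=stage)


def export_adjacency_snapshot(P: np.ndarray, layout: MontageLayout, out_stem: Path,
                              threshold_pct: float = 90.0) -> list[Path]:
    """Write one adjacency snapshot as CSV + BrainNet ``.node``/``.edge`` files.

    Edges at or below the given percentile of the *positive* weights are
    zeroed in the ``.edge`` file (100 -> empty edge set); node size/color
    encode the electrode's total connection strength.
    """
    P = np.asarray(P, dtype=float)
    out_stem.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out_stem.with_suffix(".csv")
    np.savetxt(csv_path, P, delimiter=",", fmt="%.6g",
               header=",".join(layout.names), comments="")
    pos = P[P > 0]
    if pos.size:
        cut = np.percentile(pos, threshold_pct)
        edges = np.where(P > cut, P, 0.0)
    else:
        edges = np.zeros_like(P)
    strength = P.sum(axis=1)
    node_path = out_stem.with_suffix(".node")
    with node_path.open("w") as fh:
        for name, (x, y, z), s in zip(layout.names, layout.coords, strength):
            fh.write(f"{x:.4f}\t{y:.4f}\t{z:.4f}\t{s:.4f}\t{s:.4f}\t{name}\n")
    edge_path = out_stem.with_suffix(".edge")
    np.savetxt(edge_path, edges, delimiter="\t", fmt="%.6g")
    return [csv_path, node_path, edge_path]


def export_adjacency_series(history: Sequence[np.ndarray], layout: MontageLayout,
                            indices: Sequence[int], out_dir: str | Path,
                            threshold_pct: float = 90.0) -> list[Path]:
    """Export the snapshots for the given 1-based update indices.

    ``history[i-1]`` is the adjacency after the i-th update; a typical call
    requests updates (3, 9, 15, 21, 27, 33) from a long training run.
    """
    if len(history) == 0:
        raise ValueError("empty adjacency history")
    out_dir = Path(out_dir)
    written: list[Path] = []
    for i in indices:
        if not 1 <= i <= len(history):
            raise IndexError(f"update index {i} outside history of length {len(history)}")
        written.extend(
            export_adjacency_snapshot(history[i - 1], layout,
                                      out_dir / f"adjacency_update_{i:03d}",
                                      threshold_pct)
        )
    return written
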