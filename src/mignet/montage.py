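"""Electrode geometry and the distance-based adjacency prior.

The decoder treats the 64 scalp electrodes of the international 10-10
system as graph nodes. Spatial prior knowledge enters through a weighted
adjacency matrix ``E`` whose entries are inverse Euclidean distances
between electrode positions,

    E_uv = 1 / dist(u, v)   (u != v),   E_uu = 0,

rescaled so the largest off-diagonal entry is 1. Nearby electrodes —
which record overlapping cortical sources — therefore start strongly
connected, and the graph-update layer can only shrink these weights,
never invent connections between distant sites.

The packaged montage is an idealized unit-sphere realisation of the
10-10 layout in the 64-channel PhysioNet order; only relative distances
matter for ``E``, so the sphere radius is arbitrary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MontageLayout",
    "PriorAdjacency",
    "load_builtin_montage",
    "load_montage_tsv",
    "build_prior_adjacency",
]

_BUILTIN_RESOURCE = "standard_1010_64.tsv"


@dataclass(frozen=True)
class MontageLayout:
    """Named electrode positions in 3-D head space.

    The row order of ``coords`` is the canonical node order used by every
    other module (data arrays, adjacency matrices, exported files).
    """

    names: tuple[str, ...]
    coords: np.ndarray  # (C, 3)
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (C, 3), got {coords.shape}")
        if len(self.names) != coords.shape[0]:
            raise ValueError("names and coords length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("electrode names must be unique")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Node index of an electrode label (case-insensitive)."""
        key = name.upper()
        if key not in self._index:
            raise KeyError(f"unknown electrode {name!r}")
        return self._index[key]

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance between two named electrodes."""
        return float(np.linalg.norm(self.coords[self.index(a)] - self.coords[self.index(b)]))

    def pairwise_distances(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(-1))


@dataclass(frozen=True)
class PriorAdjacency:
    """Distance prior E: symmetric, zero diagonal, max off-diagonal 1."""

    E: np.ndarray  # (C, C)

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        if E.ndim != 2 or E.shape[0] != E.shape[1]:
            raise ValueError("E must be square")
        object.__setattr__(self, "E", E)

    @property
    def n_channels(self) -> int:
        return self.E.shape[0]


def load_montage_tsv(path: str | Path) -> MontageLayout:
    """Read a montage from a ``name\\tx\\ty\\tz`` TSV file (header row required)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[0].strip().lower() != "name":
        raise ValueError(f"{path}: expected header 'name\\tx\\ty\\tz'")
    names, rows = [], []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}: malformed row {ln!r}")
        names.append(parts[0].strip().upper())
        rows.append([float(v) for v in parts[1:]])
    return MontageLayout(names=tuple(names), coords=np.array(rows))


def load_builtin_montage(n_channels: int = 64) -> MontageLayout:
    """The packaged 64-channel 10-10 montage in PhysioNet channel order.

    Only the 64-channel layout ships with the package; other channel counts
    must be supplied as a custom TSV via :func:`load_montage_tsv`.
    """
    if n_channels != 64:
        raise ValueError(
            f"no built-in montage with {n_channels} channels; "
            "only the 64-channel 10-10 layout is packaged "
            "(use load_montage_tsv for custom layouts)"
        )
    ref = importlib.resources.files("mignet.resources") / _BUILTIN_RESOURCE
    with importlib.resources.as_file(ref) as p:
        return load_montage_tsv(p)


def build_prior_adjacency(layout: MontageLayout) -> PriorAdjacency:
    """Inverse-distance adjacency prior, normalized to max off-diagonal 1.

    Raises if any two electrodes coincide (the inverse distance would be
    infinite), naming the offending pair.
    """
    dist = layout.pairwise_distances()
    C = layout.n_channels
    off = ~np.eye(C, dtype=bool)
    zero = np.argwhere((dist == 0) & off)
    if zero.size:
        u, v = zero[0]
        raise ValueError(
            f"electrodes {layout.names[u]!r} and {layout.names[v]!r} share "
            "identical coordinates (distance 0)"
        )
    E = np.zeros((C, C))
    E[off] = 1.0 / dist[off]
    E /= E.max()
    return PriorAdjacency(E=E)
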