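"""Gene-interaction networks from distance maps, and their temporal
(multilayer) extension.

A distance matrix ``X`` maps to a weighted adjacency matrix by
exponential decay below a hard proximity threshold::

    A_ij = exp(-s * X_ij)   if X_ij < d*
         = 0                otherwise

so an edge exists only between beads closer than ``d_star`` and its weight
decreases with distance at rate ``s_decay`` (1/nm).  A temporal network is
the sequence of adjacencies built from *time-averaged* distance maps over
non-overlapping windows of ``delta`` frames: the averaging happens on
distances first, then the nonlinearity is applied (the two orders differ
in general).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .distance_maps import DistanceMap
from .polymer import Trajectory

__all__ = [
    "TemporalNetwork",
    "adjacency_from_distances",
    "build_temporal_network",
    "export_edge_lists",
    "temporal_network_from_distance_csvs",
]

DEFAULT_D_STAR = 325.0  # nm; community-detection threshold


@dataclass
class TemporalNetwork:
    """A sequence of weighted symmetric adjacency layers.

    ``layers`` has shape (T, N, N); layer ``s`` covers the frame window
    ``tau_s = [s*delta, (s+1)*delta)`` of width ``delta`` frames
    (``window_seconds`` seconds of trajectory time).
    """

    layers: np.ndarray
    delta: int
    d_star: float
    s_decay: float
    window_seconds: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.layers, dtype=float)
        if a.ndim != 3 or a.shape[1] != a.shape[2]:
            raise ValueError("layers must be a (T, N, N) array")
        self.layers = a

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]

    def window_frames(self, s: int) -> range:
        return range(s * self.delta, (s + 1) * self.delta)


def adjacency_from_distances(dmap, d_star: float,
                             s_decay: float | None = None) -> np.ndarray:
    """Exponential-decay adjacency of a distance matrix.

    ``s_decay`` defaults to ``1/d_star``.  The diagonal is zero and the
    boundary case ``X_ij == d_star`` carries no edge.
    """
    if d_star <= 0:
        raise ValueError("d_star must be positive")
    if s_decay is None:
        s_decay = 1.0 / d_star
    if s_decay < 0:
        raise ValueError("s_decay must be non-negative")
    X = dmap.matrix if isinstance(dmap, DistanceMap) else np.asarray(dmap, dtype=float)
    A = np.where(X < d_star, np.exp(-s_decay * X), 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def build_temporal_network(trajectory: Trajectory, delta: int = 10,
                           d_star: float = DEFAULT_D_STAR,
                           s_decay: float | None = None,
                           n_windows: int | None = None,
                           nucleolar_only: bool = True,
                           start_frame: int = 0) -> TemporalNetwork:
    """Build layered adjacencies from a trajectory.

    Frames from ``start_frame`` on are cut into non-overlapping windows of
    ``delta`` frames; each layer applies the decay map to the window's
    time-averaged distance map.  The layer count is
    ``floor(available_frames / delta)`` capped at ``n_windows``.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if s_decay is None:
        s_decay = 1.0 / d_star
    pos = trajectory.positions[start_frame:]
    if nucleolar_only:
        pos = pos[:, trajectory.topology.nucleolar_mask, :]
    total = pos.shape[0] // delta
    if n_windows is not None:
        total = min(total, n_windows)
    if total < 1:
        raise ValueError("trajectory too short for a single window")
    n = pos.shape[1]
    layers = np.empty((total, n, n))
    for s in range(total):
        window = pos[s * delta : (s + 1) * delta]
        acc = np.zeros(n * (n - 1) // 2)
        for frame in window:
            acc += pdist(frame)
        Y = squareform(acc / delta)
        layers[s] = adjacency_from_distances(Y, d_star, s_decay)
    return TemporalNetwork(
        layers, delta=delta, d_star=d_star, s_decay=s_decay,
        window_seconds=delta * trajectory.params.save_interval,
        meta={"start_frame": start_frame, "nucleolar_only": nucleolar_only},
    )


def export_edge_lists(network: TemporalNetwork, path) -> None:
    """Write all layers as a TSV edge list (i, j, weight, layer)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\tlayer\n")
        for s in range(network.n_layers):
            ii, jj = np.nonzero(np.triu(network.layers[s], k=1))
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\t{network.layers[s][i, j]:.6g}\t{s}\n")


def temporal_network_from_distance_csvs(paths, d_star: float = DEFAULT_D_STAR,
                                        s_decay: float | None = None,
                                        window_seconds: float = 1.0) -> TemporalNetwork:
    """Build a temporal network from externally supplied distance matrices
    (one CSV per time window), e.g. maps derived from real Hi-C data."""
    if s_decay is None:
        s_decay = 1.0 / d_star
    mats = [np.loadtxt(p, delimiter=",") for p in paths]
    if not mats:
        raise ValueError("no distance matrices supplied")
    layers = np.stack([adjacency_from_distances(m, d_star, s_decay)
                       for m in mats])
    return TemporalNetwork(layers, delta=1, d_star=d_star, s_decay=s_decay,
                           window_seconds=window_seconds,
                           meta={"source": "imported"})
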