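"""Pairwise bead-bead distance maps: the Hi-C analogue.

Three map kinds are defined on a trajectory's saved frames:

* instantaneous ``X(t)`` — Euclidean distances at one frame,
* time-averaged ``Y(tau) = (1/|tau|) sum_{t in tau} X(t)``,
* population-averaged ``Z(t)`` — entrywise mean of ``X(t)`` over replicate
  simulations with different initial conditions.

All maps are symmetric with zero diagonal; averages are convex
combinations of metrics and so remain metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .polymer import Trajectory

__all__ = [
    "DistanceMap",
    "instantaneous_map",
    "time_averaged_map",
    "population_averaged_map",
    "pairwise_distances",
    "histogram_modes",
    "lowest_distance_mode",
    "export_heatmap_png",
]


@dataclass
class DistanceMap:
    """A symmetric N x N matrix of (possibly averaged) distances in nm."""

    matrix: np.ndarray
    kind: str                 # "instantaneous" | "time_averaged" | "population_averaged"
    time_ref: object = None   # frame index, time, or window description
    n_sources: int = 1        # number of averaged frames / simulations

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance map must be square")
        self.matrix = m

    @property
    def n_beads(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances as a flat vector (scipy ordering)."""
        return squareform(self.matrix, checks=False)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",", fmt="%.3f")


def _frame_positions(trajectory: Trajectory, t: float,
                     nucleolar_only: bool) -> np.ndarray:
    idx = trajectory.frame_index(t)
    pos = trajectory.positions[idx]
    if nucleolar_only:
        pos = pos[trajectory.topology.nucleolar_mask]
    return pos


def instantaneous_map(trajectory: Trajectory, t: float,
                      nucleolar_only: bool = False) -> DistanceMap:
    """Pairwise Euclidean distances at saved time ``t`` (X(t))."""
    pos = _frame_positions(trajectory, t, nucleolar_only)
    mat = squareform(pdist(pos))
    return DistanceMap(mat, "instantaneous", time_ref=t)


def time_averaged_map(trajectory: Trajectory, window,
                      nucleolar_only: bool = False) -> DistanceMap:
    """Entrywise mean of instantaneous maps over the saved times in
    ``window`` (Y(tau))."""
    window = list(window)
    if not window:
        raise ValueError("window must contain at least one saved time")
    acc = None
    for t in window:
        pos = _frame_positions(trajectory, t, nucleolar_only)
        d = pdist(pos)
        acc = d if acc is None else acc + d
    mat = squareform(acc / len(window))
    return DistanceMap(mat, "time_averaged", time_ref=(window[0], window[-1]),
                       n_sources=len(window))


def population_averaged_map(trajectories, t: float,
                            nucleolar_only: bool = False) -> DistanceMap:
    """Entrywise mean of X(t) across replicate simulations (Z(t))."""
    trajectories = list(trajectories)
    if len(trajectories) < 1:
        raise ValueError("need at least one trajectory")
    ref = trajectories[0].topology
    acc = None
    for traj in trajectories:
        topo = traj.topology
        if topo.n_beads != ref.n_beads or not np.array_equal(
                topo.nucleolar_mask, ref.nucleolar_mask):
            raise ValueError("trajectories have mismatched topologies")
        if traj.n_frames != trajectories[0].n_frames or not np.allclose(
                traj.times, trajectories[0].times):
            raise ValueError("trajectories have mismatched time grids")
        pos = _frame_positions(traj, t, nucleolar_only)
        d = pdist(pos)
        acc = d if acc is None else acc + d
    mat = squareform(acc / len(trajectories))
    return DistanceMap(mat, "population_averaged", time_ref=t,
                       n_sources=len(trajectories))


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    """Condensed pairwise distances of one (N, 3) coordinate set."""
    return pdist(np.asarray(positions, dtype=float))


# ---------------------------------------------------------------------------
# Histogram analysis (multimodality signals clustering)
# ---------------------------------------------------------------------------

def histogram_modes(distances, bin_width: float = 10.0,
                    d_max: float = 2000.0, smooth: int = 3,
                    prominence_frac: float = 0.0):
    """Locate the modes of a pairwise-distance histogram.

    Distances are binned in fixed ``bin_width`` nm bins on [0, d_max]; the
    counts are smoothed with a ``smooth``-bin moving average, and modes are
    the bin centers of the local maxima of the smoothed counts.  With a
    positive ``prominence_frac`` only maxima whose prominence reaches that
    fraction of the tallest smoothed peak are reported — the stricter
    definition used when *counting* modes (multimodality tests), where
    sampling ripples must not register.  Returns mode centers ascending.
    """
    from scipy.signal import find_peaks

    d = np.ravel(np.asarray(distances, dtype=float))
    d = d[d > 0]
    if d.size == 0:
        return np.empty(0)
    edges = np.arange(0.0, d_max + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    kernel = np.ones(smooth) / smooth
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    if smoothed.max() <= 0:
        return np.empty(0)
    # pad so a peak in the very first interior bin is detectable
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    if prominence_frac > 0:
        # a counted mode must also rise above Poisson sampling ripples
        noise_floor = 5.0 * math.sqrt(max(smoothed[smoothed > 0].mean(), 1.0))
        prominence = max(prominence_frac * smoothed.max(), noise_floor)
    else:
        prominence = None
    peaks, _ = find_peaks(padded, prominence=prominence)
    centers = edges[:-1] + bin_width / 2.0
    return centers[peaks - 1]


N_MODE_PROMINENCE = 0.10  # prominence fraction for counting modes


def count_histogram_modes(distances, **kwargs) -> int:
    """Number of well-separated modes (prominence-filtered); the
    multimodality signal used to detect clustering."""
    kwargs.setdefault("prominence_frac", N_MODE_PROMINENCE)
    return int(len(histogram_modes(distances, **kwargs)))


def lowest_distance_mode(distances, **kwargs) -> float:
    """Center (nm) of the lowest-distance local maximum of the pairwise
    distance histogram; the Fig-5-style intra-cluster peak."""
    modes = histogram_modes(distances, **kwargs)
    if modes.size == 0:
        raise ValueError("no histogram mode found")
    return float(modes[0])


def export_heatmap_png(dmap: DistanceMap, path, cmap: str = "viridis") -> None:
    """Write a distance-map heatmap image (bead x bead, nm color scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.0), constrained_layout=True)
    im = ax.imshow(dmap.matrix, cmap=cmap, origin="lower")
    fig.colorbar(im, ax=ax, label="distance (nm)")
    ax.set_xlabel("bead")
    ax.set_ylabel("bead")
    ax.set_title(f"{dmap.kind} map")
    fig.savefig(path, dpi=150)
    plt.close(fig)
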