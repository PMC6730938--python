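"""Gene-mixing statistics at the bead and community level.

Both levels reduce to one boolean pair-time engine: a pair of beads
carries a boolean series over frames (bead level: pairwise distance below
``d_star``, default 100 nm, at the 0.1 s frame resolution) or over layers
(community level: shared community label, at the window resolution).  From
the maximal true-runs (interactions) and the gaps between consecutive runs
(waits) four summary statistics follow:

* interaction fraction — unique pairs that interact at least once,
* mean interaction number — simultaneous partners per bead, averaged over
  beads and time (community level: co-members per bead),
* mean waiting time — mean gap between consecutive interactions of a pair,
* mean interaction duration — mean length of an interaction run.

Leading and trailing gaps are censored (the preceding or following
interaction was not observed) and excluded from waiting times; pairs that
never interact contribute no waiting time.  Gaps are pooled across pairs
by default (switchable to per-pair means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .communities import PartitionAssignment
from .polymer import Trajectory

__all__ = [
    "InteractionSeries",
    "IntervalData",
    "MixingSummary",
    "ClusterStats",
    "pair_interaction_intervals",
    "interaction_series_matrix",
    "comembership_series_matrix",
    "mixing_summary",
    "cluster_lifetimes",
    "persistence_probability",
]

D_STAR_MIXING = 100.0  # nm


@dataclass
class InteractionSeries:
    """Boolean interaction record of one bead pair."""

    pair: tuple
    series: np.ndarray
    source: str = "distance"   # "distance" | "community"
    step_seconds: float = 0.1

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=bool)
        if self.series.ndim != 1 or self.series.size == 0:
            raise ValueError("series must be a non-empty 1-D boolean array")


@dataclass
class IntervalData:
    """Run/gap decomposition of a boolean series (indices are [start, end)
    half-open frame ranges)."""

    runs: list
    gaps: list                 # interior gaps only
    lead_gap: tuple | None     # censored gap before the first run
    trail_gap: tuple | None    # censored gap after the last run

    def run_lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.runs], dtype=float)

    def gap_lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.gaps], dtype=float)


def pair_interaction_intervals(series) -> IntervalData:
    """Decompose a boolean series into maximal true-runs and the gaps
    between consecutive runs; censored end-gaps are reported separately."""
    if isinstance(series, InteractionSeries):
        series = series.series
    x = np.asarray(series, dtype=bool)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D boolean array")
    padded = np.concatenate([[False], x, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = list(zip(starts.tolist(), ends.tolist()))
    gaps = [(runs[k][1], runs[k + 1][0]) for k in range(len(runs) - 1)]
    lead = trail = None
    if runs:
        if runs[0][0] > 0:
            lead = (0, runs[0][0])
        if runs[-1][1] < x.size:
            trail = (runs[-1][1], x.size)
    elif x.size:
        lead = (0, x.size)
    return IntervalData(runs=runs, gaps=gaps, lead_gap=lead, trail_gap=trail)


# ---------------------------------------------------------------------------
# Boolean pair-time matrices
# ---------------------------------------------------------------------------

def interaction_series_matrix(trajectory: Trajectory,
                              d_star: float = D_STAR_MIXING,
                              start_frame: int = 0) -> tuple:
    """Bead-level (n_pairs, n_frames) boolean matrix of sub-``d_star``
    proximity over all unordered nucleolar pairs, plus the frame step in
    seconds.  Pair order follows scipy's condensed convention."""
    pos = trajectory.nucleolar_positions[start_frame:]
    T, n = pos.shape[:2]
    if n < 2:
        raise ValueError("need at least 2 nucleolar beads")
    out = np.empty((n * (n - 1) // 2, T), dtype=bool)
    for t in range(T):
        out[:, t] = pdist(pos[t]) < d_star
    return out, trajectory.params.save_interval


def comembership_series_matrix(assignment: PartitionAssignment) -> np.ndarray:
    """Community-level (n_pairs, n_layers) boolean co-membership matrix
    over all unordered bead pairs (condensed pair order)."""
    labels = assignment.labels
    n, T = labels.shape
    if n < 2:
        raise ValueError("need at least 2 beads")
    iu, ju = np.triu_indices(n, k=1)
    return labels[iu, :] == labels[ju, :]


# ---------------------------------------------------------------------------
# The four summary statistics
# ---------------------------------------------------------------------------

@dataclass
class MixingSummary:
    interaction_fraction: float
    mean_interaction_number: float
    mean_waiting_time: float       # seconds; NaN when no uncensored gap exists
    mean_interaction_duration: float  # seconds; NaN when no run exists
    level: str                     # "bead" | "community"
    n_pairs: int = 0
    step_seconds: float = 0.1
    meta: dict = field(default_factory=dict)


def _summarize(bool_matrix: np.ndarray, step_seconds: float, level: str,
               n_beads: int, pooled: bool = True,
               meta: dict | None = None) -> MixingSummary:
    P, T = bool_matrix.shape
    ever = bool_matrix.any(axis=1)
    fraction = float(ever.mean())
    # simultaneous partners per bead = 2 * interacting pairs / n_beads
    mean_number = float(2.0 * bool_matrix.sum() / (n_beads * T))
    durations = []
    waits = []
    for p in np.flatnonzero(ever):
        iv = pair_interaction_intervals(bool_matrix[p])
        durations.append(iv.run_lengths())
        g = iv.gap_lengths()
        if g.size:
            waits.append(g if pooled else np.array([g.mean()]))
    dur_all = np.concatenate(durations) if durations else np.empty(0)
    wait_all = np.concatenate(waits) if waits else np.empty(0)
    if not pooled and durations:
        dur_all = np.array([d.mean() for d in durations])
    return MixingSummary(
        interaction_fraction=fraction,
        mean_interaction_number=mean_number,
        mean_waiting_time=float(wait_all.mean() * step_seconds)
        if wait_all.size else float("nan"),
        mean_interaction_duration=float(dur_all.mean() * step_seconds)
        if dur_all.size else float("nan"),
        level=level, n_pairs=P, step_seconds=step_seconds,
        meta=meta or {},
    )


def mixing_summary(source, level: str = "bead",
                   d_star: float = D_STAR_MIXING,
                   start_frame: int = 0, pooled: bool = True) -> MixingSummary:
    """The four mixing statistics of a trajectory (bead level) or a
    community assignment (community level).

    Bead level operates at the frame resolution on sub-``d_star``
    proximity of nucleolar pairs; community level at the layer resolution
    on co-membership (the "cross-communication" statistics).
    """
    if level == "bead":
        if not isinstance(source, Trajectory):
            raise TypeError("bead-level mixing needs a Trajectory")
        mat, step = interaction_series_matrix(source, d_star, start_frame)
        n = int(source.topology.nucleolar_mask.sum())
        return _summarize(mat, step, "bead", n, pooled,
                          meta={"d_star": d_star, "start_frame": start_frame})
    if level == "community":
        if not isinstance(source, PartitionAssignment):
            raise TypeError("community-level mixing needs a PartitionAssignment")
        mat = comembership_series_matrix(source)
        step = float(source.meta.get("window_seconds", 1.0))
        return _summarize(mat, step, "community", source.n_beads, pooled,
                          meta={"window_seconds": step})
    raise ValueError("level must be 'bead' or 'community'")


# ---------------------------------------------------------------------------
# Cluster lifetime / persistence analysis
# ---------------------------------------------------------------------------

@dataclass
class ClusterStats:
    """Per-community lifetime, mean size and persistence."""

    table: pd.DataFrame
    window_seconds: float

    def __len__(self):
        return len(self.table)


def cluster_lifetimes(assignment: PartitionAssignment,
                      window_seconds: float | None = None) -> ClusterStats:
    """Lifetime and time-averaged size of every community label.

    Lifetime spans first to last populated layer inclusive (in seconds);
    mean size averages the member count over the populated layers only.
    """
    if window_seconds is None:
        window_seconds = float(assignment.meta.get("window_seconds", 1.0))
    labels = assignment.labels
    N, T = labels.shape
    rows = []
    for c in assignment.community_ids:
        present = labels == c
        per_layer = present.sum(axis=0)
        populated = np.flatnonzero(per_layer > 0)
        lifetime = (populated[-1] - populated[0] + 1) * window_seconds
        mean_size = float(per_layer[populated].mean())
        rows.append({"label": int(c), "lifetime_s": float(lifetime),
                     "mean_size": mean_size,
                     "n_layers_present": int(populated.size)})
    return ClusterStats(pd.DataFrame(rows), window_seconds)


def persistence_probability(assignment: PartitionAssignment) -> pd.DataFrame:
    """Per-community probability that a member bead keeps its label in the
    next layer, pooled over all layer transitions."""
    labels = assignment.labels
    N, T = labels.shape
    if T < 2:
        raise ValueError("persistence needs at least 2 layers")
    stats: dict = {}
    for s in range(T - 1):
        for c in np.unique(labels[:, s]):
            members = labels[:, s] == c
            stay = int(np.sum(labels[members, s + 1] == c))
            tot, kept, sizes = stats.get(c, (0, 0, []))
            sizes.append(int(members.sum()))
            stats[c] = (tot + int(members.sum()), kept + stay, sizes)
    rows = [{"label": int(c), "persistence": kept / tot,
             "mean_size": float(np.mean(sizes))}
            for c, (tot, kept, sizes) in sorted(stats.items())]
    return pd.DataFrame(rows)
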