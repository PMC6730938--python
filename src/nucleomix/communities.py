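"""Multilayer-modularity community detection for temporal networks.

Given layered adjacencies ``A^s`` the multilayer modularity of a labeling
``c_is`` (node i, layer s) is

    Q = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma * k_is k_js / 2m_s) d(s,r)
                               + omega * d(i,j) * C_sr ] * d(c_is, c_jr)

with intralayer strengths ``k_is``, layer weight ``2m_s``, resolution
``gamma``, interlayer coupling ``omega`` between consecutive layers
(``C_sr = 1`` iff ``|s - r| = 1``) and normalization
``2mu = sum_is (k_is + omega * sum_r C_sr)``.  The normalization symbol of
the quality function is housed as ``mu_norm`` here because the simulator
already uses ``mu`` for the crosslink timescale; with ``omega = 0`` and one
layer Q reduces to the standard single-layer (resolution-gamma) modularity.

Optimization is a Louvain scheme over node-layer pairs: greedy local moves
(accepted only for positive gain, computed incrementally) followed by
graph aggregation, repeated until no gain remains.  Interlayer coupling is
folded into the move graph as edges of weight ``omega`` between copies of
a bead in consecutive layers, while the null-model term tracks intralayer
strengths per layer, so aggregated super-nodes carry per-layer strength
vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import TemporalNetwork

__all__ = [
    "ModularityParams",
    "PartitionAssignment",
    "multilayer_modularity_score",
    "optimize_louvain",
    "single_layer_partition",
    "parameter_sweep",
    "export_labels_tsv",
    "render_snapshot_png",
]

_EPS_GAIN = 1e-12


@dataclass
class ModularityParams:
    """Resolution and interlayer-coupling knobs of the quality function."""

    gamma: float = 10.0
    omega: float = 1.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")


@dataclass
class PartitionAssignment:
    """Community label for every (bead, layer) pair plus provenance.

    ``labels`` has shape (N, T) with positive integer labels; a label
    shared across layers denotes the same temporal community (identity is
    inherited directly from the interlayer coupling during optimization).
    """

    labels: np.ndarray
    params: ModularityParams
    Q: float
    strengths: np.ndarray | None = None   # k_is, shape (N, T)
    layer_weights: np.ndarray | None = None  # 2m_s, shape (T,)
    mu_norm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be (n_beads, n_layers)")

    @property
    def n_beads(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]

    @property
    def community_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_communities(self) -> int:
        return self.community_ids.size


# ---------------------------------------------------------------------------
# Direct evaluation of the quality function
# ---------------------------------------------------------------------------

def _layer_quantities(layers: np.ndarray):
    k = layers.sum(axis=2)            # (T, N) strengths
    two_m = k.sum(axis=1)             # (T,)
    return k, two_m


def _normalization(k: np.ndarray, omega: float) -> float:
    T, N = k.shape
    return 0.5 * (k.sum() + omega * N * 2 * (T - 1))


def multilayer_modularity_score(network: TemporalNetwork,
                                labels: np.ndarray,
                                params: ModularityParams) -> float:
    """Exact evaluation of the multilayer modularity of ``labels``.

    Layers with zero total weight contribute no null-model term (a warning
    is emitted).  Deterministic; invariant under label permutations.
    """
    layers = network.layers
    T, N, _ = layers.shape
    labels = np.asarray(labels)
    if labels.shape == (T, N):
        labels = labels.T
    if labels.shape != (N, T):
        raise ValueError("labels must cover every (bead, layer) pair")
    k, two_m = _layer_quantities(layers)
    total = 0.0
    for s in range(T):
        A = layers[s]
        ls = labels[:, s]
        if two_m[s] <= 0:
            warnings.warn(f"layer {s} has zero total weight; null term skipped")
            inv2m = 0.0
        else:
            inv2m = 1.0 / two_m[s]
        for c in np.unique(ls):
            idx = np.flatnonzero(ls == c)
            total += A[np.ix_(idx, idx)].sum()
            if inv2m:
                K = k[s, idx].sum()
                total -= params.gamma * K * K * inv2m
    if T > 1 and params.omega > 0:
        same = labels[:, :-1] == labels[:, 1:]
        total += 2.0 * params.omega * same.sum()
    mu_norm = _normalization(k, params.omega)
    if mu_norm <= 0:
        raise ValueError("network has no weight to normalize against")
    return total / (2.0 * mu_norm)


# ---------------------------------------------------------------------------
# Louvain optimization
# ---------------------------------------------------------------------------

class _Level:
    """One aggregation level of the Louvain hierarchy.

    ``adj``: per-node dict neighbor -> weight (intralayer weights plus
    omega-weighted interlayer coupling; no self entries).
    ``self_w``: internal weight of each super-node in the ordered-pair
    convention.  ``kappa``: per-node dict layer -> intralayer strength.
    ``inv2m``: per-layer 1/(2m_s) (0 for empty layers).
    """

    __slots__ = ("adj", "self_w", "kappa", "inv2m", "gamma")

    def __init__(self, adj, self_w, kappa, inv2m, gamma):
        self.adj = adj
        self.self_w = self_w
        self.kappa = kappa
        self.inv2m = inv2m
        self.gamma = gamma

    @property
    def n(self):
        return len(self.adj)

    def partition_H(self, comm) -> float:
        """Unnormalized quality of a labeling of this level's nodes."""
        groups: dict = {}
        for u, c in enumerate(comm):
            groups.setdefault(c, []).append(u)
        H = 0.0
        for members in groups.values():
            mset = set(members)
            K: dict = {}
            for u in members:
                H += self.self_w[u]
                for v, w in self.adj[u].items():
                    if v in mset:
                        H += w
                for s, ks in self.kappa[u].items():
                    K[s] = K.get(s, 0.0) + ks
            for s, Ks in K.items():
                H -= self.gamma * self.inv2m[s] * Ks * Ks
        return H


def _build_level0(network: TemporalNetwork, params: ModularityParams) -> _Level:
    layers = network.layers
    T, N, _ = layers.shape
    k, two_m = _layer_quantities(layers)
    inv2m = np.where(two_m > 0, 1.0 / np.maximum(two_m, 1e-300), 0.0)
    M = N * T
    adj = [dict() for _ in range(M)]
    self_w = np.zeros(M)
    kappa = []
    for s in range(T):
        A = layers[s]
        ii, jj = np.nonzero(np.triu(A, k=1))
        base = s * N
        for i, j in zip(ii, jj):
            w = A[i, j]
            adj[base + i][base + j] = adj[base + i].get(base + j, 0.0) + w
            adj[base + j][base + i] = adj[base + j].get(base + i, 0.0) + w
    if params.omega > 0:
        for s in range(T - 1):
            for i in range(N):
                u = s * N + i
                v = (s + 1) * N + i
                adj[u][v] = adj[u].get(v, 0.0) + params.omega
                adj[v][u] = adj[v].get(u, 0.0) + params.omega
    for s in range(T):
        for i in range(N):
            kappa.append({s: float(k[s, i])} if k[s, i] > 0 else {})
    return _Level(adj, self_w, kappa, inv2m, params.gamma)


def _null_delta(level: _Level, u: int, K_target: dict, sign: int) -> float:
    """gamma-scaled null-model change of inserting (sign=+1) or removing
    (sign=-1) node u into/from a community with per-layer strengths
    ``K_target`` (excluding u)."""
    g = level.gamma
    acc = 0.0
    for s, ku in level.kappa[u].items():
        acc += level.inv2m[s] * ku * (2.0 * K_target.get(s, 0.0) + ku)
    return sign * g * acc


def _louvain_level(level: _Level, rng: np.random.Generator,
                   verify_moves: bool = False):
    """Greedy node-move phase; returns (community array, moved_any)."""
    n = level.n
    comm = np.arange(n)
    comm_K = [dict(level.kappa[u]) for u in range(n)]
    gamma = level.gamma
    inv2m = level.inv2m
    kappa = level.kappa
    adj = level.adj
    # fast path: a node living in a single layer (every level-0 node)
    # needs only that layer's community strength for its null term
    single = [next(iter(kappa[u].items())) if len(kappa[u]) == 1 else None
              for u in range(n)]
    improved = True
    moved_any = False
    while improved:
        improved = False
        for u in rng.permutation(n):
            a = comm[u]
            # link weights from u to each neighboring community
            L: dict = {}
            for v, w in adj[u].items():
                cv = comm[v]
                L[cv] = L.get(cv, 0.0) + w
            # take u out of a (null term without u)
            Ka = comm_K[a]
            su = single[u]
            if su is not None:
                s_u, k_u = su
                Ka[s_u] = Ka.get(s_u, 0.0) - k_u
                g_inv = gamma * inv2m[s_u] * k_u
                rem_gain = -2.0 * L.get(a, 0.0) + g_inv * (
                    2.0 * Ka.get(s_u, 0.0) + k_u)
                best_c, best_gain = a, 0.0
                for c, Lc in L.items():
                    if c == a:
                        continue
                    gain = rem_gain + 2.0 * Lc - g_inv * (
                        2.0 * comm_K[c].get(s_u, 0.0) + k_u)
                    if gain > best_gain + _EPS_GAIN or (
                            gain > best_gain - _EPS_GAIN and gain > _EPS_GAIN
                            and c < best_c):
                        best_c, best_gain = c, gain
                iso_gain = rem_gain - g_inv * k_u
            else:
                for s, ku in kappa[u].items():
                    Ka[s] = Ka.get(s, 0.0) - ku
                # H gained by removing u: lose intra links, recover null
                rem_gain = -2.0 * L.get(a, 0.0) + _null_delta(level, u, Ka, +1)
                best_c, best_gain = a, 0.0
                for c, Lc in L.items():
                    if c == a:
                        continue
                    gain = rem_gain + 2.0 * Lc \
                        + _null_delta(level, u, comm_K[c], -1)
                    if gain > best_gain + _EPS_GAIN or (
                            gain > best_gain - _EPS_GAIN and gain > _EPS_GAIN
                            and c < best_c):
                        best_c, best_gain = c, gain
                iso_gain = rem_gain + _null_delta(level, u, {}, -1)
            if iso_gain > best_gain + _EPS_GAIN:
                best_c, best_gain = -1, iso_gain
            if best_gain > _EPS_GAIN and best_c != a:
                if verify_moves:
                    before = level.partition_H(comm)
                target = best_c
                if target == -1:
                    used = set(comm)
                    target = next(c for c in range(n + 1) if c not in used)
                    while len(comm_K) <= target:
                        comm_K.append({})
                comm[u] = target
                Kt = comm_K[target]
                for s, ku in level.kappa[u].items():
                    Kt[s] = Kt.get(s, 0.0) + ku
                if verify_moves:
                    after = level.partition_H(comm)
                    if abs((after - before) - best_gain) > 1e-10 * max(
                            1.0, abs(before)):
                        raise AssertionError(
                            f"incremental gain {best_gain} != global "
                            f"difference {after - before}")
                improved = True
                moved_any = True
            else:
                # put u back into a
                for s, ku in level.kappa[u].items():
                    Ka[s] = Ka.get(s, 0.0) + ku
    return comm, moved_any


def _aggregate(level: _Level, comm: np.ndarray) -> tuple:
    """Collapse communities into super-nodes; returns (new level, mapping)."""
    ids = np.unique(comm)
    remap = {c: k for k, c in enumerate(ids)}
    mapping = np.array([remap[c] for c in comm])
    m = len(ids)
    adj = [dict() for _ in range(m)]
    self_w = np.zeros(m)
    kappa = [dict() for _ in range(m)]
    for u in range(level.n):
        cu = mapping[u]
        self_w[cu] += level.self_w[u]
        for s, ks in level.kappa[u].items():
            kappa[cu][s] = kappa[cu].get(s, 0.0) + ks
        for v, w in level.adj[u].items():
            cv = mapping[v]
            if cv == cu:
                self_w[cu] += w  # each unordered pair visited twice -> 2w total
            else:
                adj[cu][cv] = adj[cu].get(cv, 0.0) + w
    return _Level(adj, self_w, kappa, level.inv2m, level.gamma), mapping


def optimize_louvain(network: TemporalNetwork,
                     params: ModularityParams | None = None,
                     seed: int = 0, n_restarts: int = 1,
                     verify_moves: bool = False) -> PartitionAssignment:
    """Louvain optimization of multilayer modularity.

    Node order within each sweep is shuffled by a generator seeded with
    ``seed`` (deterministic for a fixed seed); ``n_restarts`` independent
    runs keep the best-Q labeling.  ``verify_moves`` cross-checks every
    accepted move's incremental gain against a full re-evaluation (slow;
    for validation).
    """
    if params is None:
        params = ModularityParams()
    layers = network.layers
    T, N, _ = layers.shape
    k, two_m = _layer_quantities(layers)
    if not (two_m > 0).any():
        raise ValueError("at least one layer must have positive weight")
    if (two_m <= 0).any():
        warnings.warn("some layers have zero total weight; their null terms "
                      "are skipped")
    mu_norm = _normalization(k, params.omega)
    best = None
    rng_master = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        level = _build_level0(network, params)
        assignment = np.arange(level.n)
        while True:
            comm, moved = _louvain_level(level, rng, verify_moves=verify_moves)
            level, mapping = _aggregate(level, comm)
            assignment = mapping[comm[assignment]]
            if not moved or level.n == 1:
                break
        H = level.partition_H(np.arange(level.n))
        Q = H / (2.0 * mu_norm)
        if best is None or Q > best[0]:
            best = (Q, assignment)
    Q, assignment = best
    labels = assignment.reshape(T, N).T.copy()
    # relabel to consecutive positive integers, ordered by first appearance
    flat = labels.T.ravel()
    _, first_idx = np.unique(flat, return_index=True)
    order = flat[np.sort(first_idx)]
    lut = {c: k + 1 for k, c in enumerate(order)}
    labels = np.vectorize(lut.get, otypes=[np.int64])(labels)
    return PartitionAssignment(
        labels=labels, params=params, Q=float(Q), strengths=k.T.copy(),
        layer_weights=two_m, mu_norm=mu_norm,
        meta={"seed": seed, "n_restarts": n_restarts,
              "window_seconds": network.window_seconds},
    )


def single_layer_partition(adjacency, gamma: float = 1.0,
                           seed: int = 0, n_restarts: int = 1,
                           d_star: float = 325.0) -> np.ndarray:
    """Louvain partition of a single network (no interlayer coupling);
    accepts an adjacency matrix or a DistanceMap (converted with the
    exponential-decay rule at ``d_star``).  Returns one label per node."""
    from .distance_maps import DistanceMap

    if isinstance(adjacency, DistanceMap):
        from .networks import adjacency_from_distances
        adjacency = adjacency_from_distances(adjacency, d_star=d_star)
    A = np.asarray(adjacency, dtype=float)
    net = TemporalNetwork(A[None, :, :], delta=1, d_star=np.inf, s_decay=0.0)
    part = optimize_louvain(net, ModularityParams(gamma=gamma, omega=0.0),
                            seed=seed, n_restarts=n_restarts)
    return part.labels[:, 0]


def parameter_sweep(network: TemporalNetwork, gamma_grid, omega_grid,
                    seeds=(0,), stability_rtol: float = 0.2) -> pd.DataFrame:
    """Grid sweep over (gamma, omega, seed).

    Each row reports Q, the community count, the mean per-layer community
    size and the bead-level persistence (fraction of node-layer pairs
    keeping their label in the next layer).  ``robust`` flags grid points
    whose mean community count differs from every adjacent grid point by
    at most ``stability_rtol`` (relative).
    """
    gamma_grid = list(gamma_grid)
    omega_grid = list(omega_grid)
    if not gamma_grid or not omega_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    for gi, gamma in enumerate(gamma_grid):
        for oi, omega in enumerate(omega_grid):
            for seed in seeds:
                part = optimize_louvain(
                    network, ModularityParams(gamma=gamma, omega=omega),
                    seed=seed)
                labels = part.labels
                per_layer_sizes = [
                    labels.shape[0] / np.unique(labels[:, s]).size
                    for s in range(labels.shape[1])
                ]
                if labels.shape[1] > 1:
                    persist = float(np.mean(labels[:, :-1] == labels[:, 1:]))
                else:
                    persist = np.nan
                rows.append({
                    "gamma": gamma, "omega": omega, "seed": seed,
                    "gamma_idx": gi, "omega_idx": oi,
                    "Q": part.Q, "n_communities": part.n_communities,
                    "mean_size": float(np.mean(per_layer_sizes)),
                    "persistence": persist,
                })
    table = pd.DataFrame(rows)
    mean_n = table.groupby(["gamma_idx", "omega_idx"])["n_communities"].mean()
    robust = {}
    for (gi, oi), val in mean_n.items():
        ok = True
        for dgi, doi in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            key = (gi + dgi, oi + doi)
            if key in mean_n.index:
                other = mean_n.loc[key]
                if abs(other - val) > stability_rtol * max(val, other, 1.0):
                    ok = False
        robust[(gi, oi)] = ok
    table["robust"] = [
        robust[(gi, oi)] for gi, oi in zip(table.gamma_idx, table.omega_idx)
    ]
    return table.drop(columns=["gamma_idx", "omega_idx"])


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_labels_tsv(assignment: PartitionAssignment, path) -> None:
    """Write labels as TSV rows (bead, layer, label)."""
    with open(path, "w") as fh:
        fh.write("bead\tlayer\tlabel\n")
        N, T = assignment.labels.shape
        for s in range(T):
            for i in range(N):
                fh.write(f"{i}\t{s}\t{assignment.labels[i, s]}\n")


def render_snapshot_png(positions: np.ndarray, labels, path,
                        title: str = "") -> None:
    """Color-coded 3D scatter of one frame's bead positions by community."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(positions[:, 0], positions[:, 1], positions[:, 2],
               c=labels, cmap="tab20", s=18, depthshade=True)
    ax.set_box_aspect((1, 1, 1))
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150)
    plt.close(fig)
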