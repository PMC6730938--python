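import itertools

import numpy as np
import pytest

from nucleomix.communities import (
    ModularityParams,
    multilayer_modularity_score,
    optimize_louvain,
    parameter_sweep,
    single_layer_partition,
)
from nucleomix.networks import TemporalNetwork


def net_from_layers(*layers):
    return TemporalNetwork(np.stack([np.asarray(a, dtype=float)
                                     for a in layers]),
                           delta=1, d_star=np.inf, s_decay=0.0)


def two_edges_graph():
    A = np.zeros((4, 4))
    A[0, 1] = A[1, 0] = 1.0
    A[2, 3] = A[3, 2] = 1.0
    return A


def clique(n):
    A = np.ones((n, n)) - np.eye(n)
    return A


def two_cliques_graph():
    A = np.zeros((8, 8))
    A[:4, :4] = clique(4)
    A[4:, 4:] = clique(4)
    return A


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1:]
        yield [[first]] + smaller


def partition_to_labels(parts, n):
    labels = np.empty(n, dtype=int)
    for c, block in enumerate(parts):
        for i in block:
            labels[i] = c
    return labels


def exhaustive_single_layer_max(A, gamma):
    """Brute-force modularity maximum over every partition of the nodes."""
    net = net_from_layers(A)
    params = ModularityParams(gamma=gamma, omega=0.0)
    best = -np.inf
    best_labels = None
    n = A.shape[0]
    for parts in set_partitions(list(range(n))):
        labels = partition_to_labels(parts, n)[:, None]
        q = multilayer_modularity_score(net, labels, params)
        if q > best:
            best, best_labels = q, labels
    return best, best_labels


class TestScore:
    def test_two_disjoint_edges_partition_scores_half(self):
        net = net_from_layers(two_edges_graph())
        labels = np.array([[0], [0], [1], [1]])
        q = multilayer_modularity_score(net, labels,
                                        ModularityParams(gamma=1.0, omega=0.0))
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_two_disjoint_edges_exhaustive_maximum_is_half(self):
        best, labels = exhaustive_single_layer_max(two_edges_graph(), 1.0)
        assert best == pytest.approx(0.5, abs=1e-12)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_all_in_one_community_zero(self):
        rng = np.random.default_rng(0)
        A = (rng.random((6, 6)) < 0.5).astype(float)
        A = np.triu(A, 1) + np.triu(A, 1).T
        net = net_from_layers(A)
        labels = np.zeros((6, 1), dtype=int)
        q = multilayer_modularity_score(net, labels,
                                        ModularityParams(gamma=1.0, omega=0.0))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_invariance(self):
        net = net_from_layers(two_edges_graph(), two_edges_graph())
        params = ModularityParams(gamma=1.5, omega=0.7)
        labels = np.array([[0, 0], [0, 1], [1, 1], [1, 0]])
        q1 = multilayer_modularity_score(net, labels, params)
        q2 = multilayer_modularity_score(net, 10 - labels * 7, params)
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_agrees_with_networkx_single_layer(self):
        """Independent cross-check of the gamma-modularity convention."""
        import networkx as nx

        rng = np.random.default_rng(4)
        A = (rng.random((7, 7)) < 0.45).astype(float)
        A = np.triu(A, 1) + np.triu(A, 1).T
        G = nx.from_numpy_array(A)
        labels = rng.integers(0, 3, size=7)
        comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        for gamma in (0.7, 1.0, 2.5):
            expect = nx.community.modularity(G, comms, resolution=gamma)
            got = multilayer_modularity_score(
                net_from_layers(A), labels[:, None],
                ModularityParams(gamma=gamma, omega=0.0))
            assert got == pytest.approx(expect, abs=1e-12)

    def test_zero_weight_layer_warns_and_skips_null(self):
        layers = [two_edges_graph(), np.zeros((4, 4))]
        net = net_from_layers(*layers)
        labels = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        with pytest.warns(UserWarning):
            q = multilayer_modularity_score(
                net, labels, ModularityParams(gamma=1.0, omega=0.0))
        assert np.isfinite(q)


class TestLouvain:
    def test_two_cliques_three_layers_recovers_exhaustive_optimum(self):
        A = two_cliques_graph()
        net = net_from_layers(A, A, A)
        params = ModularityParams(gamma=1.0, omega=1.0)
        part = optimize_louvain(net, params, seed=0)
        # the two cliques as two persistent communities
        for s in range(3):
            assert len(set(part.labels[:4, s])) == 1
            assert len(set(part.labels[4:, s])) == 1
            assert part.labels[0, s] != part.labels[4, s]
        assert len(np.unique(part.labels)) == 2
        # restricted exhaustive oracle: each (clique, layer) cell gets one
        # of two labels; the optimum over all 2^6 labelings
        best = -np.inf
        for bits in itertools.product([0, 1], repeat=6):
            labels = np.empty((8, 3), dtype=int)
            for s in range(3):
                labels[:4, s] = bits[2 * s]
                labels[4:, s] = 2 + bits[2 * s + 1]
            best = max(best, multilayer_modularity_score(net, labels, params))
        assert part.Q == pytest.approx(best, abs=1e-10)

    def test_omega_zero_matches_independent_layer_runs(self):
        rng = np.random.default_rng(9)
        layers = []
        for _ in range(2):
            A = (rng.random((6, 6)) < 0.5).astype(float)
            layers.append(np.triu(A, 1) + np.triu(A, 1).T)
        net = net_from_layers(*layers)
        part = optimize_louvain(net, ModularityParams(gamma=1.0, omega=0.0),
                                seed=3, n_restarts=4)
        q_sum = 0.0
        for s, A in enumerate(layers):
            single = single_layer_partition(A, gamma=1.0, seed=3,
                                            n_restarts=4)
            # same partition structure per layer (up to relabeling)
            a = part.labels[:, s]
            pairs_a = (a[:, None] == a[None, :])
            pairs_b = (single[:, None] == single[None, :])
            assert np.array_equal(pairs_a, pairs_b)

    def test_huge_omega_locks_labels_across_layers(self):
        rng = np.random.default_rng(12)
        layers = []
        for _ in range(3):
            A = (rng.random((6, 6)) < 0.6).astype(float)
            layers.append(np.triu(A, 1) + np.triu(A, 1).T)
        net = net_from_layers(*layers)
        part = optimize_louvain(
            net, ModularityParams(gamma=1.0, omega=1000.0), seed=0)
        assert np.all(part.labels[:, :1] == part.labels)

    def test_incremental_gains_match_global_reevaluation(self):
        rng = np.random.default_rng(21)
        layers = []
        for _ in range(3):
            A = rng.random((7, 7)) * (rng.random((7, 7)) < 0.5)
            layers.append(np.triu(A, 1) + np.triu(A, 1).T)
        net = net_from_layers(*layers)
        # verify_moves recomputes H from scratch after every accepted move
        # and raises on any mismatch beyond 1e-10
        optimize_louvain(net, ModularityParams(gamma=1.3, omega=0.8),
                         seed=5, verify_moves=True)

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        A = rng.random((10, 10)) * (rng.random((10, 10)) < 0.4)
        A = np.triu(A, 1) + np.triu(A, 1).T
        net = net_from_layers(A, A)
        p1 = optimize_louvain(net, ModularityParams(1.0, 0.5), seed=7)
        p2 = optimize_louvain(net, ModularityParams(1.0, 0.5), seed=7)
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.Q == p2.Q

    def test_exhaustive_oracle_on_random_single_layer_toys(self):
        """On 5-node toys the optimized Q equals the brute-force maximum
        over all 52 partitions."""
        rng = np.random.default_rng(31)
        for trial in range(3):
            A = rng.random((5, 5)) * (rng.random((5, 5)) < 0.6)
            A = np.triu(A, 1) + np.triu(A, 1).T
            if A.sum() == 0:
                continue
            best, _ = exhaustive_single_layer_max(A, 1.0)
            net = net_from_layers(A)
            part = optimize_louvain(net, ModularityParams(1.0, 0.0),
                                    seed=trial, n_restarts=8)
            assert part.Q == pytest.approx(best, abs=1e-10)


class TestSingleLayer:
    def test_two_disjoint_edges(self):
        labels = single_layer_partition(two_edges_graph(), gamma=1.0, seed=0)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_complete_graph_single_community(self):
        labels = single_layer_partition(clique(6), gamma=1.0, seed=0)
        assert len(set(labels)) == 1

    def test_large_gamma_all_singletons(self):
        labels = single_layer_partition(clique(6), gamma=100.0, seed=0)
        assert len(set(labels)) == 6


class TestParameterSweep:
    def test_single_point_grid_consistent_with_louvain(self):
        net = net_from_layers(two_cliques_graph())
        table = parameter_sweep(net, [1.0], [0.0], seeds=[4])
        assert len(table) == 1
        part = optimize_louvain(net, ModularityParams(1.0, 0.0), seed=4)
        assert table.Q.iloc[0] == pytest.approx(part.Q)
        assert table.n_communities.iloc[0] == part.n_communities

    def test_singleton_forcing_gamma_reports_n_communities(self):
        net = net_from_layers(clique(5))
        table = parameter_sweep(net, [200.0], [0.0], seeds=[0])
        assert table.n_communities.iloc[0] == 5

    def test_community_count_non_increasing_in_omega(self):
        rng = np.random.default_rng(17)
        A = rng.random((8, 8)) * (rng.random((8, 8)) < 0.4)
        A = np.triu(A, 1) + np.triu(A, 1).T
        net = net_from_layers(A, A, A)
        table = parameter_sweep(net, [1.0], [0.0, 0.5, 5.0], seeds=[0, 1])
        counts = table.groupby("omega")["n_communities"].mean()
        vals = counts.sort_index().values
        assert all(vals[i] >= vals[i + 1] - 1e-9 for i in range(len(vals) - 1))
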