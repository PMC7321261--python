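"""Global graph indices vs independent brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from persistnet import (
    GraphMetricsTransformer,
    build_network,
    characteristic_path_length,
    clustering_coefficient,
    compute_all,
    eigenvector_centrality,
    global_efficiency,
    modularity,
    nodal_strength,
    shortest_path_matrix,
)
from persistnet.exceptions import UndefinedMetricError, ValidationError
from conftest import random_weighted_graph, weight_matrix_from_edges


def floyd_warshall(w):
    """All-pairs shortest paths by direct triple-loop relaxation."""
    n = w.shape[0]
    D = np.where(np.isfinite(w), w, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def brute_clustering(w):
    """Direct evaluation of the geometric-mean triangle sum, weights
    normalised by the maximum present weight; average over all nodes."""
    n = w.shape[0]
    present = np.isfinite(w) & ~np.eye(n, dtype=bool)
    wmax = w[present].max()
    wn = np.where(present, w / wmax, 0.0)
    total = 0.0
    for i in range(n):
        k_i = present[i].sum()
        if k_i < 2:
            continue
        s = 0.0
        for j in range(n):
            for k in range(n):
                if j == k or not (present[i, j] and present[j, k] and present[k, i]):
                    continue
                s += (wn[i, j] * wn[j, k] * wn[k, i]) ** (1.0 / 3.0)
        total += s / (k_i * (k_i - 1))
    return total / n


def all_partitions(nodes):
    if len(nodes) == 1:
        yield [nodes]
        return
    first, rest = nodes[0], nodes[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def brute_modularity_max(w):
    """Exhaustive Q maximum via the direct modularity sum (no networkx)."""
    n = w.shape[0]
    A = np.where(np.isfinite(w), w, 0.0)
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    m2 = A.sum()
    best = -np.inf
    for part in all_partitions(list(range(n))):
        q = 0.0
        for block in part:
            idx = np.array(block)
            q += A[np.ix_(idx, idx)].sum() / m2 - (deg[idx].sum() / m2) ** 2
        best = max(best, q)
    return best


def power_iteration_centrality(w, iters=10_000, tol=1e-14):
    A = np.where(np.isfinite(w), w, 0.0)
    np.fill_diagonal(A, 0.0)
    # shift so the dominant eigenvalue is strictly separated and positive
    # (same eigenvectors; avoids oscillation when |lambda_min| ~ lambda_max)
    A = A + A.sum(axis=1).max() * np.eye(A.shape[0])
    v = np.ones(A.shape[0]) / np.sqrt(A.shape[0])
    for _ in range(iters):
        nv = A @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return v
        nv /= norm
        if np.linalg.norm(nv - v) < tol:
            return nv
        v = nv
    return v


class TestShortestPaths:
    def test_two_node_edge(self):
        w = weight_matrix_from_edges(2, [(0, 1, 0.5)])
        D = shortest_path_matrix(w)
        assert D[0, 1] == 0.5
        assert characteristic_path_length(w) == pytest.approx(0.5)
        assert global_efficiency(w) == pytest.approx(2.0)

    def test_path_graph_sums_edge_lengths(self):
        w = weight_matrix_from_edges(3, [(0, 1, 0.2), (1, 2, 0.3)])
        D = shortest_path_matrix(w)
        assert D[0, 2] == pytest.approx(0.5)
        assert characteristic_path_length(w) == pytest.approx((0.2 + 0.3 + 0.5) / 3)

    def test_triangle_cpl(self):
        w = weight_matrix_from_edges(3, [(0, 1, 0.4), (1, 2, 0.4), (0, 2, 0.4)])
        assert characteristic_path_length(w) == pytest.approx(0.4)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(5):
            w = random_weighted_graph(rng, 7, p=0.5)
            np.testing.assert_allclose(shortest_path_matrix(w), floyd_warshall(w), atol=1e-12)

    def test_negative_weights_rejected(self):
        w = weight_matrix_from_edges(3, [(0, 1, -0.2), (1, 2, 0.3)])
        with pytest.raises(ValidationError):
            shortest_path_matrix(w)

    def test_cpl_ge_on_random_networks_match_oracle_means(self, rng):
        for _ in range(5):
            w = random_weighted_graph(rng, 7, p=0.6, ensure_connected=True)
            D = floyd_warshall(w)
            off = ~np.eye(7, dtype=bool)
            assert characteristic_path_length(w) == pytest.approx(D[off].mean())
            assert global_efficiency(w) == pytest.approx((1.0 / D[off]).mean())

    def test_fully_disconnected_efficiency_zero(self):
        w = np.full((4, 4), np.inf)
        np.fill_diagonal(w, 0.0)
        assert global_efficiency(w) == 0.0
        with pytest.raises(UndefinedMetricError):
            characteristic_path_length(w)

    def test_ge_nondecreasing_under_edge_addition(self, rng):
        w = random_weighted_graph(rng, 7, p=0.4)
        base = global_efficiency(w)
        absent = [
            (i, j)
            for i, j in itertools.combinations(range(7), 2)
            if not np.isfinite(w[i, j])
        ]
        if absent:
            i, j = absent[0]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = 0.9
            assert global_efficiency(w2) >= base


class TestStrengthAndClustering:
    def test_triangle_strength(self):
        w = weight_matrix_from_edges(3, [(0, 1, 0.4), (1, 2, 0.4), (0, 2, 0.4)])
        assert nodal_strength(w) == pytest.approx(0.8)

    def test_edgeless_strength_zero(self):
        w = np.full((3, 3), np.inf)
        np.fill_diagonal(w, 0.0)
        assert nodal_strength(w) == 0.0

    def test_uniform_triangle_clustering_is_one(self):
        w = weight_matrix_from_edges(3, [(0, 1, 0.7), (1, 2, 0.7), (0, 2, 0.7)])
        assert clustering_coefficient(w) == pytest.approx(1.0)

    def test_star_clustering_zero(self):
        w = weight_matrix_from_edges(4, [(0, 1, 0.5), (0, 2, 0.5), (0, 3, 0.5)])
        assert clustering_coefficient(w) == 0.0

    def test_matches_brute_force_triple_enumeration(self, rng):
        for _ in range(5):
            w = random_weighted_graph(rng, 6, p=0.7)
            if not np.isfinite(w[~np.eye(6, dtype=bool)]).any():
                continue
            assert clustering_coefficient(w) == pytest.approx(brute_clustering(w), abs=1e-12)

    def test_uniform_weights_reduce_to_binary_clustering(self, rng):
        # with all weights equal the geometric-mean form must equal the
        # unweighted triangle fraction
        for _ in range(5):
            w = random_weighted_graph(rng, 6, p=0.6)
            wb = np.where(np.isfinite(w), 0.37, np.inf)
            np.fill_diagonal(wb, 0.0)
            present = np.isfinite(wb) & ~np.eye(6, dtype=bool)
            total = 0.0
            for i in range(6):
                k_i = present[i].sum()
                if k_i < 2:
                    continue
                tri = sum(
                    1
                    for j in range(6)
                    for k in range(6)
                    if j != k and present[i, j] and present[j, k] and present[k, i]
                )
                total += tri / (k_i * (k_i - 1))
            assert clustering_coefficient(wb) == pytest.approx(total / 6, abs=1e-12)


class TestModularity:
    def test_two_cliques_with_weak_bridge(self):
        edges = []
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                edges.append((i, j, 1.0))
        edges.append((0, 4, 0.1))
        w = weight_matrix_from_edges(8, edges)
        # closed-form Q of the two-clique partition via the direct sum
        A = np.where(np.isfinite(w), w, 0.0)
        np.fill_diagonal(A, 0.0)
        m2 = A.sum()
        deg = A.sum(axis=1)
        q_expected = 0.0
        for blk in (list(range(4)), list(range(4, 8))):
            q_expected += A[np.ix_(blk, blk)].sum() / m2 - (deg[blk].sum() / m2) ** 2
        assert modularity(w) == pytest.approx(q_expected, abs=1e-12)

    def test_complete_uniform_graph_no_structure(self):
        w = weight_matrix_from_edges(
            5, [(i, j, 1.0) for i, j in itertools.combinations(range(5), 2)]
        )
        assert modularity(w) == pytest.approx(0.0, abs=1e-12)

    def test_exact_solver_matches_exhaustive_partition_search(self, rng):
        for _ in range(8):
            n = int(rng.integers(4, 8))
            w = random_weighted_graph(rng, n, p=0.7, ensure_connected=True)
            assert modularity(w) == pytest.approx(brute_modularity_max(w), abs=1e-10)

    def test_greedy_never_beats_exact(self, rng):
        for _ in range(5):
            w = random_weighted_graph(rng, 7, p=0.7, ensure_connected=True)
            assert modularity(w, solver="greedy") <= modularity(w, solver="exact") + 1e-12

    def test_edgeless_rejected(self):
        w = np.full((4, 4), np.inf)
        np.fill_diagonal(w, 0.0)
        with pytest.raises(UndefinedMetricError):
            modularity(w)


class TestEigenvectorCentrality:
    def test_complete_uniform_graph_symmetric_centrality(self):
        n = 5
        w = weight_matrix_from_edges(
            n, [(i, j, 0.8) for i, j in itertools.combinations(range(n), 2)]
        )
        assert eigenvector_centrality(w) == pytest.approx(1 / np.sqrt(n))
        assert eigenvector_centrality(w, summary="max") == pytest.approx(1 / np.sqrt(n))

    def test_star_hub_dominates(self):
        w = weight_matrix_from_edges(5, [(0, k, 1.0) for k in range(1, 5)])
        hub_max = eigenvector_centrality(w, summary="max")
        mean = eigenvector_centrality(w, summary="mean")
        assert hub_max > mean  # hub strictly exceeds the average

    def test_matches_power_iteration_oracle(self, rng):
        for _ in range(5):
            w = random_weighted_graph(rng, 7, p=0.7, ensure_connected=True)
            v = power_iteration_centrality(w)
            assert eigenvector_centrality(w) == pytest.approx(v.mean(), abs=1e-8)
            assert eigenvector_centrality(w, summary="max") == pytest.approx(v.max(), abs=1e-8)

    def test_computed_on_largest_component(self):
        # component {0,1,2} (triangle) larger than {3,4}: leaves 3,4 at 0
        w = weight_matrix_from_edges(
            5, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0), (3, 4, 5.0)]
        )
        v_uniform = 1 / np.sqrt(3)
        assert eigenvector_centrality(w, summary="max") == pytest.approx(v_uniform)
        assert eigenvector_centrality(w) == pytest.approx(3 * v_uniform / 5)


class TestComputeAll:
    def test_node_relabeling_leaves_all_six_unchanged(self, rng):
        w = random_weighted_graph(rng, 7, p=0.8, ensure_connected=True)
        perm = rng.permutation(7)
        a = compute_all(w)
        b = compute_all(w[np.ix_(perm, perm)])
        for f in ("cpl", "ge", "ns", "mod", "cc", "ec"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-9)

    def test_same_seed_identical(self, rng):
        w = random_weighted_graph(rng, 7, p=0.8, ensure_connected=True)
        assert compute_all(w, seed=3) == compute_all(w, seed=3)

    def test_transformer_bundles_six_columns(self, rng):
        nets = [random_weighted_graph(rng, 6, p=0.9, ensure_connected=True) for _ in range(3)]
        t = GraphMetricsTransformer().fit(nets)
        out = t.transform(nets)
        assert out.shape == (3, 6)
        assert list(t.get_feature_names_out()) == ["cpl", "ge", "ns", "mod", "cc", "ec"]

    def test_affinity_flag_changes_magnitude_metrics_only(self, rng):
        counts = np.random.default_rng(0).poisson(60, size=(12, 12)).astype(float)
        counts = np.triu(counts, 1)
        counts = counts + counts.T
        from persistnet import FiberProfileMatrix, threshold_significant

        W = build_network(FiberProfileMatrix(counts, [f"R{i}" for i in range(12)]))
        N = threshold_significant(W, alpha=1.0)
        lit = compute_all(N)
        aff = compute_all(N, affinity=True)
        assert lit.cpl == aff.cpl and lit.ge == aff.ge
        assert lit.ns != aff.ns
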