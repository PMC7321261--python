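"""Shared fixtures: worked-example graphs and random-graph generators."""

import itertools

import numpy as np
import pytest


def weight_matrix_from_edges(n, edges):
    """Dense weight matrix with absent edges marked inf (0 on the diagonal)."""
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for i, j, wt in edges:
        w[i, j] = w[j, i] = wt
    return w


@pytest.fixture
def worked_example_graph():
    """6-node weighted graph admitting two distinct MSTs with the identical
    edge-weight multiset [0.1, 0.2, 0.4, 0.4, 0.5].

    The path 0-1-2-3-4-5 carries weights (0.1, 0.2, 0.4, 0.4, 0.5); the
    chord (1,3, 0.4) offers an alternative to the (2,3) edge at equal weight,
    and heavier chords never enter any MST.
    """
    edges = [
        (0, 1, 0.1),
        (1, 2, 0.2),
        (2, 3, 0.4),
        (3, 4, 0.4),
        (4, 5, 0.5),
        (1, 3, 0.4),
        (0, 2, 0.9),
        (2, 4, 0.8),
        (3, 5, 0.7),
    ]
    return weight_matrix_from_edges(6, edges)


def random_weighted_graph(rng, n, p=0.6, ensure_connected=False, duplicates=False):
    """Random symmetric weight matrix; inf marks absent edges."""
    while True:
        w = np.full((n, n), np.inf)
        np.fill_diagonal(w, 0.0)
        pool = [0.1, 0.2, 0.3, 0.4, 0.5] if duplicates else None
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < p:
                wt = rng.choice(pool) if duplicates else rng.uniform(0.05, 2.0)
                w[i, j] = w[j, i] = float(wt)
        if not ensure_connected:
            return w
        # check connectivity by simple union-find
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in itertools.combinations(range(n), 2):
            if np.isfinite(w[i, j]):
                parent[find(i)] = find(j)
        if len({find(i) for i in range(n)}) == 1:
            return w


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
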