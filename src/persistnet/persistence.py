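"""Zeroth persistent homology of weighted networks via the maximal graph filtration.

For a weighted graph ``G`` and a threshold ``lambda``, let ``B(G, lambda)``
be the subgraph keeping edges of weight ``<= lambda``. As ``lambda`` grows
the subgraphs are nested and the number of connected components ``beta_0``
can only fall: this is the graph filtration. The *maximal* filtration is the
finest one — its event values are exactly the distinct edge weights of any
minimum spanning tree (equivalently, the merge heights of the single-linkage
dendrogram), because an MST records precisely the component merges. All MSTs
of a graph share one edge-weight multiset, so the filtration is unique even
when the MST is not.

Two persistent features summarise the filtration:

* **BNP** (Betti number plot): ``beta_0`` as a right-continuous step function
  of ``lambda``. At a filtration value the merges occurring exactly there are
  included, so ``beta_0(lambda) = n - #{MST weights <= lambda}`` (per
  connected component of the input).
* **IPF** (integrated persistent feature): the total persistence still
  required to finish all remaining merges,
  ``IPF(lambda) = sum of MST weights > lambda``. It decreases monotonically
  and reaches exactly 0 at the largest filtration value. A continuous
  variant ``sum of (w - lambda)+`` is available via ``formula='continuous'``.

Each curve is reduced to a scalar *slope index*: the absolute value of the
ordinary-least-squares slope of curve value against filtration value over the
curve's breakpoints (or over a uniform grid with ``sampling='grid'``). Higher
indices mean the network's components merge over a narrower, later band of
weights — the disease-like signature of a segregated network.

Edge convention: in a weight matrix, any finite off-diagonal entry is an edge
(a weight of 0 is a real, maximally strong edge); ``inf``/``nan`` entries
mark absent edges. Disconnected inputs are handled as spanning forests with
a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .connectome import WeightedNetwork
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GraphFiltration",
    "PersistenceCurve",
    "mst_weight_multiset",
    "maximal_graph_filtration",
    "betti0_curve",
    "ipf_curve",
    "slope_index",
    "component_count_at",
    "persistence_indices",
    "PersistentFeatureTransformer",
]


def _as_weight_matrix(W) -> np.ndarray:
    if isinstance(W, WeightedNetwork):
        return W.weights
    w = np.asarray(W, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"weight matrix must be square, got shape {w.shape}")
    finite = np.isfinite(w)
    both = finite & finite.T
    if not np.allclose(w[both].reshape(-1), w.T[both].reshape(-1)) or not np.array_equal(
        finite, finite.T
    ):
        raise ValidationError("weight matrix is not symmetric")
    return w


def _graph(w: np.ndarray) -> nx.Graph:
    n = w.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    finite = np.isfinite(w[iu, ju])
    G.add_weighted_edges_from(
        (int(i), int(j), float(w[i, j])) for i, j in zip(iu[finite], ju[finite])
    )
    return G


def mst_weight_multiset(W) -> np.ndarray:
    """Sorted multiset of minimum-spanning-tree (or forest) edge weights.

    Invariant to which particular MST the algorithm finds: all MSTs of a
    graph have the identical weight multiset.
    """
    w = _as_weight_matrix(W)
    if w.shape[0] == 0:
        raise ValidationError("empty graph has no spanning tree")
    G = _graph(w)
    if nx.number_connected_components(G) > 1:
        logger.warning(
            "input graph is disconnected (%d components); computing a spanning forest",
            nx.number_connected_components(G),
        )
    edges = nx.minimum_spanning_edges(G, algorithm="kruskal", data=True)
    return np.sort([d["weight"] for _, _, d in edges])


@dataclass
class GraphFiltration:
    """The maximal graph filtration of a weighted network.

    ``filtration_values`` is the strictly increasing sequence
    ``{0} ∪ {distinct MST weights}`` and ``betti0[k]`` the number of
    connected components of ``B(G, filtration_values[k])``.
    """

    filtration_values: np.ndarray
    betti0: np.ndarray
    mst_weights: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.filtration_values = np.asarray(self.filtration_values, dtype=float)
        self.betti0 = np.asarray(self.betti0, dtype=int)
        self.mst_weights = np.asarray(self.mst_weights, dtype=float)
        fv = self.filtration_values
        if fv.size == 0 or fv[0] != 0.0 and not np.any(self.mst_weights <= 0):
            raise ValidationError("filtration values must begin at 0")
        if np.any(np.diff(fv) <= 0):
            raise ValidationError("filtration values must be strictly increasing")
        if np.any(np.diff(self.betti0) > 0):
            raise ValidationError("betti0 must be non-increasing along the filtration")
        if len(fv) != 1 + len(np.unique(self.mst_weights[self.mst_weights > 0])):
            raise ValidationError(
                "filtration length must be 1 + number of distinct positive MST weights"
            )


def maximal_graph_filtration(W) -> GraphFiltration:
    """Compute the maximal graph filtration from the MST weight multiset.

    ``beta_0`` at value ``lambda`` is ``n_nodes - #{MST weights <= lambda}``
    (threshold inclusive, so merges occurring exactly at ``lambda`` count).
    """
    w = _as_weight_matrix(W)
    n = w.shape[0]
    mst_w = mst_weight_multiset(w)
    values = np.unique(np.concatenate([[0.0], mst_w]))
    betti0 = np.array([n - int(np.sum(mst_w <= lam)) for lam in values])
    return GraphFiltration(values, betti0, mst_w, n)


@dataclass
class PersistenceCurve:
    """A persistent-feature step function over filtration values.

    Right-continuous: the value *at* a breakpoint includes the merges
    occurring there. ``kind`` is ``'BNP'`` (component counts) or ``'IPF'``
    (remaining total persistence).
    """

    kind: str
    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("BNP", "IPF"):
            raise ValidationError(f"kind must be 'BNP' or 'IPF', got {self.kind!r}")
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.breakpoints.shape != self.values.shape:
            raise ValidationError("breakpoints and values must have equal length")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValidationError("breakpoints must be strictly increasing")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValidationError(f"{self.kind} curve must be non-increasing")

    def evaluate(self, lam) -> np.ndarray | float:
        """Step-function evaluation: the value at the largest breakpoint
        <= ``lam`` (the first value below the first breakpoint)."""
        lam = np.asarray(lam, dtype=float)
        idx = np.clip(np.searchsorted(self.breakpoints, lam, side="right") - 1, 0, None)
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out


def betti0_curve(f: GraphFiltration) -> PersistenceCurve:
    """The Betti number plot: ``beta_0`` over all filtration values."""
    return PersistenceCurve("BNP", f.filtration_values, f.betti0.astype(float))


def ipf_curve(f: GraphFiltration, formula: str = "discrete") -> PersistenceCurve:
    """The integrated persistent feature over all filtration values.

    ``'discrete'`` (default): IPF(lambda) = sum of MST weights > lambda.
    ``'continuous'``: IPF(lambda) = sum of (w - lambda)+ over MST weights —
    same breakpoints, same zero terminal value, piecewise-linear in between.
    """
    if formula not in ("discrete", "continuous"):
        raise ValidationError(f"formula must be 'discrete' or 'continuous', got {formula!r}")
    w = f.mst_weights
    lam = f.filtration_values
    if formula == "discrete":
        vals = np.array([w[w > x].sum() for x in lam])
    else:
        vals = np.array([np.clip(w - x, 0.0, None).sum() for x in lam])
    return PersistenceCurve("IPF", lam, vals)


def slope_index(
    c: PersistenceCurve, sampling: str = "breakpoints", n_grid: int = 101
) -> float:
    """Absolute OLS slope of curve value against filtration value.

    ``sampling='breakpoints'`` regresses over the curve's own
    ``(breakpoint, value)`` pairs — deterministic and exact on worked
    examples. ``sampling='grid'`` evaluates the step function on a uniform
    grid of ``n_grid`` points over ``[0, lambda_max]``, which puts subjects
    with different breakpoint sets on a common footing. A single-breakpoint
    (constant) curve has index 0 by convention.
    """
    if sampling not in ("breakpoints", "grid"):
        raise ValidationError(f"sampling must be 'breakpoints' or 'grid', got {sampling!r}")
    bp, vals = c.breakpoints, c.values
    if bp.size < 2:
        logger.info("curve has a single breakpoint; slope index is 0 by convention")
        return 0.0
    if sampling == "grid":
        xs = np.linspace(0.0, bp[-1], n_grid)
        ys = np.asarray(c.evaluate(xs), dtype=float)
    else:
        xs, ys = bp, vals
    if np.ptp(xs) == 0:
        raise ValidationError("degenerate curve: identical filtration values")
    sxx = np.sum((xs - xs.mean()) ** 2)
    sxy = np.sum((xs - xs.mean()) * (ys - ys.mean()))
    return float(abs(sxy / sxx))


def component_count_at(W, lam: float) -> int:
    """Connected-component count of the subgraph keeping edges of weight
    <= ``lam``, by direct graph traversal (the slow, assumption-free route)."""
    w = _as_weight_matrix(W)
    n = w.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    keep = np.isfinite(w[iu, ju]) & (w[iu, ju] <= lam)
    G.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    return nx.number_connected_components(G)


def persistence_indices(
    W,
    *,
    ipf_formula: str = "discrete",
    sampling: str = "breakpoints",
    n_grid: int = 101,
) -> tuple[float, float]:
    """Convenience: ``(ipf_index, bnp_index)`` of one weighted network."""
    f = maximal_graph_filtration(W)
    ipf = slope_index(ipf_curve(f, ipf_formula), sampling, n_grid)
    bnp = slope_index(betti0_curve(f), sampling, n_grid)
    return ipf, bnp


class PersistentFeatureTransformer(BaseEstimator, TransformerMixin):
    """Weighted networks -> per-subject ``[ipf_index, bnp_index]`` features.

    Operates on the original (unthresholded) weighted networks: the graph
    filtration scans all thresholds itself, which is the point of the method.
    """

    def __init__(
        self, ipf_formula: str = "discrete", sampling: str = "breakpoints", n_grid: int = 101
    ):
        self.ipf_formula = ipf_formula
        self.sampling = sampling
        self.n_grid = n_grid

    def fit(self, X, y=None):
        X = list(X)
        if not X:
            raise ValidationError("empty cohort")
        self.n_subjects_ = len(X)
        return self

    def transform(self, X) -> np.ndarray:
        out = [
            persistence_indices(
                W, ipf_formula=self.ipf_formula, sampling=self.sampling, n_grid=self.n_grid
            )
            for W in X
        ]
        return np.asarray(out, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["ipf_index", "bnp_index"], dtype=object)
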