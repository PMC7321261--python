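"""Weighted network construction from fiber-connection profiles.

The canonical edge definition is one minus the Pearson correlation between
the fiber-connection profiles of two regions,

    w_ij = 1 - cov(T_i, T_j) / (sigma_i * sigma_j),

where ``T_i`` is row ``i`` of the subject's fiber-count matrix. Weights lie
in [0, 2]; a weight near 0 means a strong association, so weights act
directly as lengths in the path-based graph indices. Alternative edge
definitions (rank correlation, absolute Pearson, shrinkage-regularised
partial correlation, or a directly supplied association matrix such as an
FA-weighted one) are selected with ``method``.

By default the full length-R profile rows are correlated, self-entries (which
are structural zeros) included; ``exclude_pair=True`` drops entries ``i`` and
``j`` from both profiles before correlating, as some connectome studies do.

For graph-theoretic indices the weighted network is additionally thresholded
by keeping only edges whose underlying correlation is significant after
Bonferroni correction across all R(R-1)/2 edges (two-sided t-test on r with
R-2 degrees of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import FiberProfileMatrix
from .exceptions import (
    ConfigError,
    DegenerateProfileError,
    NumericalError,
    UnsupportedThresholdError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "WeightedNetwork",
    "ThresholdedNetwork",
    "pearson_distance_network",
    "build_network",
    "threshold_significant",
    "ConnectomeTransformer",
    "SignificanceThreshold",
]

METHODS = ("pearson_1minus", "pearson_abs", "spearman_1minus", "partial_1minus", "direct")

# weight ranges per method, with a little float slack applied before clipping
_RANGES = {
    "pearson_1minus": (0.0, 2.0),
    "spearman_1minus": (0.0, 2.0),
    "partial_1minus": (0.0, 2.0),
    "pearson_abs": (0.0, 1.0),
    "direct": (0.0, np.inf),
}


@dataclass
class WeightedNetwork:
    """Symmetric dissimilarity-weighted network over labelled regions.

    ``corr`` retains the underlying correlation matrix for correlation-based
    methods (needed for significance thresholding); ``n_profile`` is the
    length of the profiles that were correlated (sets the degrees of freedom
    of the per-edge t-test).
    """

    weights: np.ndarray
    region_labels: list[str]
    method_tag: str = "direct"
    corr: np.ndarray | None = None
    n_profile: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weights must be square, got shape {w.shape}")
        if len(self.region_labels) != w.shape[0]:
            raise ValidationError(
                f"{len(self.region_labels)} region labels for {w.shape[0]} regions"
            )
        if self.method_tag not in METHODS:
            raise ValidationError(f"method_tag must be one of {METHODS}, got {self.method_tag!r}")
        if not np.all(np.isfinite(w)):
            raise ValidationError("weights contain non-finite entries")
        if not np.allclose(w, w.T, atol=1e-9):
            i, j = np.argwhere(~np.isclose(w, w.T, atol=1e-9))[0]
            raise ValidationError(
                f"weights not symmetric: entry ({self.region_labels[i]}, {self.region_labels[j]})"
            )
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        lo, hi = _RANGES[self.method_tag]
        if np.any(w < lo - 1e-8) or np.any(w > hi + 1e-8):
            raise ValidationError(
                f"weights outside the documented range [{lo}, {hi}] for method {self.method_tag!r}"
            )
        self.weights = np.clip(w, lo, None if np.isinf(hi) else hi)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdedNetwork:
    """A weighted network with non-significant edges marked absent.

    ``mask`` is True where an edge survived; surviving edges keep their
    original weight. Absence is symmetric and the diagonal is always absent.
    """

    weights: np.ndarray
    mask: np.ndarray
    region_labels: list[str]
    alpha: float
    n_tests: int
    method_tag: str = "direct"
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.weights.shape:
            raise ValidationError("mask and weights shapes differ")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValidationError("edge-absence mask is not symmetric")
        m = self.mask.copy()
        np.fill_diagonal(m, False)
        self.mask = m

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def _profiles(T: FiberProfileMatrix) -> np.ndarray:
    return np.asarray(T.counts, dtype=float)


def _check_degenerate(rows: np.ndarray, labels, on_degenerate: str) -> np.ndarray:
    """Return boolean array marking zero-variance profiles, honouring policy."""
    degenerate = rows.std(axis=1) == 0
    if degenerate.any():
        bad = [labels[i] for i in np.flatnonzero(degenerate)]
        if on_degenerate == "raise":
            raise DegenerateProfileError(bad)
        logger.warning(
            "zero-variance profile for region(s) %s; assigning weight 1 to their edges",
            ", ".join(map(str, bad)),
        )
    return degenerate


def _corr_full(counts: np.ndarray, rank: bool) -> np.ndarray:
    rows = sps.rankdata(counts, axis=1) if rank else counts
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(rows)
    return r


def _corr_exclude_pair(counts: np.ndarray, rank: bool) -> np.ndarray:
    """Correlate profiles dropping entries i and j from both rows per pair."""
    n = counts.shape[0]
    r = np.eye(n)
    idx = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = (idx != i) & (idx != j)
            a, b = counts[i, keep], counts[j, keep]
            if rank:
                a, b = sps.rankdata(a), sps.rankdata(b)
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                rij = np.nan
            else:
                rij = float(np.corrcoef(a, b)[0, 1])
            r[i, j] = r[j, i] = rij
    return r


def pearson_distance_network(
    T: FiberProfileMatrix,
    *,
    exclude_pair: bool = False,
    on_degenerate: str = "raise",
) -> WeightedNetwork:
    """1 - Pearson correlation of fiber-connection profiles; weights in [0, 2]."""
    return build_network(T, "pearson_1minus", exclude_pair=exclude_pair, on_degenerate=on_degenerate)


def _partial_corr(counts: np.ndarray, shrinkage: float) -> np.ndarray:
    """Partial correlation between profiles from a shrinkage-regularised
    inverse covariance (shrunk toward its diagonal)."""
    cov = np.cov(counts)
    shrunk = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    try:
        prec = np.linalg.inv(shrunk)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "shrunk profile covariance is singular; increase the shrinkage "
            "intensity (e.g. shrinkage=0.5) or check for constant profiles"
        ) from exc
    d = np.sqrt(np.diag(prec))
    with np.errstate(invalid="ignore", divide="ignore"):
        partial = -prec / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial


def build_network(
    T: FiberProfileMatrix | np.ndarray,
    method: str = "pearson_1minus",
    *,
    exclude_pair: bool = False,
    shrinkage: float = 0.1,
    on_degenerate: str = "raise",
    region_labels: list[str] | None = None,
) -> WeightedNetwork:
    """Build a weighted network from a fiber-profile matrix.

    ``method='direct'`` validates and passes through an already-formed
    association matrix (e.g. FA-weighted) unchanged.
    """
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; expected one of {METHODS}")
    if on_degenerate not in ("raise", "unit"):
        raise ConfigError(f"on_degenerate must be 'raise' or 'unit', got {on_degenerate!r}")

    if method == "direct":
        if isinstance(T, FiberProfileMatrix):
            w, labels = T.counts, T.region_labels
        else:
            w = np.asarray(T, dtype=float)
            labels = region_labels or [f"ROI{i + 1:03d}" for i in range(w.shape[0])]
        return WeightedNetwork(w, list(labels), method_tag="direct")

    if not isinstance(T, FiberProfileMatrix):
        T = FiberProfileMatrix(
            np.asarray(T, dtype=float),
            region_labels or [f"ROI{i + 1:03d}" for i in range(np.asarray(T).shape[0])],
        )
    counts = _profiles(T)
    n = counts.shape[0]
    degenerate = _check_degenerate(counts, T.region_labels, on_degenerate)

    if method == "partial_1minus":
        if exclude_pair:
            raise ConfigError("exclude_pair is not defined for partial correlation")
        r = _partial_corr(counts, shrinkage)
        n_profile = n
    else:
        rank = method == "spearman_1minus"
        r = _corr_exclude_pair(counts, rank) if exclude_pair else _corr_full(counts, rank)
        n_profile = n - 2 if exclude_pair else n

    # degenerate profiles (or pairwise-degenerate exclusions) yield nan
    # correlations; treat them as "no association": r = 0, weight 1
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)

    weights = np.abs(r) if method == "pearson_abs" else 1.0 - r
    np.fill_diagonal(weights, 0.0)
    if degenerate.any():  # only reachable with on_degenerate='unit'
        bad = degenerate
        weights[bad, :] = weights[:, bad] = 1.0 if method != "pearson_abs" else 0.0
        np.fill_diagonal(weights, 0.0)
    return WeightedNetwork(
        weights, list(T.region_labels), method_tag=method, corr=r, n_profile=n_profile
    )


def correlation_pvalues(r: np.ndarray, n_profile: int) -> np.ndarray:
    """Two-sided p-values for correlation coefficients via the t-transform
    ``t = r * sqrt(df / (1 - r^2))`` with ``df = n_profile - 2``."""
    df = n_profile - 2
    if df < 1:
        raise ValidationError(f"need profiles of length >= 3 for a correlation test, got {n_profile}")
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    return p


def threshold_significant(
    W: WeightedNetwork,
    alpha: float = 0.05,
    *,
    on_unsupported: str = "raise",
) -> ThresholdedNetwork:
    """Keep only edges whose correlation is Bonferroni-significant.

    An edge survives when ``p * n_tests < alpha`` with ``n_tests =
    R(R-1)/2``; surviving edges keep their original weight. ``alpha >= 1``
    disables thresholding. Networks without an underlying correlation
    (``method_tag='direct'``) cannot be thresholded; ``on_unsupported='keep'``
    keeps all edges instead of raising.
    """
    n = W.n_regions
    n_tests = n * (n - 1) // 2
    off = ~np.eye(n, dtype=bool)
    if W.corr is None or W.n_profile is None:
        if on_unsupported == "keep":
            logger.warning(
                "no correlation p-values for method %r; keeping all edges", W.method_tag
            )
            return ThresholdedNetwork(
                W.weights, off, W.region_labels, alpha, n_tests, W.method_tag, 0
            )
        raise UnsupportedThresholdError(
            f"method {W.method_tag!r} carries no correlation p-values; "
            "pass on_unsupported='keep' to keep all edges"
        )
    if alpha >= 1.0:
        return ThresholdedNetwork(W.weights, off, W.region_labels, alpha, n_tests, W.method_tag, 0)
    p = correlation_pvalues(W.corr, W.n_profile)
    mask = (p * n_tests < alpha) & off
    mask &= mask.T
    n_removed = int(np.sum(off & ~mask) // 2)
    if n_removed:
        logger.info("Bonferroni threshold removed %d of %d edges", n_removed, n_tests)
    return ThresholdedNetwork(W.weights, mask, W.region_labels, alpha, n_tests, W.method_tag, n_removed)


class ConnectomeTransformer(BaseEstimator, TransformerMixin):
    """Per-subject fiber-count matrices -> weighted networks.

    A stateless sklearn-style transformer: ``fit`` only validates and records
    the region count, ``transform`` maps a sequence of
    :class:`FiberProfileMatrix` (or raw square arrays) to a list of
    :class:`WeightedNetwork`.

    Parameters
    ----------
    method : one of ``METHODS``.
    exclude_pair : drop entries i, j from the profiles before correlating.
    shrinkage : diagonal shrinkage intensity for partial correlation.
    on_degenerate : ``'raise'`` or ``'unit'`` for zero-variance profiles.
    """

    def __init__(
        self,
        method: str = "pearson_1minus",
        exclude_pair: bool = False,
        shrinkage: float = 0.1,
        on_degenerate: str = "raise",
    ):
        self.method = method
        self.exclude_pair = exclude_pair
        self.shrinkage = shrinkage
        self.on_degenerate = on_degenerate

    def fit(self, X, y=None):
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; expected one of {METHODS}")
        X = list(X)
        if not X:
            raise ValidationError("empty cohort")
        first = X[0].counts if isinstance(X[0], FiberProfileMatrix) else np.asarray(X[0])
        self.n_regions_ = first.shape[0]
        self.n_subjects_ = len(X)
        return self

    def transform(self, X) -> list[WeightedNetwork]:
        return [
            build_network(
                T,
                self.method,
                exclude_pair=self.exclude_pair,
                shrinkage=self.shrinkage,
                on_degenerate=self.on_degenerate,
            )
            for T in X
        ]


class SignificanceThreshold(BaseEstimator, TransformerMixin):
    """Bonferroni edge thresholding as a transformer over weighted networks."""

    def __init__(self, alpha: float = 0.05, on_unsupported: str = "raise"):
        self.alpha = alpha
        self.on_unsupported = on_unsupported

    def fit(self, X, y=None):
        X = list(X)
        if not X:
            raise ValidationError("empty cohort")
        self.n_regions_ = X[0].n_regions
        self.n_tests_ = self.n_regions_ * (self.n_regions_ - 1) // 2
        return self

    def transform(self, X) -> list[ThresholdedNetwork]:
        return [threshold_significant(W, self.alpha, on_unsupported=self.on_unsupported) for W in X]
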