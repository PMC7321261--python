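"""Nonparametric group comparison of network indices.

Two tests, mirroring how brain-network group studies report them:

* an omnibus Kruskal-Wallis rank test across all diagnostic groups
  (tie-corrected H, chi-squared p with k-1 degrees of freedom), and
* a two-sided permutation test of the difference of group means for every
  unordered pair of groups: the pooled values are randomly re-split into the
  original group sizes, the mean difference recomputed per draw, and the
  p-value read off the empirical null distribution.

The sampled permutation p uses add-one smoothing, p = (1 + #{|D*| >= |D|}) /
(1 + n_perm), the standard Monte-Carlo estimator that never returns 0. When
``n_perm`` is at least the number of distinct splits the test switches to
exact enumeration over all C(m+n, m) splits (no smoothing needed — the
identity split guarantees p > 0).

No multiple-testing correction is applied across indices or contrasts by
default; significance is reported as flags at alpha = 0.05 (pairwise) and
0.01 (omnibus).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "kruskal_wallis",
    "permutation_test",
    "compare_all",
    "derive_seed",
]

#: tolerance used when comparing |D*| against |D| (guards float round-off in
#: the permutation tail count)
_TAIL_TOL = 1e-12


@dataclass
class ComparisonResult:
    """One statistical comparison of one network index."""

    index_name: str
    comparison: str
    test: str  # 'kruskal_wallis' or 'permutation'
    statistic: float
    p_value: float
    n_permutations: int | None = None
    seed: int | None = None
    mode: str | None = None  # 'sampled' or 'exact' for permutation tests

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 or np.isnan(self.p_value)):
            # exact-enumeration p can be as small as 1/n_splits but never 0
            if self.p_value == 0.0 and self.test == "kruskal_wallis":
                return  # chi2 tail can underflow to 0 for huge H; keep as is
            raise ValidationError(f"p_value {self.p_value!r} outside (0, 1]")


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-squared p across >= 2 samples.

    All values identical across all groups is a degenerate case: there is no
    rank information, so (H, p) = (0, 1) with a log message.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValidationError("every group must contain at least one value")
    if sum(len(g) for g in groups) < 3:
        raise ValidationError("Kruskal-Wallis needs at least three values in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        logger.info("all values identical across groups; H = 0, p = 1")
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _exact_permutation_p(pool: np.ndarray, m: int, observed: float) -> tuple[float, int]:
    n_total = len(pool)
    total = pool.sum()
    n_splits = comb(n_total, m)
    n = n_total - m
    count = 0
    for idx in combinations(range(n_total), m):
        mean_a = pool[list(idx)].sum() / m
        mean_b = (total - mean_a * m) / n
        if abs(mean_a - mean_b) >= abs(observed) - _TAIL_TOL:
            count += 1
    return count / n_splits, n_splits


def _sampled_permutation_p(
    pool: np.ndarray, m: int, observed: float, n_perm: int, rng: np.random.Generator
) -> float:
    n_total = len(pool)
    n = n_total - m
    total = pool.sum()
    count = 0
    chunk = max(1, min(n_perm, 200_000 // max(n_total, 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        keys = rng.random((k, n_total))
        order = np.argsort(keys, axis=1)
        sum_a = np.take_along_axis(np.broadcast_to(pool, (k, n_total)), order[:, :m], axis=1).sum(axis=1)
        diff = sum_a / m - (total - sum_a) / n
        count += int(np.sum(np.abs(diff) >= abs(observed) - _TAIL_TOL))
        done += k
    return (1 + count) / (1 + n_perm)


def permutation_test(
    a,
    b,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    index_name: str = "",
    comparison: str = "A vs B",
) -> ComparisonResult:
    """Two-sided permutation test of the difference of means between two samples.

    The statistic is the observed ``mean(a) - mean(b)``. Falls back to exact
    enumeration of all splits when ``n_perm`` covers them (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = len(a), len(b)
    if m < 2 or n < 2:
        raise ValidationError(f"both samples need >= 2 values, got sizes {m} and {n}")
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    observed = float(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    n_splits = comb(m + n, m)
    if n_perm >= n_splits:
        logger.info(
            "n_perm=%d covers all %d distinct splits; using exact enumeration", n_perm, n_splits
        )
        p, n_eff = _exact_permutation_p(pool, m, observed)
        mode = "exact"
    else:
        rng = np.random.default_rng(seed)
        p = _sampled_permutation_p(pool, m, observed, n_perm, rng)
        n_eff = n_perm
        mode = "sampled"
    return ComparisonResult(
        index_name=index_name,
        comparison=comparison,
        test="permutation",
        statistic=observed,
        p_value=float(p),
        n_permutations=n_eff,
        seed=seed,
        mode=mode,
    )


def derive_seed(base_seed: int, name: str) -> int:
    """Deterministic child seed (< 2**31) from a base seed and a label."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


def compare_all(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    indices: list[str] | None = None,
    alpha_pairwise: float = 0.05,
    alpha_omnibus: float = 0.01,
) -> pd.DataFrame:
    """Omnibus + pairwise comparisons for every index column of an index table.

    ``table`` needs a ``group`` column; index columns default to every other
    numeric column. Returns one row per (index, comparison) with significance
    flags (reporting only — no values are filtered). Pairwise seeds are
    derived deterministically from ``seed`` and the comparison name, so any
    single row can be reproduced in isolation.
    """
    if "group" not in table.columns:
        raise ValidationError("index table must have a 'group' column")
    if table.isna().any().any():
        raise ValidationError("index table contains missing values")
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    if indices is None:
        indices = [
            c
            for c in table.columns
            if c not in ("subject_id", "group") and np.issubdtype(table[c].dtype, np.number)
        ]
    if not indices:
        raise ValidationError("no numeric index columns found")

    rows = []
    omnibus_label = " vs ".join(groups)
    for ix in indices:
        samples = {g: table.loc[table["group"] == g, ix].to_numpy(float) for g in groups}
        h, p = kruskal_wallis(list(samples.values()))
        rows.append(
            ComparisonResult(ix, omnibus_label, "kruskal_wallis", h, p).__dict__
            | {"significant": p < alpha_omnibus}
        )
        for ga, gb in combinations(groups, 2):
            label = f"{ga} vs {gb}"
            child = derive_seed(seed, f"{ix}|{label}")
            res = permutation_test(
                samples[ga], samples[gb], n_perm, child, index_name=ix, comparison=label
            )
            rows.append(res.__dict__ | {"significant": res.p_value < alpha_pairwise})
    return pd.DataFrame(rows)
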