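"""Permutation-based inference for association and relatedness structure.

Three tests make up the statistical layer:

* :func:`node_permutation_test` — does a binary node attribute (sex, age)
  predict a node metric (strength or degree)? The network is held fixed
  and attribute labels are shuffled across nodes; two-tailed p with the
  observed statistic included in the reference set, p = (b + 1)/(m + 1).
* :func:`mantel_test` — Spearman correlation between two symmetric
  matrices over the same nodes (e.g. association counts vs relatedness),
  with a node-relabeling permutation null.
* :func:`wilcoxon_rank_sum` — rank-sum comparison of two samples
  (e.g. MM vs FF relatedness values), exact by enumeration for small
  tie-free samples, otherwise normal approximation with tie and
  continuity corrections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "PermutationResult",
    "MantelResult",
    "RankSumResult",
    "node_permutation_test",
    "mantel_test",
    "wilcoxon_rank_sum",
    "binary_node_attribute",
]


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    statistic: str

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "statistic": self.statistic,
        }
        if include_null:
            d["null"] = self.null.tolist()
        return d


@dataclass
class MantelResult:
    correlation: float
    p_value: float
    n_perm: int
    seed: int | None
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "correlation": self.correlation,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_pairs": self.n_pairs,
        }


@dataclass
class RankSumResult:
    w: float
    p_value: float
    p_less: float
    p_greater: float
    n1: int
    n2: int
    method: str

    def to_dict(self) -> dict:
        return {
            "W": self.w,
            "p_value": self.p_value,
            "p_less": self.p_less,
            "p_greater": self.p_greater,
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# node permutation test
# ---------------------------------------------------------------------------

_ATTRIBUTE_LEVELS = {
    # level-1 / level-0 encodings for the standard binary node attributes
    "sex": {"male": 1, "female": 0},
    "age_class": {"adult": 1, "elderly": 1, "sub-adult": 0},
}


def binary_node_attribute(net: nx.Graph, attribute: str) -> dict[str, int]:
    """Binary labels for nodes with an interpretable attribute value.

    Sex maps male=1 / female=0; age maps adult (including elderly)=1 /
    sub-adult=0. Nodes with other values (unknown, cub) are omitted. Any
    other attribute must already be 0/1-valued on the nodes.
    """
    mapping = _ATTRIBUTE_LEVELS.get(attribute)
    labels: dict[str, int] = {}
    for v, data in net.nodes(data=True):
        raw = data.get(attribute)
        if mapping is not None:
            if raw in mapping:
                labels[v] = mapping[raw]
        elif raw in (0, 1):
            labels[v] = int(raw)
    return labels


def node_permutation_test(
    net: nx.Graph,
    attribute: str = "sex",
    metric: str = "strength",
    n_perm: int = 1000,
    seed: int | None = None,
    statistic: str = "mean_diff",
) -> PermutationResult:
    """Node-permutation test of a binary attribute's effect on a node metric.

    The observed statistic is the difference in mean metric between the
    two attribute levels (level 1 minus level 0); with
    ``statistic='std_coef'`` the metric is z-scored over the tested nodes
    first, giving an effect size on the standardized scale (identical
    p-value for a binary attribute). The null shuffles attribute labels
    over the tested nodes while the network — and hence each node's metric
    — stays fixed. Two-tailed p compares |statistic|, with the observed
    value included in the reference set: p = (b + 1) / (n_perm + 1).
    """
    if metric not in ("strength", "degree"):
        raise ValueError("metric must be 'strength' or 'degree'")
    if statistic not in ("mean_diff", "std_coef"):
        raise ValueError("statistic must be 'mean_diff' or 'std_coef'")
    labels = binary_node_attribute(net, attribute)
    nodes = sorted(labels)
    y = np.array([labels[v] for v in nodes])
    if y.min() == y.max() or len(nodes) < 2:
        raise ValueError(f"degenerate attribute {attribute!r}: need both levels")
    weight = "weight" if metric == "strength" else None
    x = np.array([net.degree(v, weight=weight) for v in nodes], dtype=float)
    if statistic == "std_coef":
        sd = x.std(ddof=1)
        x = (x - x.mean()) / sd if sd > 0 else x - x.mean()

    def stat(lab: np.ndarray) -> float:
        return float(x[lab == 1].mean() - x[lab == 0].mean())

    observed = stat(y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = stat(rng.permutation(y))
    b = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (b + 1) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        null=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        statistic=f"{statistic}[{metric} | {attribute}]",
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _check_square_symmetric(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    finite = ~np.isnan(m)
    if not np.array_equal(finite, finite.T) or not np.allclose(
        m[finite & finite.T], m.T[finite & finite.T], equal_nan=True
    ):
        raise ValueError(f"{name} must be symmetric")
    return m


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    valid = ~np.isnan(a) & ~np.isnan(b)
    ra = stats.rankdata(a[valid])
    rb = stats.rankdata(b[valid])
    if ra.std() == 0 or rb.std() == 0:
        return float("nan")
    return float(np.corrcoef(ra, rb)[0, 1])


def mantel_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test with Spearman correlation over off-diagonal pairs.

    Correlates the strict lower triangles of two symmetric matrices over
    the same node ordering (NaN cells excluded pairwise); the null applies
    one random simultaneous row/column permutation to ``b`` per iteration.
    Two-tailed p with the observed correlation included in the reference
    set.
    """
    a = _check_square_symmetric(a, "a")
    b = _check_square_symmetric(b, "b")
    n = a.shape[0]
    if b.shape[0] != n:
        raise ValueError("matrices must have the same node set")
    if n < 4:
        raise ValueError("mantel test needs >= 4 nodes (permutation space too small)")
    il = np.tril_indices(n, k=-1)
    va = a[il]
    observed = _spearman(va, b[il])
    if not np.isfinite(observed):
        raise ValueError("degenerate matrices: constant off-diagonal ranks")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        null[k] = _spearman(va, b[np.ix_(perm, perm)][il])
    bcount = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (bcount + 1) / (n_perm + 1)
    n_pairs = int(np.sum(~np.isnan(va) & ~np.isnan(b[il])))
    return MantelResult(
        correlation=observed, p_value=p, n_perm=n_perm, seed=seed, n_pairs=n_pairs
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(
    sample1,
    sample2,
    exact_limit: int = 12,
    continuity: bool = True,
) -> RankSumResult:
    """Wilcoxon rank-sum test; W is the rank-sum of ``sample1``.

    Pooled observations are mid-ranked. With ``n1 + n2 <= exact_limit``
    and no ties the null distribution of W is enumerated exactly over all
    C(N, n1) rank assignments; otherwise a normal approximation with tie
    correction (and continuity correction by default) is used. Two-tailed
    p is 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < pooled.size

    if n1 + n2 <= exact_limit and not has_ties:
        all_ranks = np.arange(1, n1 + n2 + 1)
        sums = np.array(
            [sum(c) for c in itertools.combinations(all_ranks, n1)], dtype=float
        )
        p_less = float(np.mean(sums <= w + 1e-12))
        p_greater = float(np.mean(sums >= w - 1e-12))
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * (n + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            # all pooled values identical: W is degenerate at mu
            return RankSumResult(w, 1.0, 1.0, 1.0, n1, n2, "degenerate")
        sd = math.sqrt(var)
        cc = 0.5 if continuity else 0.0
        p_less = float(stats.norm.cdf((w - mu + cc) / sd))
        p_greater = float(stats.norm.sf((w - mu - cc) / sd))
        method = "normal"
    p_two = min(1.0, 2.0 * min(p_less, p_greater))
    return RankSumResult(w, p_two, p_less, p_greater, n1, n2, method)
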