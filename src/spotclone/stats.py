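"""Statistics used across the pipeline.

Heterogeneity index, region-R² spatial-variance fraction, Moran's I,
Mann-Whitney U with an exact/asymptotic switch, log-space hypergeometric
enrichment, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from scipy.special import logsumexp

__all__ = [
    "HeterogeneityIndex",
    "heterogeneity_index",
    "spatial_variance_fraction",
    "morans_i",
    "mann_whitney_u",
    "hypergeometric_enrichment",
    "bh_adjust",
    "EXACT_MW_MAX_N",
]

#: combined sample size at or below which Mann-Whitney p-values are exact
EXACT_MW_MAX_N = 16


@dataclass
class HeterogeneityIndex:
    """Number of expression regions (≥ min_spots spots each) per Visium spot."""

    sample_id: str
    n_clusters_kept: int
    n_spots: int
    index: float


def heterogeneity_index(
    labels, n_spots: int, min_spots: int = 5, sample_id: str = ""
) -> HeterogeneityIndex:
    """Count clusters with ≥ ``min_spots`` members, normalized by spot count.

    Clusters below the size threshold are excluded so that the index
    reflects genuine tissue regions rather than clustering noise.
    """
    if n_spots <= 0:
        raise ValueError("n_spots must be positive")
    labels = np.asarray(labels)
    _, sizes = np.unique(labels, return_counts=True)
    kept = int((sizes >= min_spots).sum())
    return HeterogeneityIndex(sample_id, kept, int(n_spots), kept / n_spots)


def spatial_variance_fraction(values, labels) -> float:
    """Fraction of a gene's variance explained by tissue regions (an R²).

    1 − pooled within-region variance / total variance.  Invariant to
    affine transforms of the values; requires non-constant input.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must align")
    total_ss = float(((values - values.mean()) ** 2).sum())
    if total_ss == 0:
        raise ValueError("values are constant; fraction undefined")
    within_ss = 0.0
    for lab in np.unique(labels):
        v = values[labels == lab]
        within_ss += float(((v - v.mean()) ** 2).sum())
    return 1.0 - within_ss / total_ss


def morans_i(values, graph, node_order=None) -> float:
    """Moran's I spatial autocorrelation on a spot graph.

    Uses row-normalized adjacency weights:
    I = (n / S0) · Σ_ij w_ij z_i z_j / Σ_i z_i² with z the centred values.
    Undefined (error) for constant values.
    """
    values = np.asarray(values, dtype=float)
    nodes = list(graph.nodes) if node_order is None else list(node_order)
    n = len(nodes)
    if n < 2 or len(values) != n:
        raise ValueError("need one value per node, at least 2 nodes")
    z = values - values.mean()
    denom = float((z**2).sum())
    if denom == 0:
        raise ValueError("Moran's I undefined for constant values")
    index = {node: i for i, node in enumerate(nodes)}
    num = 0.0
    s0 = 0.0
    for node in nodes:
        nbrs = [index[v] for v in graph.neighbors(node) if v in index]
        if not nbrs:
            continue
        w = 1.0 / len(nbrs)
        s0 += w * len(nbrs)
        num += w * z[index[node]] * z[nbrs].sum()
    if s0 == 0:
        raise ValueError("graph has no edges among the given nodes")
    return float((n / s0) * num / denom)


def mann_whitney_u(x, y, alternative: str = "two_sided") -> dict:
    """Mann-Whitney U test.

    Exact p by enumeration when n_x + n_y ≤ 16 and the pooled sample has
    no ties; otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # every observation tied: no evidence either way
        return {"U": len(x) * len(y) / 2.0, "p": 1.0, "method": "degenerate"}
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= EXACT_MW_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative=alt, method=method)
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0)), "method": method}


def hypergeometric_enrichment(
    hits_in_set: int, set_size: int, hits_total: int, universe: int
) -> float:
    """Upper-tail enrichment p-value P(X ≥ hits_in_set).

    X ~ Hypergeometric(universe, hits_total, set_size); the tail is summed
    in log-space so that very small p-values keep full precision.
    """
    if not (0 <= hits_in_set <= min(set_size, hits_total)):
        raise ValueError("hits_in_set inconsistent with set_size / hits_total")
    if set_size > universe or hits_total > universe:
        raise ValueError("set or hit count exceeds universe")
    if hits_in_set == 0:
        return 1.0
    kmax = min(set_size, hits_total)
    ks = np.arange(hits_in_set, kmax + 1)
    logp = scipy.stats.hypergeom.logpmf(ks, universe, hits_total, set_size)
    return float(min(np.exp(logsumexp(logp)), 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
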