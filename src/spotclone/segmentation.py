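"""Spot-graph construction and the two clustering engines.

``segment_spatial`` is a Potts-smoothed K-means optimized by iterated
conditional modes (ICM): neighbouring spots get a bonus ``beta`` for
sharing a label, encoding the assumption that spots in close proximity are
more likely to belong to the same tissue region.  ``cluster_expression``
is the non-spatial control: PCA, kNN graph, modularity (Leiden) community
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

__all__ = [
    "SegmentationResult",
    "build_spot_graph",
    "segment_spatial",
    "potts_energy",
    "cluster_expression",
]


@dataclass
class SegmentationResult:
    """Per-spot cluster labels with provenance."""

    labels: np.ndarray  # dense ids in [0, K)
    K: int
    nodes: list
    params: dict = field(default_factory=dict)
    n_changed_per_iter: list = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.nodes, name="cluster")


def build_spot_graph(positions: pd.DataFrame, max_dist_um: float | None = None) -> nx.Graph:
    """Adjacency graph of spot centres.

    ``positions`` needs ``x_um``/``y_um`` columns indexed by spot id.  Two
    spots are adjacent iff their Euclidean distance is ≤ ``max_dist_um``
    (boundary inclusive).  The default 1.2 × the minimum nonzero centre
    spacing captures the six hexagonal neighbours while excluding the
    second ring.
    """
    if len(positions) < 2:
        raise ValueError("need at least 2 spots")
    xy = positions[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    if max_dist_um is None:
        d, _ = tree.query(xy, k=2)
        min_spacing = float(d[:, 1].min())
        if min_spacing == 0:
            raise ValueError("coincident spot centres")
        max_dist_um = 1.2 * min_spacing
    graph = nx.Graph()
    graph.add_nodes_from(positions.index)
    ids = list(positions.index)
    # small epsilon so spots at exactly max_dist are included despite fp error
    pairs = tree.query_pairs(max_dist_um * (1 + 1e-12))
    graph.add_edges_from((ids[i], ids[j]) for i, j in pairs)
    graph.graph["max_dist_um"] = float(max_dist_um)
    return graph


def potts_energy(features, labels, centroids, edges, beta: float) -> float:
    """Σ_s ‖f_s − µ_{l(s)}‖² − beta · Σ_{(s,t)∈E} 1[l(s) = l(t)]."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    data_term = float(((features - centroids[labels]) ** 2).sum())
    smooth = sum(1 for i, j in edges if labels[i] == labels[j])
    return data_term - beta * smooth


def segment_spatial(
    features,
    graph: nx.Graph,
    K: int,
    beta: float | None = None,
    max_iter: int = 50,
    seed: int = 0,
    nodes: list | None = None,
    n_restarts: int = 3,
    allow_merge: bool = True,
) -> SegmentationResult:
    """Spatially smoothed segmentation of spots into K clusters.

    Labels are initialized by seeded K-means on the features and refined by
    ICM sweeps in fixed spot order: each spot takes the label minimizing
    ‖f_s − µ_k‖² − beta · (# neighbours with label k), retaining its
    current label on ties; centroids are recomputed after each sweep.
    ``beta`` defaults to 0.5 × the median within-cluster squared distance
    at the first initialization; ``beta = 0`` reduces to plain K-means
    refinement.  ICM is a greedy descent, so ``n_restarts`` independent
    seeded initializations are run and the lowest-energy labeling kept
    (restart seeds derive from ``seed``; the first restart uses ``seed``
    itself, preserving the beta=0 K-means reduction).  With
    ``allow_merge`` the effective cluster count may drop below K when
    adjacent clusters are not genuinely distinct; disable it to force
    exactly K clusters (as in two-clone mapping).
    """
    if isinstance(features, pd.DataFrame):
        nodes = list(features.index) if nodes is None else nodes
        features = features.to_numpy(dtype=float)
    features = np.asarray(features, dtype=float)
    if nodes is None:
        nodes = list(graph.nodes)
    n = len(nodes)
    if features.shape[0] != n:
        raise ValueError("features rows must match node count")
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite features")
    if K < 2 or K > n:
        raise ValueError("need 2 <= K <= number of spots")

    index = {node: i for i, node in enumerate(nodes)}
    neighbors = [
        np.array([index[v] for v in graph.neighbors(u) if v in index], dtype=int)
        for u in nodes
    ]
    edges = [
        (index[u], index[v]) for u, v in graph.edges if u in index and v in index
    ]

    best = None
    for restart in range(max(1, n_restarts)):
        km_seed = seed if restart == 0 else seed + 1009 * restart
        km = KMeans(n_clusters=K, random_state=km_seed, n_init=10)
        labels = km.fit_predict(features)
        centroids = km.cluster_centers_.copy()
        if beta is None:  # calibrated once, on the first initialization
            d2 = ((features - centroids[labels]) ** 2).sum(axis=1)
            beta = 0.5 * float(np.median(d2))

        trace: list = []
        budget = max_iter
        for _outer in range(10):
            budget = _icm_sweeps(
                features, labels, centroids, neighbors, K, beta, budget, trace
            )
            # agglomerative phase: merge adjacent clusters whenever the
            # data-term cost of pooling them is outweighed by the smoothness
            # gain along their shared boundary.  Strictly energy-decreasing;
            # never fires at beta = 0, so the plain K-means reduction is
            # untouched.  This lets the effective number of clusters fall
            # below K when the sample has fewer genuinely distinct regions.
            merged = allow_merge and _merge_phase(features, labels, edges, K, beta)
            # Hartigan-style exact single-move descent: unlike the ICM step,
            # the energy change of moving one spot accounts for the centroid
            # shift the move causes, reaching unbalanced optima ICM misses.
            moved = _hartigan_phase(features, labels, neighbors, K, beta)
            if not merged and not moved:
                break
            for k in range(K):
                members = features[labels == k]
                if len(members):
                    centroids[k] = members.mean(axis=0)
            if budget <= 0:
                break
        cents = centroids.copy()
        for k in range(K):
            members = features[labels == k]
            if len(members):
                cents[k] = members.mean(axis=0)
        energy = potts_energy(features, labels, cents, edges, beta)
        if best is None or energy < best[0] - 1e-12:
            best = (energy, labels, trace)

    _, labels, trace = best
    # dense relabeling in order of first appearance
    uniq, dense = np.unique(labels, return_inverse=True)
    return SegmentationResult(
        labels=dense.astype(int),
        K=len(uniq),
        nodes=nodes,
        params={
            "method": "potts_icm",
            "K_requested": K,
            "beta": float(beta),
            "max_iter": max_iter,
            "seed": seed,
            "n_restarts": int(max(1, n_restarts)),
        },
        n_changed_per_iter=trace,
    )


def _icm_sweeps(features, labels, centroids, neighbors, K, beta, budget, trace):
    """ICM label updates in fixed spot order until convergence or budget."""
    n = len(labels)
    while budget > 0:
        budget -= 1
        changed = 0
        dist2 = ((features[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        for s in range(n):
            cost = dist2[s].copy()
            nbr = neighbors[s]
            if len(nbr) and beta != 0.0:
                agree = np.bincount(labels[nbr], minlength=K)
                cost = cost - beta * agree
            best = int(np.argmin(cost))
            cur = labels[s]
            if cost[best] < cost[cur]:  # retain current label on ties
                labels[s] = best
                changed += 1
        trace.append(changed)
        for k in range(K):
            members = features[labels == k]
            if len(members):
                centroids[k] = members.mean(axis=0)
        if changed == 0:
            break
    return budget


def _hartigan_phase(
    features, labels, neighbors, K, beta, max_sweeps: int = 20
) -> bool:
    """Single-spot moves accepted on the exact energy change.

    Moving spot s from cluster a (size n_a) to b (size n_b) changes the
    data term by n_b/(n_b+1)·‖x−µ_b‖² − n_a/(n_a−1)·‖x−µ_a‖² and the
    smoothness term by −beta·(c_b − c_a) with c_k the same-label neighbour
    counts.  Moves that would empty a cluster are skipped (the merge phase
    owns cluster removal).  Returns True if any move was accepted.
    """
    n = len(labels)
    sizes = np.bincount(labels, minlength=K).astype(float)
    sums = np.zeros((K, features.shape[1]))
    for k in range(K):
        members = features[labels == k]
        if len(members):
            sums[k] = members.sum(axis=0)
    moved_any = False
    for _ in range(max_sweeps):
        moved = False
        for s in range(n):
            a = labels[s]
            if sizes[a] <= 1:
                continue
            x = features[s]
            mu_a = sums[a] / sizes[a]
            loss_a = sizes[a] / (sizes[a] - 1) * float(((x - mu_a) ** 2).sum())
            nbr = neighbors[s]
            counts = (
                np.bincount(labels[nbr], minlength=K) if len(nbr) else np.zeros(K)
            )
            best_b, best_delta = -1, -1e-12
            for b in range(K):
                if b == a or sizes[b] == 0:
                    continue
                mu_b = sums[b] / sizes[b]
                gain_b = sizes[b] / (sizes[b] + 1) * float(((x - mu_b) ** 2).sum())
                delta = gain_b - loss_a - beta * (counts[b] - counts[a])
                if delta < best_delta:
                    best_b, best_delta = b, delta
            if best_b >= 0:
                sums[a] -= x
                sizes[a] -= 1
                sums[best_b] += x
                sizes[best_b] += 1
                labels[s] = best_b
                moved = moved_any = True
        if not moved:
            break
    return moved_any


def _merge_phase(features, labels, edges, K, beta) -> bool:
    """Greedily merge adjacent cluster pairs while it lowers the energy.

    Merging clusters a, b raises the data term by
    n_a·n_b/(n_a+n_b)·‖µ_a−µ_b‖² and lowers the smoothness term by
    beta × (boundary edges between a and b); merge while the balance is
    negative.  Returns True if any merge happened.
    """
    if beta <= 0:
        return False
    merged_any = False
    while True:
        labs = np.unique(labels)
        if len(labs) < 2:
            return merged_any
        sizes = {l: int((labels == l).sum()) for l in labs}
        cents = {l: features[labels == l].mean(axis=0) for l in labs}
        boundary: dict = {}
        for i, j in edges:
            a, b = labels[i], labels[j]
            if a != b:
                key = (min(a, b), max(a, b))
                boundary[key] = boundary.get(key, 0) + 1
        best_pair, best_delta = None, 0.0
        for (a, b), n_edges in boundary.items():
            na, nb = sizes[a], sizes[b]
            d2 = float(((cents[a] - cents[b]) ** 2).sum())
            delta = na * nb / (na + nb) * d2 - beta * n_edges
            if delta < best_delta:
                best_pair, best_delta = (a, b), delta
        if best_pair is None:
            return merged_any
        a, b = best_pair
        labels[labels == b] = a
        merged_any = True


def _pca(features: np.ndarray, n_pcs: int) -> np.ndarray:
    centered = features - features.mean(axis=0)
    if n_pcs > min(centered.shape):
        raise ValueError("n_pcs exceeds matrix dimensions")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each PC is positive
    signs = np.sign(Vt[np.arange(len(Vt)), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    return (U * s)[:, :n_pcs] * signs[:n_pcs]


def _leiden(g: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership)


def cluster_expression(
    features,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 20,
    nodes: list | None = None,
    force_k: int | None = None,
) -> SegmentationResult:
    """Non-spatial graph-community clustering of spots.

    Reduces the features to ``n_pcs`` principal components, builds a
    ``k_neighbors``-nearest-neighbour graph and runs seeded modularity
    (Leiden) community detection at the given resolution.  With
    ``force_k`` the resolution is searched so that exactly ``force_k``
    communities result (remaining surplus communities are merged by
    closest centroids).
    """
    if isinstance(features, pd.DataFrame):
        nodes = list(features.index) if nodes is None else nodes
        features = features.to_numpy(dtype=float)
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if nodes is None:
        nodes = list(range(n))
    n_pcs_eff = min(n_pcs, min(features.shape) - 1) if min(features.shape) > 1 else 1
    pcs = _pca(features, max(n_pcs_eff, 1))

    from sklearn.neighbors import NearestNeighbors

    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)

    if force_k is None:
        membership = _leiden(g, resolution, seed)
        used_resolution = resolution
    else:
        membership, used_resolution = _force_k_communities(g, pcs, force_k, seed)
    uniq, dense = np.unique(membership, return_inverse=True)
    return SegmentationResult(
        labels=dense.astype(int),
        K=len(uniq),
        nodes=nodes,
        params={
            "method": "leiden",
            "k_neighbors": k,
            "resolution": float(used_resolution),
            "n_pcs": int(pcs.shape[1]),
            "seed": seed,
        },
    )


def _force_k_communities(g, pcs, k, seed, max_steps: int = 40):
    """Binary-search the resolution for exactly k communities; merge surplus."""
    lo, hi = 1e-5, 50.0
    best = None
    for _ in range(max_steps):
        mid = np.sqrt(lo * hi)  # geometric bisection: resolution spans decades
        membership = _leiden(g, mid, seed)
        n_comm = len(np.unique(membership))
        if n_comm == k:
            return membership, mid
        if best is None or (
            n_comm >= k and len(np.unique(best[0])) < k
        ) or (n_comm >= k and n_comm < len(np.unique(best[0]))):
            best = (membership, mid)
        if n_comm < k:
            lo = mid
        else:
            hi = mid
    membership, res = best
    # merge surplus communities by closest centroids
    membership = membership.copy()
    while len(np.unique(membership)) > k:
        labs = np.unique(membership)
        cents = np.array([pcs[membership == l].mean(axis=0) for l in labs])
        d2 = ((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        membership[membership == labs[max(i, j)]] = labs[min(i, j)]
    if len(np.unique(membership)) < k:
        raise RuntimeError(f"could not obtain {k} communities")
    return membership, res
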