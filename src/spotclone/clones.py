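"""Transcriptome-guided mapping of genetic clones onto spots.

Clones that differ in copy number leave a dosage footprint on expression:
genes in gained regions are, on average, proportionally higher expressed.
Spots are segmented into two clusters using only the CNV-informative
genes, and the cluster with the higher mean informative-gene expression is
called the gain clone (clone A, the daughter clone carrying the extra
chromothriptic event; clone B is the ancestral, mostly diploid clone).  A
non-spatial community-detection clustering of the same features serves as
a control, and FISH-style per-nucleus probe counts validate the mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .io import CloneCNVProfile
from .segmentation import SegmentationResult, cluster_expression, segment_spatial
from .stats import mann_whitney_u

__all__ = [
    "CloneMap",
    "select_clone_genes",
    "compute_clone_score",
    "map_clones",
    "concordance",
    "validate_with_fish",
]

POLARITY_TOLERANCE = 1e-9


@dataclass
class CloneMap:
    """Per-spot clone labels with scores and control-clustering provenance."""

    frame: pd.DataFrame  # barcode-indexed: clone, clone_score, margin, control_clone
    concordance_with_control: float
    gene_set: list
    params: dict = field(default_factory=dict)
    segmentation: SegmentationResult | None = None


def _differential_regions(
    p1: CloneCNVProfile, p2: CloneCNVProfile
) -> list[tuple[str, int, int]]:
    """Maximal regions where the two clones' copy numbers differ."""
    regions = []
    chroms = {c for c, *_ in p1.intervals} | {c for c, *_ in p2.intervals}
    for chrom in sorted(chroms):
        iv1 = [(s, e, cn) for c, s, e, cn in p1.intervals if c == chrom]
        iv2 = [(s, e, cn) for c, s, e, cn in p2.intervals if c == chrom]
        cuts = sorted({x for s, e, _ in iv1 + iv2 for x in (s, e)})
        for a, b in zip(cuts, cuts[1:]):
            cn1 = next((cn for s, e, cn in iv1 if s <= a and b <= e), p1.ploidy)
            cn2 = next((cn for s, e, cn in iv2 if s <= a and b <= e), p2.ploidy)
            if cn1 != cn2:
                if regions and regions[-1][0] == chrom and regions[-1][2] == a:
                    regions[-1] = (chrom, regions[-1][1], b)
                else:
                    regions.append((chrom, a, b))
    return regions


def select_clone_genes(
    annotation: pd.DataFrame, profiles: dict[str, CloneCNVProfile]
) -> list[str]:
    """Genes overlapping any region where the two clones differ in copy number.

    With whole-chromosome CNV profiles this reduces to all genes on the
    differing chromosomes (e.g. chromosomes 8 and 12 in the patient data).
    A gene straddling a region boundary is included (any-overlap rule).
    """
    if len(profiles) != 2:
        raise ValueError("exactly two clone profiles required")
    p1, p2 = profiles.values()
    if p1.ploidy != p2.ploidy:
        raise ValueError("clone profiles must share ploidy")
    regions = _differential_regions(p1, p2)
    if not regions:
        raise ValueError("clone CNV profiles are identical: clones indistinguishable")
    genes = []
    for row in annotation.itertuples():
        for chrom, start, end in regions:
            if row.chromosome == chrom and row.start < end and start < row.end:
                genes.append(row.gene_id)
                break
    return genes


def compute_clone_score(adata: ad.AnnData, gene_set) -> pd.Series:
    """Per-spot mean normalized expression over the clone-informative genes."""
    gene_set = [g for g in gene_set if g in adata.var_names]
    if not gene_set:
        raise ValueError("empty clone gene set")
    if "lognorm" not in adata.layers:
        raise ValueError("normalized layer required")
    sub = adata[:, gene_set]
    vals = np.asarray(sub.layers["lognorm"]).mean(axis=1)
    return pd.Series(vals, index=adata.obs_names, name="clone_score")


def concordance(labels1, labels2) -> float:
    """Best agreement between two 2-label partitions over label permutations."""
    l1 = np.asarray(labels1)
    l2 = np.asarray(labels2)
    if len(l1) != len(l2):
        raise ValueError("labelings cover different spot sets")
    u1, u2 = np.unique(l1), np.unique(l2)
    if len(u1) > 2 or len(u2) > 2:
        raise ValueError("concordance is defined for 2-label partitions")
    b1 = l1 == u1[0]
    b2 = l2 == u2[0]
    agree = float(np.mean(b1 == b2))
    return max(agree, 1.0 - agree)


def map_clones(
    adata: ad.AnnData,
    annotation: pd.DataFrame,
    profiles: dict[str, CloneCNVProfile],
    graph,
    beta: float | None = None,
    max_iter: int = 50,
    seed: int = 0,
    gain_is_clone_a: bool = True,
) -> CloneMap:
    """Segment spots into two clones from CNV-informative gene expression.

    Steps: restrict the normalized features to the clone gene set (only
    QC-surviving genes are observable); run the spatially smoothed
    segmentation with K = 2; label the cluster with the higher mean clone
    score as the gain clone; run the non-spatial control clustering forced
    to two communities on the same features and record the concordance.
    """
    gene_set = [g for g in select_clone_genes(annotation, profiles) if g in adata.var_names]
    if not gene_set:
        raise ValueError("no clone-informative genes survive QC")
    if "lognorm" not in adata.layers:
        raise ValueError("normalized layer required; run normalize_log1p first")
    features = pd.DataFrame(
        np.asarray(adata[:, gene_set].layers["lognorm"]),
        index=adata.obs_names,
        columns=gene_set,
    )
    seg = segment_spatial(
        features, graph, K=2, beta=beta, max_iter=max_iter, seed=seed, allow_merge=False
    )
    score = compute_clone_score(adata, gene_set)
    mean_scores = score.groupby(seg.labels).mean()
    if len(mean_scores) < 2:
        raise ValueError("segmentation collapsed to a single cluster: no clone signal")
    if abs(mean_scores.iloc[0] - mean_scores.iloc[1]) < POLARITY_TOLERANCE:
        raise ValueError(
            "cluster mean clone scores are equal: clone polarity undecidable"
        )
    gain_cluster = int(mean_scores.idxmax())
    gain_label, other_label = ("A", "B") if gain_is_clone_a else ("B", "A")
    clone = np.where(seg.labels == gain_cluster, gain_label, other_label)

    # per-spot confidence: margin between distances to the two cluster centroids
    X = features.to_numpy()
    cents = np.array([X[seg.labels == k].mean(axis=0) for k in range(2)])
    d2 = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(-1)
    own = d2[np.arange(len(X)), seg.labels]
    other = d2[np.arange(len(X)), 1 - seg.labels]
    margin = np.sqrt(other) - np.sqrt(own)

    control = cluster_expression(features, seed=seed, force_k=2)
    conc = concordance(seg.labels, control.labels)
    ctrl = control.labels
    if np.mean(ctrl == seg.labels) < 0.5:
        ctrl = 1 - ctrl
    control_clone = np.where(ctrl == gain_cluster, gain_label, other_label)

    frame = pd.DataFrame(
        {
            "clone": clone,
            "clone_score": score.values,
            "margin": margin,
            "cluster": seg.labels,
            "control_clone": control_clone,
        },
        index=adata.obs_names,
    )
    return CloneMap(
        frame=frame,
        concordance_with_control=conc,
        gene_set=gene_set,
        params={"seed": seed, "beta": seg.params["beta"], "method": "spatial"},
        segmentation=seg,
    )


def validate_with_fish(
    nuclei: pd.DataFrame, fish: pd.DataFrame, min_reliable_n: int = 10
) -> dict:
    """Compare per-nucleus FISH counts between clone territories.

    For each probe: the empirical count distribution (fractions at 0, 1,
    2, 3, 4+ signals) per clone area, and a two-sided Mann-Whitney
    comparison of the counts between clone-A and clone-B nuclei.  A probe
    with fewer than ``min_reliable_n`` nuclei in either area is flagged
    unreliable.
    """
    if "clone" not in nuclei:
        raise ValueError("nuclei must carry a clone assignment")
    assigned = nuclei[nuclei["clone"].isin(["A", "B"])]
    for clone in ("A", "B"):
        if not (assigned["clone"] == clone).any():
            raise ValueError(f"clone area {clone} contains no nuclei")
    merged = fish.merge(assigned[["nucleus_id", "clone"]], on="nucleus_id")
    report = {}
    for probe, grp in merged.groupby("probe", sort=True):
        counts = {c: grp.loc[grp["clone"] == c, "count"].to_numpy() for c in ("A", "B")}
        if len(counts["A"]) == 0 or len(counts["B"]) == 0:
            raise ValueError(f"probe {probe}: a clone area has no nuclei")
        dist = {}
        for c, vals in counts.items():
            binned = np.minimum(vals, 4)
            frac = np.bincount(binned, minlength=5) / len(vals)
            dist[c] = {"0": frac[0], "1": frac[1], "2": frac[2], "3": frac[3], "4+": frac[4]}
        mw = mann_whitney_u(counts["A"], counts["B"], alternative="two_sided")
        report[probe] = {
            "distribution": dist,
            "U": mw["U"],
            "p": mw["p"],
            "n": {"A": int(len(counts["A"])), "B": int(len(counts["B"]))},
            "reliable": min(len(counts["A"]), len(counts["B"])) >= min_reliable_n,
        }
    return report
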