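"""Quality control, normalization and informative-gene selection.

Boundary convention: "less than" thresholds exclude strictly-below values
only, so a gene detected in exactly 10% of spots (or exactly 10 spots) is
kept.  Every filter appends a record to ``uns["qc_state"]``.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import scipy.sparse as sp

from .stats import morans_i

__all__ = [
    "filter_spots",
    "filter_genes",
    "normalize_log1p",
    "select_hvg",
    "select_svg_morans",
]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _record(adata: ad.AnnData, entry: dict) -> None:
    state = list(adata.uns.get("qc_state", []))
    state.append(entry)
    adata.uns["qc_state"] = state


def filter_spots(adata: ad.AnnData, min_counts: int = 0, min_genes: int = 0) -> ad.AnnData:
    """Drop spots with total counts < ``min_counts`` or detected genes < ``min_genes``."""
    if min_counts < 0 or min_genes < 0:
        raise ValueError("thresholds must be non-negative")
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    keep = (totals >= min_counts) & (detected >= min_genes)
    if not keep.any():
        raise ValueError("spot filter removed every spot")
    out = adata[keep].copy()
    _record(
        out,
        {
            "step": "filter_spots",
            "min_counts": int(min_counts),
            "min_genes": int(min_genes),
            "n_removed": int((~keep).sum()),
        },
    )
    return out


def filter_genes(
    adata: ad.AnnData,
    min_fraction_of_spots: float | None = None,
    min_spots: int | None = None,
) -> ad.AnnData:
    """Drop rarely detected genes.

    Exactly one criterion must be given: ``min_fraction_of_spots`` keeps a
    gene detected in ≥ fraction·n_spots spots (patient-sample mode,
    conventionally 0.10); ``min_spots`` keeps a gene detected in
    ≥ min_spots spots (xenograft mode, conventionally 10).
    """
    if (min_fraction_of_spots is None) == (min_spots is None):
        raise ValueError("give exactly one of min_fraction_of_spots / min_spots")
    detected = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    if min_fraction_of_spots is not None:
        threshold = min_fraction_of_spots * adata.n_obs
        entry = {"step": "filter_genes", "min_fraction_of_spots": float(min_fraction_of_spots)}
    else:
        threshold = min_spots
        entry = {"step": "filter_genes", "min_spots": int(min_spots)}
    keep = detected >= threshold
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    out = adata[:, keep].copy()
    entry["n_removed"] = int((~keep).sum())
    _record(out, entry)
    return out


def normalize_log1p(adata: ad.AnnData, target_sum: float | None = None) -> ad.AnnData:
    """Library-size normalization followed by log1p, into ``layers["lognorm"]``.

    normalized(s, g) = log(1 + count(s, g) · target_sum / total_s); the
    target defaults to the median spot total.  Spots with zero total must
    be filtered out first.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("zero-total spot present; run filter_spots first")
    if target_sum is None:
        target_sum = float(np.median(totals))
    out = adata.copy()
    X = _dense(out.X).astype(float)
    out.layers["lognorm"] = np.log1p(X * (target_sum / totals)[:, None])
    out.uns["normalize_target_sum"] = float(target_sum)
    return out


def select_hvg(adata: ad.AnnData, n_top: int, n_bins: int = 20) -> list[str]:
    """Top ``n_top`` highly variable genes by mean-trend-standardized variance.

    The mean–variance trend is a running median of log variance in
    ``n_bins`` bins of log mean (deterministic and assumption-light); genes
    are ranked by their variance relative to the trend, clipped at ±10 on
    the log scale.  Requires the normalized layer.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("normalized layer required; run normalize_log1p first")
    if n_top > adata.n_vars:
        raise ValueError("n_top exceeds number of genes")
    Y = np.asarray(adata.layers["lognorm"])
    mean = Y.mean(axis=0)
    var = Y.var(axis=0, ddof=1)
    logmean = np.log1p(mean)
    logvar = np.where(var > 0, np.log(np.maximum(var, 1e-300)), -np.inf)
    order = np.argsort(logmean, kind="stable")
    trend = np.empty_like(logvar)
    # keep >= ~10 genes per bin so the running median is a stable trend
    n_bins_eff = int(np.clip(adata.n_vars // 10, 1, n_bins))
    bins = np.array_split(order, n_bins_eff)
    for b in bins:
        if len(b) == 0:
            continue
        finite = logvar[b][np.isfinite(logvar[b])]
        trend[b] = np.median(finite) if len(finite) else 0.0
    resid = np.clip(logvar - trend, -10.0, 10.0)
    resid[~np.isfinite(logvar)] = -np.inf  # constant genes rank last
    ranked = np.argsort(-resid, kind="stable")
    return [adata.var_names[i] for i in ranked[:n_top]]


def select_svg_morans(adata: ad.AnnData, graph, n_top: int) -> list[str]:
    """Top ``n_top`` spatially variable genes ranked by Moran's I.

    A screening statistic for spatial expression structure: genes whose
    normalized values autocorrelate along the spot graph rank first.
    Constant genes are skipped with a warning.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("normalized layer required; run normalize_log1p first")
    Y = np.asarray(adata.layers["lognorm"])
    scores = np.full(adata.n_vars, -np.inf)
    n_constant = 0
    for j in range(adata.n_vars):
        vals = Y[:, j]
        if np.ptp(vals) == 0:
            n_constant += 1
            continue
        scores[j] = morans_i(vals, graph, node_order=list(adata.obs_names))
    if n_constant:
        warnings.warn(f"skipped {n_constant} constant genes in Moran's I ranking")
    ranked = np.argsort(-scores, kind="stable")
    return [adata.var_names[i] for i in ranked[:n_top]]
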