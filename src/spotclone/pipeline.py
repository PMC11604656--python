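"""End-to-end orchestration: the steps each CLI subcommand performs.

Functions here glue the per-module operations together with the config
record from :mod:`spotclone.io`; they are plain library calls so that the
CLI stays a thin shell and tests can drive full runs directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import clones as cl
from . import geometry as geo
from . import io as scio
from . import preprocess as pp
from . import segmentation as seg
from . import stats as st
from . import synthetic as syn

__all__ = [
    "prepare_dataset",
    "segmentation_features",
    "run_map_clones",
    "run_heterogeneity",
    "run_nuclei",
    "run_full",
]


def prepare_dataset(adata: ad.AnnData, cfg: dict) -> ad.AnnData:
    """QC filters + normalization as configured."""
    adata = pp.filter_spots(adata, cfg["min_counts"], cfg["min_genes"])
    if cfg["gene_filter_mode"] == "fraction":
        adata = pp.filter_genes(adata, min_fraction_of_spots=cfg["min_fraction_of_spots"])
    else:
        adata = pp.filter_genes(adata, min_spots=cfg["min_spots"])
    return pp.normalize_log1p(adata)


def segmentation_features(adata: ad.AnnData, graph, cfg: dict, n_pcs: int = 20):
    """Spatially-variable-gene selection + PCA features for segmentation."""
    n_top = min(cfg["n_hvg"], adata.n_vars)
    svg = pp.select_svg_morans(adata, graph, n_top)
    Y = np.asarray(adata[:, svg].layers["lognorm"])
    feats = seg._pca(Y, min(n_pcs, min(Y.shape) - 1))
    return pd.DataFrame(feats, index=adata.obs_names)


def run_map_clones(
    adata: ad.AnnData,
    annotation: pd.DataFrame,
    profiles: dict,
    cfg: dict,
    truth_clones: dict | None = None,
) -> tuple[cl.CloneMap, dict]:
    """QC, normalize, map clones; report accuracy when truth is available."""
    prepared = prepare_dataset(adata, cfg)
    graph = seg.build_spot_graph(prepared.obs)
    clone_map = cl.map_clones(
        prepared, annotation, profiles, graph, beta=cfg["beta"], seed=cfg["seed"]
    )
    report = {
        "n_spots": int(prepared.n_obs),
        "n_genes": int(prepared.n_vars),
        "n_clone_genes": len(clone_map.gene_set),
        "concordance_with_control": clone_map.concordance_with_control,
        "qc_state": list(prepared.uns["qc_state"]),
    }
    if truth_clones:
        truth = pd.Series(truth_clones).reindex(clone_map.frame.index)
        ok = truth.notna()
        report["clone_accuracy"] = float(
            (clone_map.frame.loc[ok, "clone"] == truth[ok]).mean()
        )
    return clone_map, report


def run_heterogeneity(samples: dict[str, ad.AnnData], cfg: dict) -> pd.DataFrame:
    """Heterogeneity index for each sample via spatial segmentation."""
    rows = []
    for sample_id, adata in samples.items():
        prepared = prepare_dataset(adata, cfg)
        graph = seg.build_spot_graph(prepared.obs)
        feats = segmentation_features(prepared, graph, cfg)
        result = seg.segment_spatial(
            feats,
            graph,
            K=min(cfg["n_clusters"], prepared.n_obs),
            beta=cfg["beta"],
            max_iter=cfg["max_iter"],
            seed=cfg["seed"],
        )
        hi = st.heterogeneity_index(
            result.labels,
            prepared.n_obs,
            min_spots=cfg["min_cluster_spots"],
            sample_id=sample_id,
        )
        rows.append(
            {
                "sample_id": sample_id,
                "n_clusters_kept": hi.n_clusters_kept,
                "n_spots": hi.n_spots,
                "index": hi.index,
            }
        )
    return pd.DataFrame(rows)


def run_nuclei(
    clone_map: cl.CloneMap, positions: pd.DataFrame, nuclei: pd.DataFrame, cfg: dict
) -> tuple[pd.DataFrame, dict]:
    """Territories → nucleus assignment → nuclear-area comparison."""
    graph = seg.build_spot_graph(positions)
    territories = geo.build_territories(
        clone_map.frame["clone"], positions, graph, alpha=cfg["alpha_um"]
    )
    assigned = geo.assign_nuclei(nuclei, territories)
    stats = geo.compare_nuclear_area(assigned)
    return assigned, stats


def run_full(cfg: dict, out_dir: str | Path) -> dict:
    """Simulate a default synthetic sample and run every stage on it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    params = syn.default_params(seed=seed)
    truth = syn.make_truth(params)
    sample_dir = out_dir / "sample"
    adata = syn.write_synthetic_sample(sample_dir, truth)

    clone_map, clone_report = run_map_clones(
        adata,
        truth.annotation,
        truth.profiles,
        cfg,
        truth_clones=dict(zip(truth.clone_field["spot_id"], truth.clone_field["clone"])),
    )
    clone_map.frame.to_csv(out_dir / "clone_map.tsv", sep="\t")

    nuclei = syn.simulate_nuclei(
        truth.clone_field,
        density_per_mm2=400.0,
        area_lognormal_params_per_clone={
            "A": (np.log(60.0), 0.35),
            "B": (np.log(40.0), 0.35),
        },
        seed=seed + 1,
    )
    positions = clone_map.frame.join(adata.obs[["x_um", "y_um"]])[["x_um", "y_um"]]
    assigned, area_stats = run_nuclei(clone_map, positions, nuclei, cfg)
    assigned.to_csv(out_dir / "nuclei_assigned.csv", index=False)

    fish = syn.simulate_fish_counts(
        nuclei,  # counts reflect each nucleus's true clone
        probe_cn_per_clone={"cen8": {"A": 4, "B": 2}, "MDM2": {"A": 4, "B": 2}},
        efficiency=0.9,
        false_rate=0.05,
        seed=seed + 2,
    )
    fish_report = cl.validate_with_fish(assigned, fish)

    structures = syn.simulate_structure_table(
        n_crops=3,
        cell_area_dist=(np.log(40.0), 0.5),
        mt_area_dist=(np.log(8.0), 0.6),
        counts_per_crop=(120, 40),
        seed=seed + 3,
    )
    from . import microtubes as mt

    quant = mt.microtube_area_per_cell(mt.filter_structures(structures))

    report = {
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "clone_mapping": clone_report,
        "nuclear_area": area_stats,
        "fish_validation": {
            probe: {k: v for k, v in rep.items() if k != "distribution"}
            for probe, rep in fish_report.items()
        },
        "microtube_area_per_cell": {
            r["sample_id"]: r["mt_area_per_cell_um2"] for _, r in quant.iterrows()
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
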