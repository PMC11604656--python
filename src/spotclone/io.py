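"""Readers and writers for every on-disk format the pipeline touches.

Conventions
-----------
* The in-memory spot container is an :class:`anndata.AnnData` with spots as
  observations and genes as variables.  ``X`` holds raw integer counts
  (sparse), ``obs`` carries ``in_tissue``, ``array_row``, ``array_col``,
  ``x_um``, ``y_um``, ``layers["lognorm"]`` the normalized matrix, and
  ``uns["qc_state"]`` a list of applied-filter records.
* Genomic intervals are 0-based half-open throughout.
* All coordinates are carried in micrometres after applying the
  pixel-to-micrometre scale given at read time (Visium position files store
  full-resolution pixels).
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "CloneCNVProfile",
    "read_spot_dataset",
    "write_spot_dataset",
    "read_gene_annotation",
    "read_cnv_profiles",
    "write_cnv_profiles",
    "read_nuclei",
    "read_structures",
    "read_config",
    "read_truth",
]

POSITIONS_V1_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]

#: Known configuration keys with their defaults.  Thresholds mirror the
#: published analysis: clusters below 5 spots are dropped from the
#: heterogeneity index, genes seen in <10% of spots (patient samples) or
#: <10 spots (xenograft samples) are removed, cells below 10 µm² and
#: microtubes at or below 2 µm² are excluded from microtube quantification,
#: and clone mapping is forced to two clusters.
CONFIG_DEFAULTS: dict = {
    "seed": 0,
    "um_per_px": 1.0,
    "min_counts": 100,
    "min_genes": 10,
    "gene_filter_mode": "fraction",  # "fraction" (human) or "spots" (PDX)
    "min_fraction_of_spots": 0.10,
    "min_spots": 10,
    "n_hvg": 2000,
    "n_clusters": 12,
    "clone_k": 2,
    "beta": None,  # Potts smoothness; None = data-driven default
    "max_iter": 50,
    "min_cluster_spots": 5,
    "alpha_um": None,  # alpha-shape parameter; None = 1/(1.5 * spacing)
    "cell_min_area_um2": 10.0,
    "microtube_min_area_um2": 2.0,
}


@dataclass
class CloneCNVProfile:
    """Per-clone copy-number intervals (0-based half-open, ploidy-relative)."""

    clone: str
    intervals: list = field(default_factory=list)  # (chrom, start, end, cn)
    ploidy: int = 2

    def __post_init__(self) -> None:
        by_chrom: dict = {}
        for chrom, start, end, cn in self.intervals:
            if start >= end:
                raise ValueError(
                    f"clone {self.clone}: interval {chrom}:{start}-{end} has start >= end"
                )
            if cn < 0:
                raise ValueError(f"clone {self.clone}: negative copy number {cn}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"clone {self.clone}: overlapping intervals on {chrom}"
                    )


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir_path}")


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_positions(dir_path: Path) -> Path:
    for name in (
        "tissue_positions.csv",
        "tissue_positions_list.csv",
        "tissue_positions.csv.gz",
        "tissue_positions_list.csv.gz",
    ):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no tissue_positions CSV in {dir_path}")


def read_positions(path: str | Path) -> pd.DataFrame:
    """Read a Visium tissue-positions CSV (v1 headerless or v2 headered)."""
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    pos = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=None if has_header else POSITIONS_V1_COLUMNS,
    )
    missing = set(POSITIONS_V1_COLUMNS) - set(pos.columns)
    if missing:
        raise ValueError(f"positions file missing columns: {sorted(missing)}")
    if pos["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in positions file")
    return pos


def read_spot_dataset(dir_path: str | Path, um_per_px: float = 1.0) -> ad.AnnData:
    """Read a 10x-style matrix directory into a spot×gene AnnData.

    The matrix on disk is gene×spot (MatrixMarket, 1-based coordinates); it
    is transposed to spot×gene.  Only ``in_tissue == 1`` spots enter the
    matrix view; the full positions table is kept in
    ``uns["positions_full"]``.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    with _open_maybe_gzip(mtx_path, "rt") as fh:
        counts = scipy.io.mmread(fh)
    counts = sp.csr_matrix(counts.T)  # -> spot × gene
    with _open_maybe_gzip(_find(dir_path, "barcodes.tsv")) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gzip(_find(dir_path, "features.tsv")) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    genes = [row[0] for row in feat_rows]

    if counts.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[0]} barcodes but barcodes.tsv has {len(barcodes)}"
        )
    if counts.shape[1] != len(genes):
        raise ValueError(
            f"matrix has {counts.shape[1]} genes but features.tsv has {len(genes)}"
        )
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")

    pos = read_positions(_find_positions(dir_path)).set_index("barcode")
    missing = set(barcodes) - set(pos.index)
    if missing:
        raise ValueError(f"{len(missing)} barcodes missing from positions file")
    pos = pos.loc[barcodes]

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["in_tissue"] = pos["in_tissue"].astype(int).values
    obs["array_row"] = pos["array_row"].astype(int).values
    obs["array_col"] = pos["array_col"].astype(int).values
    obs["x_um"] = pos["pxl_col_in_fullres"].astype(float).values * um_per_px
    obs["y_um"] = pos["pxl_row_in_fullres"].astype(float).values * um_per_px

    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    if len(feat_rows[0]) > 1:
        var["gene_name"] = [row[1] for row in feat_rows]

    adata = ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var)
    adata.uns["positions_full"] = pos.reset_index()
    adata.uns["um_per_px"] = float(um_per_px)
    adata.uns["qc_state"] = []
    keep = adata.obs["in_tissue"].values == 1
    return adata[keep].copy()


def write_spot_dataset(adata: ad.AnnData, dir_path: str | Path) -> None:
    """Write a spot dataset as matrix.mtx + barcodes/features TSV + positions CSV."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    if adata.n_vars == 0:
        raise ValueError("refusing to write a dataset with zero genes")
    X = sp.coo_matrix(adata.X)
    if not np.issubdtype(X.dtype, np.integer):
        if np.any(X.data != np.round(X.data)):
            raise ValueError("counts must be integers for MTX output")
        X = X.astype(np.int64)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), X.T)  # gene × spot on disk
    with open(dir_path / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    with open(dir_path / "features.tsv", "w") as fh:
        names = (
            adata.var["gene_name"]
            if "gene_name" in adata.var
            else pd.Series(adata.var_names, index=adata.var_names)
        )
        for gid in adata.var_names:
            fh.write(f"{gid}\t{names[gid]}\tGene Expression\n")
    um_per_px = float(adata.uns.get("um_per_px", 1.0))
    pos = pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "in_tissue": adata.obs.get("in_tissue", 1),
            "array_row": adata.obs["array_row"].astype(int).values,
            "array_col": adata.obs["array_col"].astype(int).values,
            "pxl_row_in_fullres": adata.obs["y_um"].values / um_per_px,
            "pxl_col_in_fullres": adata.obs["x_um"].values / um_per_px,
        }
    )
    pos.to_csv(dir_path / "tissue_positions_list.csv", header=False, index=False)


def read_gene_annotation(tsv_path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chromosome, start, end)."""
    ann = pd.read_csv(tsv_path, sep="\t")
    required = {"gene_id", "chromosome", "start", "end"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    if not (
        np.issubdtype(ann["start"].dtype, np.number)
        and np.issubdtype(ann["end"].dtype, np.number)
    ):
        raise ValueError("non-numeric coordinates in annotation")
    if (ann["start"] >= ann["end"]).any():
        bad = ann.loc[ann["start"] >= ann["end"], "gene_id"].iloc[0]
        raise ValueError(f"gene {bad}: start >= end")
    return ann


def read_cnv_profiles(tsv_path: str | Path) -> dict[str, CloneCNVProfile]:
    """Read per-clone CNV intervals from TSV (clone, chromosome, start, end, copy_number)."""
    tab = pd.read_csv(tsv_path, sep="\t")
    required = {"clone", "chromosome", "start", "end", "copy_number"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"CNV profile missing columns: {sorted(missing)}")
    profiles = {}
    for clone, grp in tab.groupby("clone", sort=True):
        intervals = [
            (str(r.chromosome), int(r.start), int(r.end), int(r.copy_number))
            for r in grp.itertuples()
        ]
        ploidy = int(grp["ploidy"].iloc[0]) if "ploidy" in grp else 2
        profiles[str(clone)] = CloneCNVProfile(str(clone), intervals, ploidy)
    return profiles


def write_cnv_profiles(profiles: dict[str, CloneCNVProfile], tsv_path: str | Path) -> None:
    rows = [
        {
            "clone": p.clone,
            "chromosome": chrom,
            "start": start,
            "end": end,
            "copy_number": cn,
            "ploidy": p.ploidy,
        }
        for p in profiles.values()
        for chrom, start, end, cn in p.intervals
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_nuclei(csv_path: str | Path) -> pd.DataFrame:
    """Read a nucleus table CSV (nucleus_id, x_um, y_um, area_um2 [, true_clone])."""
    nuc = pd.read_csv(csv_path)
    required = {"nucleus_id", "x_um", "y_um", "area_um2"}
    missing = required - set(nuc.columns)
    if missing:
        raise ValueError(f"nucleus table missing columns: {sorted(missing)}")
    for col in ("x_um", "y_um", "area_um2"):
        if not np.issubdtype(nuc[col].dtype, np.number):
            raise ValueError(f"non-numeric column {col} in nucleus table")
    if (nuc["area_um2"] <= 0).any():
        raise ValueError("nucleus areas must be positive")
    return nuc


def read_structures(csv_path: str | Path) -> pd.DataFrame:
    """Read a structure table CSV (sample_id, crop_id, class, area_um2)."""
    tab = pd.read_csv(csv_path)
    required = {"sample_id", "crop_id", "class", "area_um2"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"structure table missing columns: {sorted(missing)}")
    bad = set(tab["class"]) - {"cell", "microtube"}
    if bad:
        raise ValueError(f"unknown structure classes: {sorted(bad)}")
    if len(tab) and (tab["area_um2"] <= 0).any():
        raise ValueError("structure areas must be positive")
    return tab


def read_config(path: str | Path) -> dict:
    """Read a YAML config, filling defaults; unknown keys warn but are kept."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a mapping")
    unknown = set(user) - set(CONFIG_DEFAULTS)
    if unknown:
        warnings.warn(f"unknown config keys ignored by the pipeline: {sorted(unknown)}")
    cfg = dict(CONFIG_DEFAULTS)
    cfg.update(user)
    return cfg


def read_truth(path: str | Path) -> dict:
    """Read a synthetic ground-truth JSON written by the simulator."""
    with open(path) as fh:
        return json.load(fh)
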