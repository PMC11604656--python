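"""Synthetic spot-lattice samples with known clone structure.

Every downstream stage of the pipeline (clone mapping, territory geometry,
nuclear morphology, FISH validation, microtube quantification) is exercised
on data from this module, so the generators reproduce the statistical
structure the analyses assume:

* a hexagonal spot lattice with Visium v1 geometry (offset rows, 100 µm
  centre-to-centre spacing),
* two spatially contiguous genetic clones whose copy-number differences
  drive gene expression through a linear dosage effect (expression
  multiplier = copy_number / ploidy),
* negative-binomial counts (variance = µ + µ²/θ) with lognormal per-spot
  library-size factors and per-gene baselines,
* a normal-cell contamination fraction that dilutes the dosage signal as a
  mean mixture: µ ∝ (1−c)·d + c,
* matched nuclei with clone-dependent lognormal area distributions and
  per-nucleus FISH-style probe counts (binomial detection of the true copy
  number plus Poisson false signals).

All generators take an explicit seed and draw from a single
``numpy.random.Generator``; given identical parameters and seed the output
is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as scio

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "hex_lattice",
    "generate_clone_field",
    "generate_region_field",
    "make_truth",
    "simulate_counts",
    "simulate_region_counts",
    "simulate_nuclei",
    "simulate_fish_counts",
    "simulate_structure_table",
    "write_synthetic_sample",
    "default_params",
]

ROW_STEP = np.sqrt(3.0) / 2.0  # row pitch in units of spacing for a hex lattice


@dataclass
class SimulationParams:
    """Parameters of one synthetic sample.

    ``nb_dispersion`` is the negative-binomial size parameter θ in the
    variance = µ + µ²/θ convention (large θ → Poisson).  ``contamination``
    is the fraction of dosage-neutral (normal-cell) signal mixed into every
    spot's mean.
    """

    n_rows: int = 40
    n_cols: int = 40
    spacing_um: float = 100.0
    n_genes: int = 2000
    baseline_mean: float = 1.0
    gene_logmean_sd: float = 1.0
    nb_dispersion: float = 2.0
    libsize_sd: float = 0.3
    contamination: float = 0.2
    layout: str = "half_split"
    blob_smooth_um: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("lattice must be at least 2x2")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.layout not in ("half_split", "blob"):
            raise ValueError(f"unknown layout {self.layout!r}")


def default_params(**overrides) -> SimulationParams:
    """The default study conditions: 40×40 lattice, 2000 genes, contamination 0.2."""
    return SimulationParams(**overrides)


def hex_lattice(n_rows: int, n_cols: int, spacing_um: float) -> pd.DataFrame:
    """Spot centres on an offset hexagonal lattice (odd rows shifted by spacing/2)."""
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    x = cols * spacing_um + (rows % 2) * spacing_um / 2.0
    y = rows * spacing_um * ROW_STEP
    ids = [f"spot-{r:03d}-{c:03d}" for r, c in zip(rows, cols)]
    return pd.DataFrame(
        {
            "spot_id": ids,
            "array_row": rows,
            "array_col": cols,
            "x_um": x,
            "y_um": y,
        }
    )


def _blob_labels(
    lattice: pd.DataFrame, smooth_um: float, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.normal(size=len(lattice))
    xy = lattice[["x_um", "y_um"]].to_numpy()
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * smooth_um**2))
    smoothed = w @ noise
    # threshold at the median: keeps the smoothed-noise geometry while
    # guaranteeing both clones are populated
    return np.where(smoothed >= np.median(smoothed), "A", "B")


def generate_clone_field(params: SimulationParams) -> pd.DataFrame:
    """Assign a clone label in {A, B} to every lattice spot.

    ``half_split`` puts clone A on columns < n_cols/2; ``blob`` thresholds
    seeded Gaussian-smoothed noise (bandwidth ``blob_smooth_um``) producing
    an irregular but spatially coherent clone boundary.
    """
    lattice = hex_lattice(params.n_rows, params.n_cols, params.spacing_um)
    if params.layout == "half_split":
        clone = np.where(lattice["array_col"] < params.n_cols / 2, "A", "B")
    else:
        for attempt in range(10):
            rng = np.random.default_rng(params.seed + attempt)
            clone = _blob_labels(lattice, params.blob_smooth_um, rng)
            if (clone == "A").any() and (clone == "B").any():
                break
        else:
            raise RuntimeError("blob layout produced an empty clone in 10 attempts")
    out = lattice.copy()
    out["clone"] = clone
    if not ((out["clone"] == "A").any() and (out["clone"] == "B").any()):
        raise RuntimeError("clone field has an empty clone")
    return out


def generate_region_field(
    params: SimulationParams, n_regions: int, seed: int | None = None
) -> pd.DataFrame:
    """Partition the lattice into ``n_regions`` contiguous expression regions.

    Regions are nearest-seed (Voronoi) cells of randomly placed seed spots;
    used to build samples of controlled spatial heterogeneity.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    lattice = hex_lattice(params.n_rows, params.n_cols, params.spacing_um)
    if n_regions > len(lattice):
        raise ValueError("more regions than spots")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    seeds = rng.choice(len(lattice), size=n_regions, replace=False)
    xy = lattice[["x_um", "y_um"]].to_numpy()
    d2 = ((xy[:, None, :] - xy[None, seeds, :]) ** 2).sum(-1)
    out = lattice.copy()
    out["region"] = d2.argmin(axis=1)
    return out


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated sample.

    ``gene_dosage`` maps clone label → per-gene expression multiplier
    (copy_number / ploidy; 1.0 outside CNV-differential regions).
    """

    params: SimulationParams
    clone_field: pd.DataFrame
    gene_dosage: dict = field(default_factory=dict)
    informative_genes: set = field(default_factory=set)
    annotation: pd.DataFrame | None = None
    profiles: dict | None = None


#: synthetic genome: two clone-differential chromosomes (as in the patient
#: data, chr8 and chr12) plus one neutral chromosome carrying the rest
_CHROM_SIZE = 150_000_000


def make_truth(
    params: SimulationParams,
    n_informative: int = 200,
    cn_gain: int = 4,
    ploidy: int = 2,
) -> SyntheticTruth:
    """Build clone field, gene annotation, CNV profiles and dosage multipliers.

    ``n_informative`` genes are placed on the two clone-differential
    chromosomes (half on chr8, half on chr12) where clone A carries
    ``cn_gain`` copies and clone B the ploidy ``2``; all other genes sit on
    chr1 at equal copy number.
    """
    if n_informative > params.n_genes:
        raise ValueError("n_informative exceeds n_genes")
    clone_field = generate_clone_field(params)
    genes = [f"gene{i:04d}" for i in range(params.n_genes)]
    chrom = np.array(["chr1"] * params.n_genes, dtype=object)
    half = n_informative // 2
    chrom[:half] = "chr8"
    chrom[half:n_informative] = "chr12"
    # spread genes along each chromosome, 10 kb loci
    starts = np.zeros(params.n_genes, dtype=int)
    for c in ("chr8", "chr12", "chr1"):
        idx = np.where(chrom == c)[0]
        starts[idx] = np.linspace(1_000_000, _CHROM_SIZE - 1_000_000, len(idx)).astype(int)
    annotation = pd.DataFrame(
        {"gene_id": genes, "chromosome": chrom, "start": starts, "end": starts + 10_000}
    )
    profiles = {
        "A": scio.CloneCNVProfile(
            "A",
            [
                ("chr8", 0, _CHROM_SIZE, cn_gain),
                ("chr12", 0, _CHROM_SIZE, cn_gain),
                ("chr1", 0, _CHROM_SIZE, ploidy),
            ],
            ploidy,
        ),
        "B": scio.CloneCNVProfile(
            "B",
            [
                ("chr8", 0, _CHROM_SIZE, ploidy),
                ("chr12", 0, _CHROM_SIZE, ploidy),
                ("chr1", 0, _CHROM_SIZE, ploidy),
            ],
            ploidy,
        ),
    }
    dosage_a = np.ones(params.n_genes)
    dosage_a[:n_informative] = cn_gain / ploidy
    gene_dosage = {"A": dosage_a, "B": np.ones(params.n_genes)}
    return SyntheticTruth(
        params=params,
        clone_field=clone_field,
        gene_dosage=gene_dosage,
        informative_genes=set(genes[:n_informative]),
        annotation=annotation,
        profiles=profiles,
    )


def _nb_counts(
    mu: np.ndarray, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with variance = µ + µ²/θ (gamma–Poisson)."""
    if np.any(mu > 1e12):
        raise OverflowError("negative-binomial means exceed the supported range")
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-300) / theta)
    return rng.poisson(lam)


def _assemble_adata(
    counts: np.ndarray, field_df: pd.DataFrame, extra_obs: dict | None = None
) -> ad.AnnData:
    obs = pd.DataFrame(index=pd.Index(field_df["spot_id"].values, name="barcode"))
    obs["in_tissue"] = 1
    for col in ("array_row", "array_col", "x_um", "y_um"):
        obs[col] = field_df[col].values
    for key, val in (extra_obs or {}).items():
        obs[key] = val
    n_genes = counts.shape[1]
    var = pd.DataFrame(index=pd.Index([f"gene{i:04d}" for i in range(n_genes)], name="gene_id"))
    adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)
    adata.uns["qc_state"] = []
    adata.uns["um_per_px"] = 1.0
    return adata


def _group_counts(
    field_df: pd.DataFrame,
    group_col: str,
    multipliers: dict,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    n_spots, n_genes = len(field_df), params.n_genes
    libsize = np.exp(rng.normal(0.0, params.libsize_sd, size=n_spots))
    baseline = params.baseline_mean * np.exp(
        rng.normal(0.0, params.gene_logmean_sd, size=n_genes)
    )
    c = params.contamination
    mu = np.empty((n_spots, n_genes))
    for g, mult in multipliers.items():
        mask = (field_df[group_col] == g).to_numpy()
        mu[mask] = (1.0 - c) * np.asarray(mult) + c
    mu *= libsize[:, None] * baseline[None, :]
    return _nb_counts(mu, params.nb_dispersion, rng)


def simulate_counts(truth: SyntheticTruth) -> ad.AnnData:
    """Draw the spot×gene count matrix implied by a SyntheticTruth.

    count(s, g) ~ NB(mean = L_s · β_g · [(1−c)·d_{clone(s),g} + c], θ) with
    lognormal library factors L_s and gene baselines β_g.
    """
    rng = np.random.default_rng(truth.params.seed)
    counts = _group_counts(truth.clone_field, "clone", truth.gene_dosage, truth.params, rng)
    return _assemble_adata(
        counts, truth.clone_field, {"true_clone": truth.clone_field["clone"].values}
    )


def simulate_region_counts(
    params: SimulationParams,
    n_regions: int,
    region_effect_sd: float = 0.5,
    seed: int | None = None,
) -> ad.AnnData:
    """A sample whose expression differs between ``n_regions`` contiguous regions.

    Each region multiplies every gene's mean by an independent lognormal
    factor (log-sd ``region_effect_sd``), giving regions distinct
    transcriptional profiles of realistic magnitude.
    """
    seed = params.seed if seed is None else seed
    field_df = generate_region_field(params, n_regions, seed=seed)
    rng = np.random.default_rng(seed)
    multipliers = {
        r: np.exp(rng.normal(0.0, region_effect_sd, size=params.n_genes))
        for r in range(n_regions)
    }
    counts = _group_counts(field_df, "region", multipliers, params, rng)
    return _assemble_adata(counts, field_df, {"true_region": field_df["region"].values})


def simulate_nuclei(
    clone_field: pd.DataFrame,
    density_per_mm2: float,
    area_lognormal_params_per_clone: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Scatter nuclei in each clone's territory with clone-specific areas.

    Nuclei are placed uniformly in a disc of radius spacing/2 around each
    spot centre, with a Poisson number per spot matching ``density_per_mm2``;
    areas are lognormal with per-clone ``(log_median, log_sd)``.
    """
    if density_per_mm2 <= 0:
        raise ValueError("density_per_mm2 must be positive")
    for clone in clone_field["clone"].unique():
        if clone not in area_lognormal_params_per_clone:
            raise ValueError(f"no area parameters for clone {clone}")
    rng = np.random.default_rng(seed)
    spacing = _min_spacing(clone_field)
    radius = spacing / 2.0
    disc_mm2 = np.pi * radius**2 / 1e6
    lam = density_per_mm2 * disc_mm2
    counts = rng.poisson(lam, size=len(clone_field))
    rows = []
    for (spot, n) in zip(clone_field.itertuples(), counts):
        if n == 0:
            continue
        r = radius * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, size=n)
        log_med, log_sd = area_lognormal_params_per_clone[spot.clone]
        areas = np.exp(rng.normal(log_med, log_sd, size=n))
        for k in range(n):
            rows.append(
                (
                    spot.x_um + r[k] * np.cos(phi[k]),
                    spot.y_um + r[k] * np.sin(phi[k]),
                    areas[k],
                    spot.clone,
                )
            )
    nuc = pd.DataFrame(rows, columns=["x_um", "y_um", "area_um2", "true_clone"])
    nuc.insert(0, "nucleus_id", [f"nuc{i:06d}" for i in range(len(nuc))])
    return nuc


def _min_spacing(field_df: pd.DataFrame) -> float:
    """Minimum nonzero centre-to-centre distance, estimated within rows."""
    xs = field_df.sort_values(["array_row", "array_col"])
    gaps = xs.groupby("array_row")["x_um"].diff().dropna()
    gaps = gaps[gaps > 0]
    return float(gaps.min()) if len(gaps) else 100.0


def simulate_fish_counts(
    nuclei: pd.DataFrame,
    probe_cn_per_clone: dict,
    efficiency: float,
    false_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-nucleus FISH-style probe counts.

    Each of the nucleus's true copies of the probed locus is detected
    independently with probability ``efficiency``; spurious signals arrive
    at Poisson rate ``false_rate``:
    count = Binomial(CN_clone,probe, efficiency) + Poisson(false_rate).
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    if false_rate < 0:
        raise ValueError("false_rate must be >= 0")
    if "true_clone" not in nuclei:
        raise ValueError("nuclei need a true_clone column")
    rng = np.random.default_rng(seed)
    rows = []
    for probe, cn_by_clone in probe_cn_per_clone.items():
        cn = nuclei["true_clone"].map(cn_by_clone).to_numpy()
        if np.any(pd.isna(cn)) or np.any(cn < 0):
            raise ValueError(f"probe {probe}: missing or negative copy number")
        counts = rng.binomial(cn.astype(int), efficiency) + rng.poisson(
            false_rate, size=len(nuclei)
        )
        rows.append(
            pd.DataFrame(
                {"nucleus_id": nuclei["nucleus_id"].values, "probe": probe, "count": counts}
            )
        )
    return pd.concat(rows, ignore_index=True)


CROP_SIDE_UM = 400.0  # quantification crops are fixed 400 × 400 µm


def simulate_structure_table(
    n_crops: int,
    cell_area_dist: tuple,
    mt_area_dist: tuple,
    counts_per_crop: tuple,
    seed: int = 0,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Per-crop cell/microtube records with lognormal areas.

    ``cell_area_dist`` and ``mt_area_dist`` are (log_median, log_sd) of the
    area distribution in µm²; ``counts_per_crop`` is (n_cells, n_microtubes).
    """
    n_cells, n_mts = counts_per_crop
    if n_crops < 1 or n_cells < 0 or n_mts < 0:
        raise ValueError("invalid counts")
    rng = np.random.default_rng(seed)
    rows = []
    for crop in range(n_crops):
        for cls, n, (log_med, log_sd) in (
            ("cell", n_cells, cell_area_dist),
            ("microtube", n_mts, mt_area_dist),
        ):
            areas = np.exp(rng.normal(log_med, log_sd, size=n))
            for a in areas:
                rows.append((sample_id, f"crop{crop}", cls, a))
    return pd.DataFrame(rows, columns=["sample_id", "crop_id", "class", "area_um2"])


def write_synthetic_sample(
    dir_path: str | Path, truth: SyntheticTruth, adata: ad.AnnData | None = None
) -> ad.AnnData:
    """Write a full synthetic sample (MTX dir, annotation, CNV profiles, truth JSON)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    if adata is None:
        adata = simulate_counts(truth)
    scio.write_spot_dataset(adata, dir_path)
    truth.annotation.to_csv(dir_path / "gene_annotation.tsv", sep="\t", index=False)
    scio.write_cnv_profiles(truth.profiles, dir_path / "cnv_profiles.tsv")
    payload = {
        "params": asdict(truth.params),
        "informative_genes": sorted(truth.informative_genes),
        "clones": dict(
            zip(truth.clone_field["spot_id"], truth.clone_field["clone"])
        ),
    }
    with open(dir_path / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    return adata
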