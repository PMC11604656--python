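# spotclone

Spatial mapping of genetic clones and tissue-heterogeneity statistics for
Visium-style spot transcriptomics.

Tumours such as chromothriptic medulloblastoma contain genetically distinct
clones that differ in chromosome copy number. Because expression scales with
gene dosage, spots lying in a clone's territory show systematically higher
mean expression of genes in gained regions. `spotclone` turns this into a
tested analysis pipeline for spot×gene count matrices:

- **Spatially smoothed segmentation** — a Potts-model K-means optimized by
  iterated conditional modes (ICM). Labels minimise
  `Σ_s ‖f_s − µ_{l(s)}‖² − β · Σ_{(s,t)∈E} 1[l(s)=l(t)]`
  over the hexagonal spot-adjacency graph, so neighbouring spots prefer a
  common label. An energy-decreasing merge phase lets the effective number
  of clusters fall below K when a sample has fewer genuinely distinct
  regions; a Hartigan-style single-move descent sharpens local optima.
- **Clone mapping** — spots are segmented into two clusters using only
  CNV-informative genes (genes overlapping regions where the clones' copy
  numbers differ, e.g. whole chromosomes 8 and 12); the cluster with the
  higher mean informative-gene expression is the gain clone A, the other the
  ancestral clone B. A non-spatial PCA + kNN + Leiden control clustering of
  the same features is recorded for concordance.
- **Clone territories and nuclear morphology** — the largest connected
  component of each clone's spots is outlined with an alpha-shape (Delaunay
  triangles kept iff circumradius ≤ 1/α); nucleus centroids are assigned by
  point-in-polygon and nuclear areas compared between clones
  (two-sided Mann-Whitney U).
- **FISH-style validation** — per-nucleus probe-count distributions
  (fractions at 0, 1, 2, 3, 4+ signals) per clone territory with a
  Mann-Whitney comparison.
- **Spatial heterogeneity index** — number of segmentation clusters with at
  least 5 spots divided by the spot count, plus a region-R² measure of the
  fraction of a gene's variance explained by tissue regions, and Moran's I
  for spatially variable gene screening.
- **Tumour-microtube quantification** — post-classification area filters
  (cells ≥ 10 µm², microtubes > 2 µm²) and microtube area per cell over
  400 × 400 µm crops, with Welch t-tests between sample groups.
- **Synthetic data** — a generator producing hexagonal spot lattices with
  two contiguous clones, negative-binomial counts with linear dosage
  effects and normal-cell contamination, matched nuclei and FISH counts, so
  the whole pipeline is testable without any sequencing data.

## Worked example

```python
import numpy as np
import spotclone as sc
from spotclone import io as scio, pipeline as pl

params = sc.default_params(seed=1)          # 40x40 hex lattice, 2000 genes
truth = sc.make_truth(params, n_informative=200, cn_gain=4)
adata = sc.simulate_counts(truth)

cfg = dict(scio.CONFIG_DEFAULTS)
cfg["seed"] = 1
clone_map, report = pl.run_map_clones(
    adata, truth.annotation, truth.profiles, cfg,
    truth_clones=dict(zip(truth.clone_field.spot_id, truth.clone_field.clone)),
)
print(f"clone accuracy vs truth: {report['clone_accuracy']:.3f}")
print(f"concordance with Leiden-style control: {report['concordance_with_control']:.3f}")

nuclei = sc.simulate_nuclei(
    truth.clone_field, density_per_mm2=400.0,
    area_lognormal_params_per_clone={"A": (np.log(60.0), 0.35), "B": (np.log(40.0), 0.35)},
    seed=2,
)
positions = adata.obs.loc[clone_map.frame.index, ["x_um", "y_um"]]
assigned, area_stats = pl.run_nuclei(clone_map, positions, nuclei, cfg)
print(f"median nuclear area: clone A {area_stats['median_A']:.1f} um^2, "
      f"clone B {area_stats['median_B']:.1f} um^2 (p = {area_stats['p_two_sided']:.2e})")
```

prints

```
clone accuracy vs truth: 1.000
concordance with Leiden-style control: 0.995
median nuclear area: clone A 59.4 um^2, clone B 40.0 um^2 (p = 2.94e-276)
```

The per-spot clone map recovers the simulated clone field exactly; the
spatial and non-spatial clusterings agree on 99.5% of spots; and nuclei
assigned to the daughter-clone territory (enriched for polyploid cells in
the simulated contrast) have ~1.5× larger median area than those of the
ancestral clone, a difference the rank test detects overwhelmingly at
~4900 nuclei.

The same stages are available from the shell:

```bash
spotclone simulate --out sample/ --seed 1
spotclone map-clones sample/ --out results/ --seed 1
spotclone microtubes structures.csv --out mt.json
spotclone full --out run/ --seed 1
```

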