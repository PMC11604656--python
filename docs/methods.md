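# Methods

This note documents the models, parameter choices and numerical decisions
behind `spotclone`, and what the synthetic experiments do and do not show.

## Data model and formats

The in-memory container is an `AnnData` with spots as observations: raw
integer counts in `X`, lattice indices and micrometre coordinates in
`obs`, the normalized matrix in `layers["lognorm"]`, and a record of every
applied filter in `uns["qc_state"]`. On disk the pipeline speaks the 10x
dialects: a gene×spot MatrixMarket coordinate-integer matrix with
barcode/feature TSVs, and a Visium tissue-positions CSV (the headerless v1
column order is the default; a headered v2 file is auto-detected by
sniffing the first line). Position files store full-resolution pixels; a
configurable `um_per_px` scale converts to micrometres at read time, and
all geometry downstream is in µm. Genomic intervals are 0-based
half-open everywhere.

## Quality control and normalization

Spots are kept when total counts and detected genes reach configurable
thresholds; real tissue sections need per-sample thresholds chosen from
count histograms, so the defaults (`min_counts=100`, `min_genes=10`) are
config values, not constants of the method. Gene filtering follows the
two conventions used for patient and xenograft material: detected in at
least 10% of spots, or in at least 10 spots. "Less than" thresholds
exclude strictly-below values only, so a gene at exactly the boundary is
kept. Normalization is library-size scaling to the median spot total
followed by `log1p`; zero-total spots must be filtered first.

Highly variable genes are ranked by variance relative to a mean–variance
trend estimated as a running median of log variance in up to 20 bins of
log mean (at least ~10 genes per bin). A running median was chosen over a
loess fit because it is deterministic, assumption-light and adequate for a
screening statistic. Spatially variable genes are ranked by Moran's I on
the normalized values over the spot graph — a fully specified substitute
for Gaussian-process spatial-variance screening that preserves the same
monotone intent (genes with spatial structure rank first). Constant genes
are skipped with a warning.

## Spot graph

Two spots are adjacent iff their centres lie within `max_dist_um`
(boundary inclusive), defaulting to 1.2 × the minimum nonzero centre
spacing: on a hexagonal lattice this captures exactly the six first-ring
neighbours (distance 1.0 × spacing) and excludes the second ring
(≥ √3 × spacing).

## Spatially smoothed segmentation

Segmentation minimises the Potts objective

    E(l) = Σ_s ‖f_s − µ_{l(s)}‖²  −  β · Σ_{(s,t)∈E} 1[l(s) = l(t)]

by coordinate descent with three strictly energy-non-increasing phases:

1. **ICM sweeps** in fixed (row-major) spot order from a seeded K-means
   initialization, each spot taking the label minimising its local cost
   and retaining its current label on ties (stability).
2. **Agglomerative merges**: pooling adjacent clusters a, b raises the
   data term by `n_a n_b/(n_a+n_b)·‖µ_a−µ_b‖²` and lowers the smoothness
   term by `β·(boundary edges)`; merges are applied greedily while the
   balance is negative. This is what lets the *effective* cluster count
   fall below K when a sample has fewer genuinely distinct regions — the
   property that makes the heterogeneity index comparable across samples
   run with identical settings. At β = 0 no merge can fire, so the plain
   K-means reduction case is exact.
3. **Hartigan-style single moves**: the exact energy change of moving one
   spot, including the centroid shift the move causes
   (`n_b/(n_b+1)·‖x−µ_b‖² − n_a/(n_a−1)·‖x−µ_a‖² − β·Δneighbours`). This
   reaches unbalanced optima that fixed-centroid ICM cannot.

ICM is a greedy descent, so a small number of restarts (default 3) from
seeded initializations are run and the lowest-energy labeling kept; the
first restart uses the caller's seed, preserving determinism and the β = 0
reduction. β defaults to 0.5 × the median within-cluster squared distance
at initialization — large enough to smooth single-spot noise, small enough
that genuine expression boundaries (which carry data-term differences far
above the noise scale) survive. On random ≤ 12-spot instances the descent
reaches the brute-force global optimum in ≥ 90% of trials (regression
test); on larger instances only monotonicity is guaranteed.

Clone mapping calls the segmenter with K = 2 and merging disabled, because
there the two-cluster structure is imposed by the question (which of two
clones?), not discovered.

The non-spatial control mirrors the standard expression-clustering recipe:
PCA (deterministic-sign SVD, default 20 components), a 15-nearest-neighbour
graph, and seeded Leiden community detection. When a fixed number of
communities is required, the resolution is bisected geometrically (the
count is monotone in resolution in practice) and any surplus communities
are merged by closest centroids.

## Clone mapping

Clone-informative genes are those overlapping any genomic region where the
two clones' copy-number profiles differ (any-overlap rule; with
whole-chromosome profiles this reduces to all genes on the differing
chromosomes). Only genes surviving QC enter the score — anything else is
unobservable. The per-spot clone score is the mean normalized expression
over this set; normalized rather than raw values are used so the score is
invariant to library size. After the two-cluster segmentation, the cluster
with the higher mean score is labelled the gain clone A (the daughter
clone carrying the extra rearrangement; the ancestral clone B is mostly
diploid at the informative loci); an inversion flag covers loss regions.
Equal cluster means within 1e-9 raise an error — polarity is genuinely
undecidable without a dosage signal. Per-spot confidence is reported as
the margin between distances to the two cluster centroids, but not
thresholded.

## Clone territories and nuclear morphology

Per-spot labels are noisy, so each clone's territory is the largest
connected component of its spots on the spot graph (ties broken by
smallest lexicographic spot id), outlined by an alpha-shape: Delaunay
triangles kept iff circumradius ≤ 1/α, returned as the union polygon(s).
α → 0 recovers the convex hull. The default α satisfies
1/α = 1.5 × spot spacing: hex-adjacent triangles (circumradius
≈ 0.58 × spacing) are always kept while triangles spanning holes wider
than about three spacings are dropped. If the alpha-shape of the largest
component is disconnected, all its boundary polygons are kept. Nucleus
centroids are assigned by point-in-polygon with boundaries counting as
inside; centroids inside multiple hulls (possible only on shared
boundaries) or outside all hulls are left unassigned. Nuclear areas are
compared between clones with a two-sided Mann-Whitney U test plus medians.

## Statistics

- **Heterogeneity index**: clusters with ≥ 5 spots divided by the QC-passed
  spot count. The 5-spot floor removes noise clusters so the index
  reflects genuine tissue regions; it is invariant to relabeling.
- **Spatial variance fraction**: `1 − pooled within-region variance /
  total variance`, an R² of the segmentation regions — a documented,
  desk-computable substitute for a Gaussian-process variance
  decomposition, with the same monotone intent.
- **Moran's I** with row-normalized adjacency weights,
  `I = (n/S0)·Σ w_ij z_i z_j / Σ z_i²`; undefined (error) for constant
  values; the permutation-null mean is −1/(n−1).
- **Mann-Whitney U**: exact enumeration p when the pooled sample has ≤ 16
  untied observations, otherwise the normal approximation with midrank tie
  correction and continuity correction; a fully tied pooled sample returns
  p = 1.
- **Hypergeometric enrichment**: upper-tail P(X ≥ k) summed in log space
  (logpmf + logsumexp), so deep-tail p-values keep full relative
  precision. The universe is an explicit parameter, as conventions differ
  (all genes vs expressed genes).
- **Benjamini-Hochberg**: the step-up `q_(i) = min_{j≥i}(p_(j)·n/j)`
  mapped back to input order.
- **Microtube group comparison**: pairwise Welch t-tests (one- or
  two-tailed) with BH adjustment. A multi-group Dunnett-style ANOVA was
  deliberately not implemented — pairwise Welch + BH answers the same
  question with standard machinery.

## Microtube quantification

Structures come from an external pixel classifier as
(sample, crop, class, area) records over fixed 400 × 400 µm crops. Cells
are kept at area ≥ 10 µm² (boundary inclusive, as printed), microtubes
strictly above 2 µm². The per-crop statistic is total microtube area per
retained cell; the per-sample value defaults to the mean over crops, with
a pooled-across-crops alternative exposed because either aggregation is
defensible. Crops with no retained cells are excluded with a warning.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analyses rely on:

- **Geometry**: offset-row hexagonal lattice, 100 µm centre-to-centre
  (Visium v1 geometry).
- **Clone fields**: a half-plane split (`half_split`) or thresholded
  Gaussian-smoothed noise (`blob`, bandwidth 300 µm by default); the blob
  threshold is the field median, which keeps the smoothed-noise geometry
  while guaranteeing both clones are populated; a re-draw loop guards the
  degenerate case regardless.
- **Counts**: `count(s,g) ~ NB(µ = L_s·β_g·[(1−c)·d_{clone(s),g} + c], θ)`
  with lognormal library factors `L_s` (log-sd 0.3) and gene baselines
  `β_g` (log-sd 1.0, scale 1.0 → ≈ 3 300 UMIs/spot over 2000 genes),
  dispersion θ = 2 in the `var = µ + µ²/θ` convention (stated explicitly
  to avoid dispersion-convention bugs), and contamination c = 0.2 by
  default. The dosage multiplier is linear in copy number
  (`d = CN/ploidy`) — a modelling choice, since no quantitative
  dosage-to-expression calibration exists; real dosage effects are
  attenuated, which the contamination parameter partially absorbs. The
  contamination is a mean mixture, not a count mixture, which keeps the
  informative-gene contrast analytic: the clone A/B mean ratio converges
  to `d·((1−c) + c/d)`.
- **Default study conditions**: 40×40 lattice, 2000 genes, 200
  clone-informative genes at copy number 4 vs 2, contamination 0.2.
  Heterogeneity experiments use 20×20 lattices with 500 genes and
  region-wise lognormal expression multipliers (log-sd 0.5) over 2, 4 or 8
  nearest-seed (Voronoi) regions — small enough that a full
  monotonicity-and-power experiment runs in minutes, large enough that
  every region can clear the 5-spot floor.
- **Nuclei**: Poisson-placed uniformly in discs of radius spacing/2 around
  spot centres at a set density (400/mm² in the full run, ≈ 3 nuclei per
  spot), with per-clone lognormal areas (median 60 vs 40 µm² for the
  simulated polyploid-vs-diploid contrast).
- **FISH counts**: `Binomial(CN, efficiency) + Poisson(false_rate)` per
  nucleus and probe — binomial detection of each true copy plus spurious
  signals.

Each generator draws from a single explicitly seeded
`numpy.random.Generator`; outputs are bit-reproducible given parameters
and seed.

Not emulated: histology images and segmentation artefacts, read-level
data, spot-boundary mixing of clones (clone fields are crisp), spatial
covariation of library size with tissue state, more than two clones, and
cell-type composition structure. Passing recovery tests therefore show
that the algorithms extract the signal they assume, under the stated noise
model — not that real tissue meets those assumptions.

## Problem sizes in the test and acceptance runs

Unit tests run on 8×8 to 10×10 lattices with ~100 genes. The acceptance
suite uses the default 40×40/2000-gene conditions (10 seeds) for clone
recovery and control concordance, 20×20/500-gene samples for the
heterogeneity experiments (10 seeds per region count, ten 5-vs-5
replicate experiments for power), 40 random ≤ 12-spot instances for the
brute-force segmentation check, and 200 replicates for each null
calibration. `scripts/acceptance.py` reports medians over 3 seeds for the
lattice-scale quantities and one full end-to-end run; all sizes are the
package's own choices for a convincing yet desk-scale experiment.

## Known limitations

- The ICM descent guarantees monotone energy but not global optimality;
  quality on large instances is assessed only indirectly (recovery and
  concordance tests).
- The forced-K resolution search for Leiden control clustering relies on
  the community count being monotone in resolution; pathological graphs
  may need the centroid-merge fallback.
- The Mann-Whitney normal approximation is used for all tied or large
  samples; p-values on heavily discrete data (FISH counts) are
  approximate, and the validation report flags probes with < 10 nuclei
  per area as unreliable rather than suppressing them.
- Clone mapping supports exactly two clones; multi-clone deconvolution is
  an extension point, not implemented.
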