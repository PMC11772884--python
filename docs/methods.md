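# Methods

`stromarch` implements the in-house spatial computations used to study
the stromal architecture of hepatocellular carcinoma (HCC) margins:
tumors either encapsulated by a fibrotic ring (FR+) — a fibroblast-dense
collagen capsule at the tumor–liver interface — or carrying
intratumoral stroma without a ring (FR−). Every stage is exercisable on
a bundled synthetic tissue generator with exact ground truth, so no
external data download is needed to test or demonstrate the pipeline.

## Spot data model and quality control (`io_core`)

Spatial expression arrives as a GEM-style TSV (`gene, x, y, count`) on
an integer spot grid with a physical pitch (0.5 µm for DNA-nanoball
chips). Coordinates are 0-based; duplicate `(gene, x, y)` records are
summed on read. `aggregate_bins` pools 50×50 spots into bin50 units
(25 µm) by half-open floor division, conserving totals and per-gene
marginals. `qc_filter` removes bins whose mitochondrial count fraction
strictly exceeds 0.25; the fraction of an empty bin is defined as 0 so
empty bins are never spuriously removed. The median-distinct-genes rule
(> 500 per bin50) is a chip-level inclusion criterion, so it is
reported, never used to drop bins. The filter is applied at bin50
resolution, after aggregation.

## Nuclei-seeded iterative segmentation (`segmentation`)

1. **Initial threshold.** Exact Otsu (between-class-variance
   maximization over every split between distinct sorted intensities)
   on a median-filtered copy of the nuclei-staining image. The exact
   search is used instead of a histogram approximation because the
   variance curve of overlapping intensity mixtures is nearly flat at
   its maximum, where histogram binning can move the argmax by more
   than a gray level. A constant image returns its constant (zero
   foreground) with a warning.
2. **Watershed with a lightness guard.** The thresholded, smoothed
   image is split at the ridges of its Euclidean distance transform
   (markers = distance-transform peaks, minimum separation 5 px).
   Each candidate nucleus must be brighter inside than around: mean
   interior intensity over mean intensity of a 2-pixel surrounding
   ring must exceed `lightness_ratio` (default 1.2, exposed as a knob
   since only the idea, not the neighborhood or value, is canonical).
   This discards smudged staining regions.
3. **Signal transform.** Raw spot counts are damped as ln(tanh(count)),
   defined as 0 at count 0 (the formula is undefined there and an
   empty spot carries no signal); `log1p` is available as an
   alternative damping with the same intent but no singularity at
   zero. The transform is monotone for count ≥ 1, so the
   expansion order below does not depend on the choice, nor on the
   logarithm base.
4. **Synchronous expansion.** All nuclei grow in rounds over the
   occupied spot grid. In each round a cell may claim the unclaimed
   occupied spots 4-adjacent to its start-of-round territory. Spots
   are processed in decreasing transformed-signal order, ties broken
   by grid position (y, then x); a contested spot goes to the
   not-yet-full cell with the nearest seed centroid, ties to the lower
   cell id. A cell stops at its class size cap — 2500 spots for HCC
   nuclei, 900 for non-HCC, class taken from the region label under
   the seed by default — or when a round claims nothing. Synchronous
   (rather than sequential per-cell) expansion was chosen because it
   is order-independent across cells and reproducible; all tie-break
   rules are deterministic, and a naive round-by-round reference
   implementation agrees exactly on randomized small grids.

`benchmark_segmentation` matches predicted and true objects greedily by
IoU (≥ 0.5) and reports object precision/recall/F1 plus the fraction of
truth-assigned spots given to the matched predicted cell.

## Margin zoning and layer enrichment (`zoning`)

The tumor–normal boundary is the set of tumor bins 4-adjacent to liver
or stroma bins in the region mask. An exact Euclidean distance
transform to that set, signed positive into the tumor, yields:

* **Layers** of one bin50 width (25 µm): index
  i = sign(d)·⌈|d|/25 µm⌉, with d = 0 on the tumor side (layer +1);
  layers beyond 2 mm per side are left unassigned by default.
* **Zones**: tumor core (d > 500 µm), tumor edge (0 ≤ d ≤ 500 µm),
  liver edge (−w ≤ d < 0, where w is 500 µm for FR− and the full
  fibrotic-ring width for FR+), distal (d < −w). d = 0 is placed on
  the tumor side everywhere for internal consistency with the layer
  convention.
* **Layer enrichment**: layers are grouped into consecutive
  non-overlapping windows of five; for type t and window i,
  value(i) = (cᵗ(i)/s(i)) / Σₖ cᵗ(k)/s(k), with the window area s(i)
  measured in bins of the distance field (not inferred from cell
  counts). Rows sum to 1 exactly; 0/0 is defined as 0 (absent types
  produce a zero row and a warning). Raw counts can first be converted
  to within-window fractions of all cells, or of a type's parent
  lineage (e.g. fibroblast subsets over all fibroblasts in situ).

Distances are Euclidean, not geodesic along the tissue; for strongly
invaginated real boundaries a geodesic variant would differ, which is a
known limitation. Tile-level scores from segmented areas are
ρ₁ = (IS₁+IS₂)/(S₁+S₂) (immune) and F₁ = S₁/(S₁+S₂) (stroma); the
upstream image classifier producing those areas is out of scope and the
areas are taken as given.

## Recurrent cellular neighborhoods (`rcn`)

Each cell's neighborhood is the count of cells of each type within
50 µm in the same tissue section, excluding the index cell by default.
The counts matrix (documents = cells, words = neighbor types) is
decomposed by latent Dirichlet allocation — batch variational Bayes
from scikit-learn, deterministic given the seed — and K-means over the
per-cell topic loadings, pooled across samples (n_init = 10, best
inertia kept), yields RCN labels. Counts rather than proportions are
fed to the topic model, matching its count-data semantics. Per-RCN
composition is the type frequency of member cells; per-patient
occurrence is the fraction of each patient's cells per RCN.

## Proximity shift analysis (`proximity`)

For a source and a target type (optionally restricted to one zone),
each source cell contributes the Euclidean distance to its nearest
target cell in the same sample (self excluded when source = target).
Distances are pooled across samples within a group; a per-sample
stratified comparison can be built by calling the estimator per sample.
Two groups are compared at percentiles 30–70 with the Harrell-Davis
estimator — the beta-weighted L-estimator of a quantile,
HD(p) = Σᵢ wᵢ x₍ᵢ₎, wᵢ = I_{i/n}(a,b) − I_{(i−1)/n}(a,b),
a = (n+1)p, b = (n+1)(1−p) — with independent bootstrap resampling per
group (2000 replicates) and bias-corrected percentile confidence
intervals; a percentile is significant when its CI excludes 0. No
cross-percentile multiplicity correction is applied. The estimator is
the standard Harrell-Davis form; a trimmed variant (dropping the
smallest beta weights) is available but off by default. Bootstrap
estimates are vectorized (one sort per resample matrix, one matrix
product per percentile), so Monte-Carlo calibration at hundreds of
replicates runs in seconds.

## Consensus-NMF metaprograms (`metaprograms`)

Per sample, rank-10 NMF (NNDSVD-a initialization, negatives clipped to
0 first) of the cells × genes matrix yields one signature per factor:
its top 100 genes by loading, ties broken by name. Signatures pooled
across samples are clustered agglomeratively (average linkage — the
linkage is not canonical, average is the symmetric default) under the
1 − Jaccard distance between gene sets, cut at a requested program
count or height. Clusters with members from ≥ 2 samples are recurrent
metaprograms; the consensus set keeps genes present in at least half of
the member signatures (an intermediate definition this package fixes,
ordered by frequency then name). Programs are scored per cell as the
mean expression of their genes — the mean is adopted throughout, with
every derived score (bulk-cohort signature scores, abundance scores)
using the same aggregation for comparability — and refined to
the 30 candidate genes (union of member signatures) most Pearson-
correlated with the score, ties by name. Only gene rankings are
consumed downstream, limiting sensitivity to the NMF solver.

## Synthetic tissue generator (`synthetic`)

The generator plants exactly the structure the analyses are meant to
recover, with one seed fanned out through spawned child generators
(sub-seeds logged in the tissue provenance):

* **Geometry.** A disk-shaped tumor (radius 900 µm in a 2.4 mm field)
  in liver; FR+ adds a stroma annulus of the configured ring width
  (default 500 µm) to the region mask. FR− intratumoral stroma is
  represented as elevated fibroblast density inside the tumor rather
  than as mask patches — mask-level patches would seed spurious
  boundary bins inside the tumor and conflate the margin-layer
  analysis.
* **Cells.** Per-zone per-type intensities (cells/mm²) realized as an
  inhomogeneous Poisson process by uniform thinning. FR+ places
  ~700 fibroblasts/mm² in the ring versus ~40 in the core; FR−
  reverses the gradient (150/mm² intratumoral, 60 outside).
* **Co-localization hubs.** Anchor cells of type A in clustered
  niches (8 niches, ~24 anchors each, Gaussian sd 20 µm), each anchor
  carrying a type-B partner with probability 0.9 at an exponential
  radial offset of scale 20 µm — a single interpretable distance scale
  whose mean the truth report verifies. CAF-FAP↔PDCD1⁺ CD8 hubs sit in
  the FR− tumor core; CAF-C7↔SPP1⁺ macrophage hubs in the FR+ ring;
  FR+ cores carry both hub types scattered (not co-localized) so group
  comparisons have a null side. Niche size follows from an explicit
  design rule: background cells within one niche radius plus one
  neighborhood radius (~70 µm) of a niche center acquire the hub's
  neighborhood profile and join the hub's RCN, so anchors per niche
  are set to at least twice the expected background cells of the
  densest type in that halo (~12 at 800 HCC/mm²). The resulting
  ~45-cell aggregates have the size and density of small lymphoid
  aggregates.
* **Expression and image.** Each cell emits ~Poisson(300) transcripts
  scattered uniformly over a 4 µm-radius footprint and snapped to the
  spot grid; genes are drawn from type-specific marker means plus
  shared background genes, with 5% mitochondrial counts. The nuclei
  image renders a Gaussian blob (σ = 2 µm) per cell plus additive
  noise; the segmentation preset enforces a 14 µm hard-core separation
  (blobs ≥ 3σ apart, disjoint footprints, ~250 cells per 0.16 mm²
  field), the regime the seeded segmentation targets.

What the generator does **not** emulate: irregular or invaginated tumor
boundaries, touching/overlapping nuclei, cell-shape anisotropy,
segmentation-confounding ambient RNA, spatial expression gradients
within a zone, or patient-level covariates. Passing tests therefore
demonstrate correctness of the computations and recoverability of
planted structure under these idealized conditions, not performance on
real chips.

## Problem sizes used in tests and the acceptance script

Margin tissues are 2.4 × 2.4 mm with ~6000 cells each; segmentation
fields are 0.4 × 0.4 mm (~250 cells, ~75k transcripts); expression
cohorts are 4 samples × 200 cells × 1000 genes with 3 planted programs
of 100 genes. The test suite sweeps 10 seeds for structure-recovery and
direction-of-effect properties and 200 null replicates (n = 200 per
group) for the type-I calibration of the shift test; the acceptance
script uses 3–5 seeds per quantity to keep a full from-scratch rerun
fast. These sizes were chosen so planted effects are comfortably above
sampling noise while a complete run stays interactive.

## Numerical conventions

* Ties everywhere break deterministically (grid position, lower cell
  id, gene name), so identical inputs and seeds give identical output.
* Bias-corrected bootstrap proportions are clipped to
  [1/(B+1), B/(B+1)] before the normal quantile transform.
* CI endpoints are widened to include the point estimate when the BC
  percentile interval would exclude it.
* Layer/zone assignment of a cell uses the signed distance of the bin
  containing it; cells outside the mask extent are flagged unassigned.
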