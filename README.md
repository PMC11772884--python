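# stromarch

Spatial analysis of tumor stromal architecture for high-resolution
spatial transcriptomics of hepatocellular carcinoma (HCC) margins.

Some HCC tumors are encapsulated by a **fibrotic ring** (FR⁺) — a
fibroblast-dense capsule at the tumor–liver interface — while others
(FR⁻) carry intratumoral stroma and no ring. The two architectures
organize immune cells differently, and quantifying that organization
requires a chain of spatial computations that this package implements
as a tested, reusable library with a CLI:

* **Nuclei-seeded iterative cell segmentation** of sub-micron spot
  grids: exact-Otsu thresholding of the nuclei stain, marker watershed
  with an interior-vs-surround lightness guard, then synchronous
  expansion of every nucleus over occupied RNA spots in order of
  decreasing ln(tanh(count)) signal, capped at 2500 spots for HCC and
  900 for non-HCC cells.
* **Tumor-margin compartmentalization**: exact signed Euclidean
  distance to the tumor–normal boundary; 25 µm layers; the four zones
  tumor core / tumor edge / liver edge / distal split at 500 µm (the
  liver edge widens to the full ring width in FR⁺ tumors); and the
  area-normalized layer enrichment
  value(i) = (cᵗ(i)/s(i)) / Σₖ cᵗ(k)/s(k), plus the tile scores
  ρ₁ = (IS₁+IS₂)/(S₁+S₂) and F₁ = S₁/(S₁+S₂).
* **Recurrent cellular neighborhoods (RCN)**: 50 µm neighborhood
  type-count matrix → latent Dirichlet allocation → K-means over topic
  loadings, with per-RCN composition and per-patient occurrence.
* **Proximity shift analysis**: nearest-neighbor distances between two
  cell types compared across groups at percentiles 30–70 with the
  Harrell-Davis quantile estimator, HD(p) = Σᵢ wᵢ x₍ᵢ₎ with
  regularized-incomplete-beta weights, and bias-corrected bootstrap
  confidence intervals.
* **Consensus-NMF metaprograms**: per-sample rank-10 NMF signatures
  (top 100 genes/factor), 1 − Jaccard hierarchical clustering into
  recurrent programs, mean-expression scoring, top-30 refinement by
  correlation with the program score.
* **A ground-truthed synthetic tissue generator** emulating both
  architectures — per-zone Poisson cell intensities, planted
  co-localization hubs (CAF-FAP↔PDCD1⁺ CD8 in FR⁻ cores,
  CAF-C7↔SPP1⁺ macrophages in the FR⁺ ring, exponential pair offsets
  of scale 20 µm), marker and mitochondrial genes, a matching nuclei
  image, and the exact spot-to-cell map — so every stage is testable
  without any data download.

See `docs/methods.md` for the full model descriptions, parameter
defaults, and known limitations.

## Worked example

Simulate an FR⁺ and an FR⁻ tissue, zone them, and compare how close
PDCD1⁺ CD8 T cells sit to FAP⁺ fibroblasts in the tumor core of each
architecture:

```bash
stromarch simulate --archetype FRpos --seed 2 --out frpos/
stromarch simulate --archetype FRneg --seed 3 --out frneg/
stromarch zones --cells frpos/cells.csv --mask frpos/region_mask.tif \
    --group FRpos --fr-width-um 500 --out frpos_zoned.csv
stromarch zones --cells frneg/cells.csv --mask frneg/region_mask.tif \
    --group FRneg --out frneg_zoned.csv
python - <<'PY'
import pandas as pd
pd.concat([pd.read_csv("frpos_zoned.csv"), pd.read_csv("frneg_zoned.csv")]) \
  .to_csv("all_zoned.csv", index=False)
PY
stromarch shift --cells all_zoned.csv --source CAF-FAP --target CD8_PDCD1 \
    --zone tumor_core --boot 2000 --seed 0 --out shift.csv
```

which prints the shift table (group a = FR⁺, group b = FR⁻):

```
 percentile      hd_a     hd_b     delta    ci_low   ci_high  significant
         30 34.406241 4.703334 29.702908 22.587212 39.843371         True
         40 41.144775 5.569470 35.575304 26.964872 46.191185         True
         50 49.027463 6.783416 42.244046 30.862491 53.307827         True
         60 56.449525 8.001323 48.448202 38.067331 63.770961         True
         70 66.847383 9.583615 57.263768 43.501135 69.479847         True
```

Every percentile difference is positive with a confidence interval
excluding zero: in the FR⁻ tumor core a FAP⁺ fibroblast's nearest
PDCD1⁺ CD8 T cell is ~5–10 µm away (inside a planted hub), versus
~34–67 µm in the FR⁺ core where the same types are scattered — the
co-localization hub, recovered from coordinates alone. The same cell
tables feed `stromarch enrich` (fibroblast enrichment peaking in the
ring layers for FR⁺ and in intratumoral layers for FR⁻), `stromarch
rcn` (hub pairs isolated as distinct neighborhoods), and `stromarch
segment` / `stromarch mp` for the segmentation and metaprogram stages.

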