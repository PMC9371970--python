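# celldissect

Image-guided single-cell laser-microdissection proteomics, as one tested
Python pipeline: evaluate instance segmentations, discover morphology
phenotypes, plan laser-microdissection (LMD) cuts and export them as
contour XML, run the downstream low-input proteomics statistics, and map
class-level proteome results back onto the source image.

The package is for computational biologists building or validating
microscopy-to-proteomics workflows: every stage runs on synthetic
fixtures with known ground truth, so the whole loop — image → segmented
cells → phenotype classes → dissected samples → differential proteins →
tissue heat map — is exercisable and testable without any external data.

## What it computes

- **Segmentation evaluation** — objects matched one-to-one by
  intersection-over-union (Jaccard index), a pair counting only if
  IoU > t (default 0.7):

  precision(t) = TP/(TP+FP), recall(t) = TP/(TP+FN),
  F1(t) = 2·precision·recall/(precision+recall),

  reported per image and as mean ± s.e.m. over images. A classical
  threshold + distance-transform-watershed baseline segmenter is
  included; learned segmenters plug in via a simple contract.
- **Phenotyping** — per-object nuclear area, perimeter, solidity, form
  factor (4πA/P²), staining intensities and neighbor counts; supervised
  marker gating; and an unsupervised phenotype finder (k-means on
  z-scored features, classes numbered by descending frequency).
- **LMD planning** — polygonized contours with an outward safety offset
  (Minkowski buffer), travel-minimizing cut order (exact for ≤ 10 cuts),
  least-squares affine scan→stage registration from fiducials, 384-well
  routing, and nanometer-exact contour XML export/import. Closed-form
  arithmetic: cutting accuracy 10/magnification µm; cells per area =
  area × thickness / 2,000 µm³.
- **Proteomics statistics** — 30% valid-value filter, downshifted-normal
  imputation N(µ − 1.8σ, (0.3σ)²), SAM-style s0-moderated t-test
  (s0 = 0.1) and one-way ANOVA with permutation-based FDR (5%), and
  Fisher-exact term enrichment with Benjamini–Hochberg correction.
- **Spatial integration** — median-per-annotation class scores z-scored
  across classes, painted onto cell centroids as a tissue heat map.

## Worked example

`examples/04_proteomics_stats.py` generates a synthetic two-group
proteome (1,000 proteins, 4 replicates per group, 100 planted effects of
2.0 log2 fold change, missing-not-at-random dropout) and runs the full
statistical workflow:

```
matrix: 1000 proteins x 8 samples, 7.4% missing
after 30% valid-value filter: 925 proteins
101 significant at permutation FDR 5% (70 label permutations)
sensitivity 0.98, false discoveries 7 of 101
planted_pathway    p= 5.26e-40 q= 3.16e-39 ENRICHED
random_term_0      p= 6.54e-01 q= 9.81e-01
...
```

Reading the numbers: the filter keeps proteins quantified in ≥ 70% of
samples; the permutation test (all 70 distinct 4-vs-4 label
assignments) flags 101 proteins at an estimated FDR of 5%, recovering
98% of the planted effects with 7 false discoveries — consistent with
the nominal rate; and the enrichment test isolates the term the effects
were planted in, leaving random terms flat.

The other examples cover segmentation + evaluation (`01`), phenotype
discovery (`02`), cut planning with registration, well routing and XML
export (`03`), and the spatial tissue heat map (`05`). Each prints what
it computes and what the numbers mean. A thin CLI mirrors the main
steps (`celldissect --help`).

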