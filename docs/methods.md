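# Methods

This note documents the models, conventions and numerical choices behind
`celldissect`, in the order the pipeline runs: synthetic fixtures →
segmentation → evaluation → phenotyping → cut planning → proteomics
statistics → spatial re-integration.

## Coordinate and statistical conventions

- Pixel (row r, col c) has its physical center at ((c + 0.5)·px,
  (r + 0.5)·px) µm, origin at the image top-left, x rightward, y downward.
  All centroids and contours use this convention.
- Sample standard deviations use the n − 1 denominator everywhere
  (z-scoring, s.e.m., imputation column statistics, pathway z-scores).
- All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed gives byte-identical fixtures and identical statistical output.

## Synthetic fixtures

The image generator places non-overlapping rotated ellipses on a noisy
background. Per class it draws area (normal, 10% CV, truncated at 20% of
the mean), eccentricity (uniform in the class range) and a per-object
mean intensity (normal, stated CV); pixels get multiplicative log-normal
texture (σ = 0.1) plus additive Gaussian camera noise. Placement is
rejection sampling with at most 100 attempts per object and a 4 px
clearance between objects; in dense fields some objects may not place,
and the truth table records what did. The default six morphology classes
use frequencies (0.33, 0.30, 0.28, 0.03, 0.03, 0.03) — three common and
three rare classes — with distinct area/eccentricity/intensity so the
standard feature set separates them. The per-class parameter values are
free choices of this package: they exercise area, perimeter, solidity,
form-factor and intensity discrimination and are not claims about any
particular cell line.

What the generator does *not* emulate: touching/overlapping nuclei,
intensity gradients and vignetting, out-of-focus blur, tissue
autofluorescence, and non-elliptical shapes. Passing tests therefore
demonstrate correctness of the algorithms under controlled conditions,
not segmentation performance on real tissue.

The proteome generator draws per-protein baseline log2 abundance from
N(25, 2) (typical label-free intensity scale), adds the planted log2
fold change to group 2 for the first `n_true_effects` proteins, and adds
within-group noise N(0, 0.3). Missingness is left-censoring: a cell with
true intensity x drops out with probability sigmoid(slope·(midpoint − x));
defaults (midpoint 21, slope 1) give a few percent missingness
concentrated in low-abundance proteins — the regime in which
downshifted-normal imputation is the appropriate fill-in. Defaults
(1,000 proteins, 2 × 4 replicates, 100 effects of 2.0 log2FC, sd 0.3)
are the conditions the validation simulations use.

Planted-cluster feature clouds for phenotype benchmarks place k class
centers as a regular simplex with pairwise distance `separation_sd`
(unit within-class sd), built by centering k scaled identity rows and
embedding the rank-(k−1) configuration via SVD.

## Baseline segmentation

Gaussian blur (default σ = 1 µm) → global threshold (Otsu default, Li or
a fixed value) → removal of objects below `min_area_um2` (default
10 µm², suppressing speckle) → distance-transform watershed. Watershed
seeds are local maxima of the distance transform *after* smoothing it
with a 2 px Gaussian, constrained to be at least `split_footprint_um`
(default 8 µm) apart: the smoothing removes discretization plateaus on
the medial ridge of elongated nuclei that would otherwise over-seed
them, while genuinely touching nuclei keep two distinct maxima. Output
labels are renumbered in raster-scan order of centroids, making the
operation a pure function of image and parameters. Deep-learning
segmenters plug in through the `Segmenter` contract; the package ships
only the classical baseline.

## Segmentation evaluation

IoU (Jaccard) of two objects is |a∩b| / (|a| + |b| − |a∩b|), computed
for all pairs at once from the joint label histogram. A pair is eligible
only if IoU is *strictly greater* than the threshold t (default 0.7).
The one-to-one matching maximizes the number of matched pairs and, among
maximum-cardinality matchings, total IoU (assignment with reward
K + IoU, K larger than any achievable IoU sum). At t ≥ 0.5 the matching
is unique regardless, since no object can exceed 0.5 IoU with two
partners. 0/0 conventions: precision (recall) is defined as 1 when its
denominator is 0; F1 is 1 only when both masks are empty, else 0 when
TP = 0. Batch evaluation reports mean F1 ± s.e.m. (sd/√n across images).

## Phenotype features and classification

Per object: area = pixel count × px²; perimeter = length of the
marching-squares 0.5-level boundary after smoothing the closed contour
with a circular 3-point moving average — the raw marching-squares
polygon overestimates a digital disk's perimeter by ~4–5%, and the
smoothing keeps a disk's form factor within a few percent of 1 at radii
from 3 px up (tolerance 1.05 for tiny objects); solidity = area /
convex-hull area; form factor = 4πA/P² (1 for a perfect disk); total and
mean intensity per channel; neighbor count = objects with centroid
within a radius (default 50 µm, configurable).

The unsupervised phenotype finder z-scores the selected features and
runs k-means with 25 restarts from a fixed seed. k is a required user
input (no automatic model selection is implied by the method); classes
are renumbered 1..k by descending frequency so labels are stable across
runs. Features are standardized before clustering because the per-class
summaries are reported in z-scored units; a constant feature is rejected
rather than silently dropped. Marker gating assigns class 1 when the
chosen statistic (mean or total channel intensity) strictly exceeds the
cutoff, class 2 otherwise.

## LMD cut planning

Objects are polygonized into one outer marching-squares contour each
(holes discarded — the laser cuts outer boundaries only), stored
counter-clockwise in µm. The safety offset is a Minkowski buffer with
round joins (32 segments per quadrant); offset 0 is the identity and
negative offsets are rejected. Cut ordering minimizes the open-path
stage travel through contour centroids from a fixed start: exact
Held–Karp dynamic programming for n ≤ 10, nearest-neighbor + full 2-opt
beyond, with deterministic tie-breaking by object id. Centroids, not
laser entry points, define the travel metric; entry-point optimization
is out of scope.

Scan→stage registration is a 6-parameter least-squares affine fit from
≥ 3 non-collinear fiducial pairs. An affine (rather than similarity)
model absorbs slight anisotropy between the two microscopes; the RMS
residual is always reported so a bad fiducial is visible. Collinear
fiducials (rank < 2 after centering) are rejected.

Closed-form throughput arithmetic: theoretical cutting accuracy is
10/magnification µm (≈ 70 nm at ×150); the expected cell content of a
dissected area is area × section thickness / 2,000 µm³ (average
mammalian cell volume), e.g. 80,000–160,000 µm² of a 2.5 µm section ≈
100–200 cells. Well routing sends each class to a stated well or fills
consecutive wells with fixed-size batches (384-well ids A1..P24), and
reports per-well object counts and summed area so samples can be
normalized by collected object count or by area.

The contour XML dialect stores three calibration points and per-shape
vertex lists as integer nanometers (µm × 1000, round half up, i.e.
⌊x + 0.5⌋). Write→read round-trips are exact at nm precision. The
dialect is this package's own documented stand-in for proprietary vendor
schemas.

## Proteomics statistics

- **Filtering**: proteins flagged as decoy/contaminant/site-only are
  removed; zeros are treated as missing; a protein is kept iff its
  missing fraction is ≤ 0.30 (a protein missing in exactly 30% of
  samples is retained).
- **Imputation**: per sample column with observed mean μ and sd σ, each
  missing cell is drawn from N(μ − 1.8σ, (0.3σ)²). Per-column (rather
  than whole-matrix) statistics follow the common convention for this
  imputation; the choice matters little when columns share a scale.
- **s0 t-statistic**: d = (mean_a − mean_b)/(s0 + se), se the pooled
  two-sample standard error; s0 = 0 recovers Student's t exactly; s0
  (default 0.1) damps large fold changes with tiny variance.
- **ANOVA**: classical one-way F; with two groups F = t² exactly; a
  1e-12 variance floor keeps all-identical proteins finite.
- **Permutation FDR**: candidate cutoffs are the observed |statistic|
  values. FDR̂(c) = median over permutations of #{|stat_perm| ≥ c} /
  #{|stat_obs| ≥ c}; a protein's q-value is the minimum FDR̂ over
  cutoffs at or below its own |statistic| (monotone non-increasing in
  |statistic|); proteins with q ≤ the target (default 0.05) are flagged.
  Group-label assignments are enumerated exhaustively when their number
  is ≤ `n_perm` (default 250; e.g. all 70 assignments for 4 vs 4),
  otherwise `n_perm` seeded random permutations are drawn. The median
  (not mean) null count is used. One documented consequence of the
  median with small designs: at the very top cutoff the null exceedance
  count is integer-valued, and when the observed labeling's maximum
  exceeds the median of all relabelings' maxima — which happens by
  chance in a sizeable fraction of pure-null datasets — the estimated
  FDR at that single cutoff is 0 and the top protein alone is flagged.
  The fraction of proteins affected is tiny (~1/1,000 in the validation
  simulations); the error-control simulation therefore reports the
  false-positive *fraction* among tested proteins. The null simulation
  uses complete matrices: under missing-not-at-random censoring,
  downshift imputation gives proteins whose dropout happens to
  concentrate in one group a genuine group difference, which measures
  the imputation model rather than the FDR estimator.
- **Enrichment**: one-sided Fisher exact test per term on the 2×2 table
  (in-term × significant) within the background, equal to the
  hypergeometric upper tail; Benjamini–Hochberg across the terms of one
  run; the reported z-score is the standardized deviation of the in-term
  significant count from its hypergeometric expectation. Terms with no
  quantified members are skipped with a warning.

## Spatial re-integration

Per-class geometry XML files (the package's LMD dialect or a minimal
generic polygon dialect) are aggregated into one cell table; centroids
come from the exact polygon (shoelace) formula. A term's score for a
class is the *median* level of the term's quantified member proteins in
that class's proteome, z-scored across classes. Scores are computed per
class and painted onto every cell of that class — the proteomes are
measured per class, so per-cell scores would misrepresent the data.
Whether to normalize across classes or across the whole slide is
genuinely open; z-across-classes is the default and raw medians are
available (`zscore=False`) for any other normalization. The heat map
uses a symmetric diverging scale centered at 0, with a neutral "no data"
color for classes lacking a score (reported in the log).

## Problem sizes used in validation

The test suite validates on: 512×512 px fixture fields of 50 nuclei (10
seeds) for segmentation; 200 random small mask pairs (≤ 6 objects/side)
against exhaustive matching; 3,000-point six-class clouds for phenotype
recovery; exhaustive-permutation cut ordering up to n = 8; 100 random
polygons for offset geometry; 10,000 imputed cells for imputation
moments; 20 null datasets of 1,000 proteins (4 vs 4) plus one
planted-effect dataset for error control and power; all 2×2 tables with
N ≤ 50 against direct hypergeometric summation; 100 random cut plans for
XML round-trips. These sizes were chosen so each check is statistically
meaningful at desk scale.

## Known limitations

- The baseline segmenter is a comparator-grade classical method; it is
  not expected to approach learned segmenters on real tissue.
- The neighborhood feature is a centroid-radius count, a deliberate
  reduction of richer neighborhood descriptors.
- The permutation-FDR estimator is validated by simulation, not by
  output equality with any external implementation.
- The LMD XML dialect is not a vendor schema; adapters are expected for
  real instruments.
- Throughput figures of real hardware (contours/hour) are outside the
  software's scope.
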