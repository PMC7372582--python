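# Methods

This note records the models, parameter choices and numerical conventions
behind `phenoscreen`, and what the synthetic-data experiments do and do not
demonstrate about real screens.

## Profiling pipeline

The preprocessing order is fixed: cells → image medians → QC → per-plate
DMSO normalization → feature selection → global scaling → well medians.

* **Aggregation.** Both the image- and the well-level aggregate are the
  median. The image level is median-by-construction (robust against
  segmentation outliers); the well level reuses the same statistic for
  consistency and robustness. Missing feature values are ignored by the
  median.
* **QC.** An image is removed when its cell count is *strictly* below
  `min_cells` (default 20; a 20-cell image is kept) or when an external
  image-quality flag marks it. Which imager-specific quality metrics define
  "low quality" is left to the caller: the API accepts a generic per-image
  flag set rather than hard-coding any one metric.
* **DMSO normalization.** Every feature is divided by the plate's median
  over DMSO image profiles, so per-plate DMSO medians equal 1 exactly
  afterwards (to the last bit when the DMSO count is odd, to ~1e-12
  otherwise). A feature whose DMSO median is 0 on any plate is dropped
  instead of being rescued with an epsilon — division artifacts would
  otherwise dominate downstream distances. A plate with no surviving DMSO
  image is a hard error since nothing can anchor it.
* **Feature selection** runs in a fixed order: (1) features with any
  missing value; (2) zero variance, or near-zero variance with the
  conventional thresholds — frequency ratio of the two most common values
  ≥ 95/5 *and* distinct-value fraction ≤ 10%; (3) greedy pairwise-Pearson
  elimination at |r| > 0.95: repeatedly take the most correlated violating
  pair and drop its member with the larger mean absolute correlation to all
  remaining features (ties broken by reverse-lexicographic name for
  determinism). The procedure is idempotent and leaves no retained pair
  above the cutoff on the data used for selection. Selection statistics are
  computed per cell line, since each line is analysed separately throughout;
  cross-line work (model transfer) intersects the per-line feature sets.
* **Scaling** is the standard z-transform (subtract the global mean, divide
  by the global population SD). A zero-variance feature reaching this stage
  is a hard error — it indicates a broken upstream filter.

## MoA classifier

A 500-tree random forest in which each tree is fit on a class-stratified
balanced bootstrap: from every class, `n_min` observations (the smallest
class size) drawn with replacement. This mirrors the stratified
`sampsize` balancing of classical random-forest implementations and keeps
votes unbiased by class frequency; the installed scikit-learn has no such
sampling mode, so the ensemble loop is implemented here over
`DecisionTreeClassifier` (per-split feature subsampling `sqrt`, default
tree depth unlimited). Out-of-bag votes are accumulated per observation
from the trees that did not draw it; `oob_error_` is the vote-majority
error over observations with at least one OOB vote. Class probabilities
are tree-vote fractions — simple, monotone in evidence, and exactly what a
"percent of trees" readout reports.

Training observations are well profiles; the three screened concentrations
of each reference compound are pooled under one class label, and DMSO
wells form their own class (reference embeddings show vehicle controls
clustering apart, so the vehicle phenotype is treated as one of the
classes). Leave-one-cell-line-out CV trains on the pooled other cancer
lines and tests on the held-out line; it requires a shared feature set
(`harmonize_features`), and reports per-fold accuracy, confusion matrix
(row-normalised diagonal = per-class sensitivity) and the training OOB
error, since "accuracy" for such panels is quoted both ways in the
literature.

## Hit calling

* **Phenotypic.** PCA (default 15 components, or the smallest number
  explaining a target variance fraction) on a line's well profiles; the
  DMSO wells' scores give the reference mean and covariance. The score is
  the *squared* Mahalanobis distance, computed by Cholesky solve (never an
  explicit inverse); the squared convention matches the magnitude of
  screen-scale thresholds like 1500. Thresholding is strict (`>`). Because
  an absolute threshold is data-scale-specific, the default on synthetic
  data calibrates per line from the DMSO null: for a Gaussian reference
  estimated from n wells, the distance of an independent point follows
  p(n−1)(n+1)/(n(n−p)) · F(p, n−p), and the threshold is that law's
  99.9th percentile (a χ² approximation and empirical quantiles are also
  available). Ledoit-Wolf or fixed-λ shrinkage toward scaled identity is
  available when DMSO wells are scarce relative to the dimension.
* **Viability.** z = (nuclei count − plate DMSO mean)/plate DMSO SD,
  per plate by default (screen-wide pooling is a config option), then the
  median over a compound's replicate wells. A line-level hit is z ≤ −3.
* **Selectivity.** Phenotypic: hits in ≥ 2 cancer lines and in *no*
  control line. Viability: a line-level hit counts only if at least one
  control line sits ≥ 2 z-units above it (z_control − z_EAC ≥ 2; at the
  boundary, an EAC z of −3 qualifies with a control z of exactly −1), and
  ≥ 2 cancer lines must qualify. Compounds missing a required line are
  flagged incomplete and excluded rather than guessed. The final hit list
  is the union of both selective sets with per-source provenance.

### A calibration caveat for multi-plate screens

The χ²/F calibration of null distances is a *within-plate* statement. With
several plates, the per-plate DMSO median is estimated with error δ_p;
dividing by it shifts every treated well on plate p by −δ_p, while the
plate's DMSO wells — which generated the estimate — are re-centred around
it. PCA then finds the inter-plate offset direction (it carries real
variance), and query wells show systematically larger distances along it
than the self-normalised DMSO reference predicts. On two-plate null
screens this inflates the mean squared distance by ~10–15% at a few
hundred DMSO wells per plate; at screen scale it argues for per-plate
references or generous null quantiles rather than literal χ² thresholds.
The package's null-calibration test therefore runs on a single
high-density plate, where the χ² statement holds (measured ≈ 4% above the
component count over 10 seeds).

## Response clustering and embeddings

Compound × cell-line matrices of z-scores or Mahalanobis distances are
centered and scaled per compound row (sample SD; constant or incomplete
rows are excluded and reported). Cell lines are compared by
1 − Spearman ρ (range [0, 2]; rank-based, hence invariant to monotone
transforms of any one line's responses) and clustered with complete
linkage; both axes can be clustered for biclustered heat maps. Dendrograms
export to Newick and JSON merge lists. t-SNE (perplexity 30, 1000
iterations, seeded) is provided for visualisation only. Dose trajectories
project a compound's dose series into a fitted reference PCA space and
report, per ascending dose, the distance to the DMSO centroid and the
nearest reference class by class-centroid distance — a quantitative stand-in
for what is usually judged visually on overlay plots.

## Synthetic screens

The generator emulates the data layer of an 8-line Cell Painting screen
(6 EAC-like lines, 2 tissue-matched controls), with per-cell features

    x = plate_effect × (baseline(line) + signature(class) × dose_scale + ε)

* `n_features` 733; cell-level noise ε ~ N(0, 1); per-line baselines
  U(5, 15) per feature (positive, so median division is well defined).
* Class signatures are sparse: a random 10% of features shifted ±
  `effect_size` (default 2.0) cell-level SDs; sparsity mirrors
  channel/compartment-localised phenotypes and keeps feature selection and
  classification non-trivial. Signatures are line-invariant by default
  (class phenotypes transfer across lines); `line_specific_signatures`
  draws private per-line signatures to study transfer failure.
* Dose scaling 0.25/0.6/1.0 at 0.1/1/10 µM — a modelling choice; no
  dose-response shape is implied by the assay itself.
* Plate effects are log-normal multiplicative per (plate, feature), SD
  0.05 on the log scale; removed exactly by DMSO-median division.
* Cell counts per image ~ Poisson(300); a fraction (default 2%) of images
  are artifacts drawn uniformly in [0, 19] cells, i.e. below the QC
  threshold by construction. Nuclei counts per well are the summed
  per-image counts with artifact images excluded by default (image QC
  applies to counting as well as morphology; raw sums are available).
* The screening library (default 500 compounds at 10 µM, single
  replicate) contains 20 planted selective actives: each gets a private
  sparse signature and a viability factor of 0.3, applied only in its 2–6
  truly active EAC lines and never in a control. An optional
  `n_group_toxic` pool gives compounds role-structured viability factors
  (one factor shared by all EAC lines, another by all controls) to create
  screens in which line *roles* form response groups, used for the
  control-clade clustering analyses.
* Everything is deterministic given the seed: identical configs produce
  byte-identical tables, and per-line tables are generated lazily so the
  full default screen never needs to be in memory at once.

What the synthetic experiments show: that the pipeline's statistics are
implemented correctly (medians, normalisation identities, selection
invariants, distance laws), that the hit-calling rules recover planted
selectivity with high sensitivity and low FDR when effects are as modelled,
and that classification and transfer behave as expected under shared vs
private signatures. What they do not show: performance on real morphology
data — real features are heavy-tailed, correlated in structured blocks,
and drift within plates (edge effects, gradients), none of which the
generator models; absolute accuracies and hit counts on real screens are
therefore out of reach by design, and only directional and calibration
properties are claimed.

## Problem sizes in the test suite

Tests run the generator at deliberately reduced sizes chosen once: unit
tests use 4-line, 96-well, tens-of-features screens; the recovery analysis
runs the full default design (8 lines × 2 plates × 384 wells, 733
features, 300 cells/image); the null-calibration analysis uses one
1536-well plate per seed (768 DMSO wells keep the covariance estimate
tight in 15 dimensions); the classifier analyses use the default reference
library (7 compound classes × 5 compounds × 3 doses × 2 wells + DMSO per
line). Random seeds are fixed in every test.
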