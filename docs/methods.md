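# Methods

## Data model

A sample is a *bag*: a `K x D` matrix of tile embeddings plus the
upper-left pixel coordinate of each 128 px tile (x = column, y = row,
0-based). Bags live in HDF5 files (`embeddings` float32, `coords` int64,
scalar metadata as attributes); a TSV manifest indexes the cohort and
carries donor ids and optional split labels. All spatial operations share
one frame, the *base grid*: cell `(y // tile_size, x // tile_size)`. A
tile whose footprint `[x, x+T) x [y, y+T)` straddles cell borders counts
toward every cell it covers, which is how overlap-tiled bags (stride <
tile size) are fused.

## Segmentation

Tile classification is non-parametric: the plurality class among the
k = 200 nearest annotated embeddings (k = 50 is the documented choice for
higher-magnification regimes; both are parameters). Distances are
Euclidean on the raw embeddings by default, cosine by flag — embeddings
from ViT-style encoders are compared directly, not through any 2-D
projection. Tie-breaks are deterministic everywhere: vote count, then
summed inverse neighbour distance (per tile) or summed vote fraction (per
base cell), then lowest class index. Base cells covered by no tile are
marked unclassified and excluded from composition denominators, so
compositions are always normalised over classified tissue.

Held-out accuracy uses `n_folds` independent stratified holdouts of
`holdout_frac` per class (defaults 10 x 10%), reporting per-fold and
median/sd accuracy. Independent draws rather than a partition were chosen
so the two knobs are free to disagree (e.g. 5 folds of 20%).

## Expression regression

Targets are log2(TPM+1) values of genes passing the expression filter
(TPM > 10 in at least ceil(0.05 n) samples, strict inequality). The model
is a single linear layer per gene, a ReLU (only to keep tile scores
non-negative), and mean pooling; the sample prediction is therefore
*exactly* the mean of the tile scores, an identity asserted in tests to
1e-12 rather than assumed.

Because the network is linear-ReLU-mean, its gradient has closed form and
the trainer is plain NumPy rather than an autodiff framework: for sample
loss `L = (1/G) Σ_g (Y_g - Ŷ_g)²`,

    dL/dW[:,g] = -(2/G)(Y_g - Ŷ_g) (1/K) Xᵀ m_g,   m_g = 1[XW+b > 0]_g

with the analogous bias term. Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8)
applies one update per sample (batch size 1). Numerical choices worth
recording:

- **Initialisation.** W = 0 and b = per-gene mean of the training
  targets. Starting tile scores are positive, so the ReLU passes
  gradients from the first step (a zero init would be a dead network),
  and a constant-target cohort is fit exactly at step 0.
- **Learning rate.** Exponential decay from 1e-4 to 10% of that by the
  final epoch (`lr_final_factor`); the schedule shape is a free choice,
  only the starting value and "decaying" are fixed by the regime.
- **Bag dropout** redraws a uniform keep-fraction in [0.70, 1.00] at each
  visit; **feature dropout** (p = 0.10) uses inverted scaling so
  inference needs no correction.
- **Gene groups.** Genes are processed in groups of ≤ 500 with gradients
  accumulated across groups and a single update per sample. Each group
  contributes its genes' share (2/G per gene) of the full-MSE gradient,
  so grouping is purely a memory layout: any group size yields
  bit-identical trajectories under one seed (tested).
- **Checkpointing.** The returned model is the epoch with minimum
  validation MSE ("best on validation"); `last` is available. Splits are
  80:10:10 over *donors*, and donor-disjointness is asserted, never
  assumed.

Evaluation reports per-gene Pearson r across held-out samples; genes with
zero prediction or target variance are flagged undefined (NaN), never
silently zeroed. Heatmaps average the post-ReLU tile scores of all tiles
covering each base cell (75% overlap, stride = T/4, is the intended
regime); averaging after the ReLU keeps the map non-negative and equal to
what the model actually scores per tile.

## Spatial statistics

SSES for gene i and region R in sample S is the ratio of means
`mean_R / mean_S`; R = S gives exactly 1, positive rescaling of the
scores cancels. A flat-zero sample has no defined ratio and propagates as
missing with a reason, as does a zero-variance field in Moran's I —
undefined is never coerced to 0, which would silently rank flat genes as
"not enriched / not autocorrelated" rather than "unmeasurable". Cohort
SSES averages per-sample scores over samples whose ROI has at least
`min_roi_tiles` (default 10; single-tile ROIs make the ratio unstable)
and reports contributing-sample counts.

Moran's I uses configurable lattice weights: rook (default), queen, kNN
or inverse distance, optionally row-standardised (default on) and
optionally periodic. The periodic (torus) variant exists because it
admits an exact closed-form check — a ±1 checkerboard under
row-standardised rook weights gives I = −1 with no boundary effects. The
permutation test is one-sided for positive autocorrelation with
`p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm)`; under permutation
E[I] = −1/(N−1).

## Compositional statistics

Proportions are compositional (they sum to 1), so each phenotype of
interest is re-expressed in pivot coordinates with that part rotated
first; only the **first** coordinate — the part's log-dominance over the
geometric mean of the rest — enters the regressions. The transform is an
orthonormal isometric log-ratio basis (coordinate norms equal
centred-log-ratio norms, cross-checked against an independent clr
implementation in tests). Zeros are handled by multiplicative replacement
with δ = 0.65 / (total tiles in the sample), below the smallest
observable nonzero proportion, scaling nonzero parts by 1 − zδ so ratios
are preserved.

Covariate associations fit one OLS of the phenotype on all covariates and
report each target's coefficient conditional on the others, Bonferroni
adjusted across the family. Differential expression shares one design
matrix across genes, so the per-gene OLS fits are solved jointly through
the normal equations (validated per-gene against statsmodels) with BH
step-up at FDR 1%. The interaction model `Y = I + β₁G + β₂P + β₃P×G + ε`
uses raw (uncentred) G and P by default, as written; centring is a flag
and leaves β₃ unchanged (tested). Rank-deficient designs raise with the
offending columns named.

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
with ground truth exposed for every stage:

- **Tissue maps**: Voronoi tessellation of uniform seed points on the
  grid, each region a uniformly drawn class — the simplest mechanism
  giving contiguous multi-scale regions.
- **Embeddings**: isotropic Gaussians with class means on a regular
  simplex scaled to `class_sep * embed_sd`, so pairwise class separation
  is uniform and difficulty is one knob. Defaults (8, 1) are an easy
  regime in which tile classes are essentially noiseless.
- **Expression**: the MIL model's own generative form — per-gene linear
  scorer, ReLU, mean over tiles — plus Gaussian noise truncated at zero.
  The first `n_classes` genes are planted class markers (weight vector
  pointing at one class mean, bias 0, so the ReLU silences other
  classes); they are the ground truth for enrichment and heatmap tests.
  Default noise is *relative*: sd = 5% of each gene's across-sample
  signal sd.
- **Donors, covariates, genotypes**: samples assigned round-robin to
  donors; age/sex/BMI/ischemic-time/5 PCs at plausible post-mortem-cohort
  scales; dosages Binomial(2, allele frequency) (Hardy–Weinberg).
  Planted covariate effects shift a class proportion before
  renormalisation; planted interactions add β₃·G·P to a gene.

Reference conditions used throughout the deeper tests and the acceptance
script: 200 samples, 10x10 grid (100 tiles), D = 32, G = 50, 100 donors,
class_sep = 8, 5% relative noise. Every stream derives from
`(seed, stage, sample index)`, so generation order is irrelevant to
reproducibility.

**What passing these tests does not show.** The generator draws
embeddings i.i.d. within class — no within-region texture gradients,
staining batch effects, scanner variation or label noise — and its
expression lies exactly in the regressor's hypothesis class. Recovery
results therefore certify the estimator and the optimisation, not
real-data performance; real cohorts add model misspecification that no
desk-scale simulation exercises. Compositions here derive from a handful
of Voronoi seeds and are smoother than real substructure proportions.

## Known limitations

- The trainer is single-threaded NumPy; it is sized for desk-scale
  cohorts (minutes), not for tens of thousands of slides.
- Only the single interaction model is implemented, not a cis-window
  eQTL scan; only global Moran's I, not local indicators.
- Annotated tiles are assumed correct; there is no label-noise handling.
- Bags must share one embedding dimension per cohort; mixed encoders are
  rejected rather than projected.
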