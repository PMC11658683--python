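# Methods

`gonadci` implements a desk-scale reconstruction of a supporting-lineage
analysis of fetal mouse gonad scRNA-seq: quality control, normalization,
cell-cycle phase assignment, machine-learned Sertoli/granulosa cell-identity
scores (SCI/GCI), hyperbola-based double-positive calling, cross-dataset ICA
projection with label transfer, and proportion/score statistics. Because raw
data at atlas scale is not part of the package, a synthetic-data generator
provides inputs with known ground truth; all quantitative claims made by the
test suite and the acceptance script are statements about that generator's
output, not about any real dataset.

## Synthetic data generator

The generator (`gonadci.simulate`) emulates the structure the analysis
relies on:

- **Cell types.** Ten types of the fetal gonad: three pre-supporting states
  (PS1, PS2, cycling pre-supporting), pre-Sertoli, Sertoli, granulosa,
  supporting-like cells (SLC), gonad progenitors, Leydig and germ cells.
  Each type carries a planted marker program (default 50 genes) whose
  negative-binomial mean is multiplied by `exp(effect)` in cells of that
  type; the default effect is 1.5 natural-log units (~4.5-fold). A few
  genuine symbols (Sox9/Amh for Sertoli, Foxl2/Fst/Irx3 for granulosa,
  Pax8 for SLC, ...) seed each program for readability; the rest are
  synthetic identifiers.
- **Counts.** Negative binomial via a gamma-Poisson mixture with mean
  `nb_mean` (default 0.1 per gene per cell — deliberately sparse, giving a
  few hundred counts per cell at 2,000 genes) and dispersion 0.5.
  Per-cell library size is scaled by a log-normal factor (sigma 0.3) so
  percentile QC filters have genuine outliers to remove. Ten
  mitochondrial genes receive a per-cell count share drawn uniformly from
  1-8%.
- **Composition.** A genotype x stage mixture table assigns cell-type
  proportions for XX wild type, XY wild type and the XY *Znrf3*-null
  (`XY_Zdel`) at 11.5/12.5/14.5 dpc. The defaults encode the qualitative
  biology: XY WT progresses to a Sertoli-dominated gonad, XX WT to a
  granulosa-dominated one, and the mutant retains pre-supporting cells,
  develops XY granulosa cells and an enlarged SLC pool with few Sertoli
  cells. Each (genotype, stage) group receives `n_cells_per_type` x
  (number of nonzero types) cells (default 200 per type), split over two
  samples and assigned multinomially, so per-type counts follow the
  mixture within sampling error.
- **Double-positive cells.** A latent class: supporting-lineage cells
  convert with a per-genotype probability (defaults 0.02 XX WT / 0.05
  XY WT / 0.25 XY Z-del, reflecting the elevated double-positive burden of
  the mutant; a single scalar is also accepted) and express *both* the
  Sertoli and the granulosa program at 0.7x the log effect. They keep the
  nominal cell-type label; the `dp_truth` column records the ground truth.
  The attenuation is a modelling convenience that produces intermediate
  cells without asserting a mechanism.

Not simulated: doublets, ambient RNA, batch effects, spliced/unspliced
layers, gene-gene correlation beyond the planted programs, and realistic
library depths. Passing tests therefore demonstrate that the algorithms
behave as specified on data satisfying their assumptions, not that they are
robust to every artefact of real droplet data.

## Quality control and normalization

Cells are filtered first per sample — total counts and genes expressed
outside the 2nd-98th percentile, mitochondrial percentage outside the
2nd-95th — and then globally, dropping the bottom 5th percentile of total
counts among retained cells. Percentiles use linear interpolation (the
numpy default) and removal is strict (`< low value`, `> high value`), so a
degenerate all-equal distribution removes nothing. The three per-sample
rules are applied sequentially within a sample (counts, genes, mito), each
on the survivors of the previous one, and the report attributes each removal
to the first rule that caught it. Samples with fewer than 10 cells skip the
per-sample percentile rules (a percentile of a handful of cells is
meaningless); an `is_doublet` column, when present, is honoured before
anything else. The global 5%-of-counts rule is a percentile rule, not an
absolute count threshold: the absolute value it implies depends entirely on
the data.

Normalization scales each cell to a target sum of 10,000 counts computed
over genes *outside* the top 5% by total dataset count (ties broken by gene
order); excluded genes are still scaled and log-transformed — they are only
excluded from the size-factor denominator. A cell whose non-excluded sum is
zero falls back to its total sum (warned); an all-zero cell stays all zero.
`log1p` completes the transform. A consequence used by the tests: for every
cell with a nonzero non-excluded sum, `expm1` of its non-excluded values
sums back to exactly 10,000.

## Cell-cycle phase assignment

Module scores are computed per sample with the standard construction (mean
expression of the set genes minus the mean of seeded control genes drawn
from matching expression bins; 25 bins, 100 controls by default, via
scanpy's `score_genes`). The phase rule: S if the S score exceeds both the
G2M score and zero; G2M if its score is >= the S score and positive;
otherwise G1. Every cell receives exactly one phase. Cells without an
elevated program hover near score zero, so their S/G2M assignment is noise —
only planted-program cells are meaningfully called, which is what the tests
assert.

## Identity scoring (SCI/GCI)

**Gene assessment.** Within the training scope (XY WT cells for the Sertoli
model, XX WT for granulosa), each gene expressed in at least 3 scoped cells
is scored by the ROC AUC of its log-normalized expression against the
target-vs-rest labels, computed exactly from rank sums with midranks for
ties. Genes are ranked by `|AUC - 0.5|` descending (ties broken by gene
order); direction is positive when AUC > 0.5. Fitting a one-predictor
binomial GLM per gene and taking the AUC of its fitted scores is
mathematically equivalent for ranking — the logistic transform is monotone,
so the fitted-score AUC equals `0.5 + |AUC_raw - 0.5|` — and the package
computes the rank-sum form directly while exposing the GLM route
(`single_gene_glm_auc`) for verification.

**Model building.** Ranked genes are offered one at a time to an
unpenalized binomial GLM. A candidate is accepted iff it improves the mean
AUC over stratified 5-fold cross-validation (folds fixed once per fit,
seeded) by more than `tol = 1e-4` against the running best; the empty model
has AUC 0.5. Selection stops at 50 accepted genes, when the ranking is
exhausted, or after 20 consecutive rejections (`patience`; settable to
`None` to scan the whole ranking). The accepted trace is monotone
non-decreasing by construction. The final model is refit on all training
cells. Degenerate cases: `tol = inf` accepts nothing and raises an
"empty model" error; classes too small to stratify raise rather than
silently producing single-class folds.

**Scoring.** Every cell — including genotypes absent from training —
receives `100 x logistic(intercept + sum(coef x expression))` per model:
SCI under the Sertoli model, GCI under the granulosa model, each strictly
inside [0, 100]. Model genes missing from a query matrix are imputed as
zero expression with a warning.

Numerical choices: logistic fits use lbfgs capped at 200 iterations; on
linearly separable training data the unpenalized MLE diverges, the cap
leaves a finite, near-saturated fit whose ranking of cells is stable, which
is all the score uses. CV-AUC evaluation uses the held-out fold only.

## Double-positive calling

The region is the rectangular hyperbola `sci x gci >= a x b` with `a = 10`
and `b` the 97.5th linear-interpolation percentile of GCI among reference
cells — by default granulosa cells of 14.5 dpc XX wild-type samples, the
fully differentiated ovarian reference (at least 20 reference cells
required). Boundary equality counts as inside; either score at zero can
never be double-positive (the axes are asymptotes). The predicate lives in
one function so an alternative region shape is a one-line swap. Group-wise
DP proportions are compared pairwise by 2x2 chi-square (no Yates correction
by default), switching to Fisher's exact test when an expected count is
below 5, with Benjamini-Hochberg q-values across all comparisons.

## Cross-dataset projection and label transfer

A FastICA decomposition is fitted on the reference dataset
(arbitrary-variance whitening, so the unmixing in whitened space is exactly
orthogonal). The model stores the centre vector, the whitening matrix K and
the orthogonal rotation R; projection of a query cell x is
`R K (x - centre)`, with query genes aligned to the model's gene list by
identifier (missing genes imputed as zero; fewer than 50% present refuses
the projection as meaningless). Default 30 components. Labels are
transferred with a multinomial logistic-regression classifier trained on a
class-balanced subsample of the reference component scores — 500 cells per
class, drawn without replacement, seeded; smaller classes contribute all
their cells with a warning.

The held-out label-recovery checks run on a dataset generated with
`dp_fraction = 0`: double-positive cells are deliberately intermediate
between two programs, so a "planted label" is ill-defined for them and they
are excluded from a check that is about unambiguous labels.

## Proportion and score statistics

Per-sample cell-type proportions are computed over non-excluded types
(zero-count types appear with proportion 0; a sample with no included cells
is dropped with a warning). Pairwise comparisons pool counts across samples
within genotype (and stage) and test each cell type's 2x2 in-type/out-of-type
table by chi-square (Fisher fallback as above), BH-corrected across the run;
per-sample testing is available by grouping differently. The PCA of the
sample x cell-type proportion matrix is centred, with components capped at
the matrix rank; identical samples yield all-zero coordinates. Score
comparisons use the unpaired two-sample Wilcoxon rank-sum test, exact when
both groups are tie-free with at most 25 observations, otherwise the normal
approximation with tie and continuity correction; a pooled sample with a
single distinct value returns p = 1.

## Problem sizes

The default study conditions simulate ~15,600 cells x 2,000 genes (200
cells per type per genotype-stage group, two samples per group). The
stepwise-cap benchmark uses a two-class dataset of 600 cells with 500
individually weak but genuinely informative genes (effect 0.4 log-units),
chosen so that discrimination keeps improving gene after gene instead of
saturating — the regime in which the 50-gene cap, not a performance
plateau, terminates selection. The test suite uses a reduced variant of
the study conditions (60 cells per type, 12 markers per type, 425 genes)
for module-level checks and the full conditions for the end-to-end checks.

## Known limitations

- The exact algebraic form of the double-positive hyperbola is a design
  choice (`sci x gci >= a x b`); it honours the stated roles of `a` and `b`
  and the axis-exclusion property, but other hyperbola parameterisations
  exist and would classify borderline cells differently.
- Unpenalized logistic fits on separable data rely on the iteration cap for
  regularisation; coefficients are not interpretable as effect sizes.
- The generator's independence of genes given type means selection
  behaviour on correlated real transcriptomes (where stepwise rejection of
  redundant genes matters more) is only partially exercised.
- Cell-cycle scoring inherits scanpy's binned control-gene sampling; scores
  for cells without a planted program are noise around zero by design.
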