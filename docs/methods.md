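# Methods

This note documents the models implemented in modulonkit, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## The decomposition model

The compendium is a gene × sample matrix X of logTPM values, centered per
project on a reference condition. ICA factorises X ≈ M·A: columns of M are
statistically independent gene-weight profiles and rows of A their
activities per sample. The biological reading is that each component is a
set of genes whose expression moves together because a common regulatory
input modulates them; thresholding a column of M yields the iModulon's
member genes.

### Robustness by restart clustering

FastICA is a fixed-point method with a random initial rotation, so a
single run is not reproducible component-by-component. `run_ica` therefore
runs the algorithm `n_restarts` times (default 100 in production, 10 in
tests — the smaller setting is sufficient for the sharply identifiable
synthetic modules), pools all gene-weight vectors, and clusters them with
DBSCAN on the distance 1 − |Pearson r| (eps 0.2). Only clusters drawing on
at least ⌈n_restarts/2⌉ distinct restarts survive; each is represented by
its centrotype (the member minimising summed within-cluster distance).
Columns of M are unit L2 norm with the largest-magnitude gene weight made
positive; A is recomputed as M⁺X so the X ≈ M·A contract holds for the
reported matrices rather than for any individual restart.

Whitening is by SVD of X *without* mean removal: genes are the
observations, the top-d left singular vectors span the retained subspace,
and consequently M·A reconstructs X exactly up to the discarded singular
subspace. (Centering before whitening would silently drop the mean
direction from the reconstruction.) The contrast is log-cosh; convergence
tolerance 1e-6, at most 1000 iterations.

### Dimensionality selection

The requested component count d is swept (production default 30–100 in
steps of 10; the tests sweep around the planted dimensionality). At each d
the sweep records the robust component count and how many of those are
single-gene-like — thresholded membership empty, a single gene, or one
gene carrying ≥ half the column's squared weight. The selected dimension
is the one, among those where *every* robust component is multi-gene, that
yields the most such components (ties toward the smaller d).

Rationale: under-decomposition mixes true modules, so all components are
multi-gene and the no-single-gene condition holds trivially but
productivity is low; past the intrinsic dimensionality, surplus components
chase residual noise and collapse into single-gene or empty components.
The rule therefore finds the crossing point from above. A "smallest d with
no single-gene components" rule is not usable, since the lowest swept
dimension almost always satisfies it vacuously. When no dimension
satisfies the condition, the d minimising the single-gene shortfall is
returned and flagged approximate.

## Quality control

Order of operations is fixed: exclusion → correlation filter → centering.

* **Exclusion**: a sample is dropped if it has fewer than 500,000 mapped
  reads, failed sequence-level QC, or lacks metadata; samples left without
  a replicate partner are then dropped too.
* **Correlation filter**: within each (project, condition) group, if *any*
  pairwise Pearson r between member columns falls below the threshold
  (default 0.80; the sweep reports 0.80/0.85/0.90/0.95), the whole group
  is replaced by its unweighted arithmetic mean column. "Any pair below
  threshold" is the strictest reading of internal inconsistency; averaging
  is unweighted because no error model for individual samples is
  available. A zero-variance sample makes Pearson r undefined and is a
  named error rather than a silent NaN.
* **Centering**: each project's reference-condition mean profile is
  subtracted gene-wise from all of that project's samples, making
  activities interpretable as log fold changes against the project
  reference. The operation is idempotent.
* **Hierarchical outlier scan**: average-linkage clustering on 1 − r with
  a cut height flags singleton samples as atypical. It is advisory only —
  no principled automatic cut exists, so exclusion is left to the analyst.

## iModulon thresholding

The default method iteratively strips the largest-|weight| gene from a
component until the remainder passes a D'Agostino K² normality test
(p > 1e-4), i.e. until the heavy-tailed outlier block is gone. The
threshold is placed midway between the smallest stripped |weight| and the
largest kept one, so membership (|w| > threshold) is exactly the stripped
set and is invariant to sign flips and gene order. At least 8 genes are
always retained in the bulk so the test is defined. Components whose
weights are already Gaussian threshold to the empty set and are treated as
noise components. A mean + c·sd quantile rule (c = 3) is available as a
cheaper alternative.

## Differential iModulon activity

DIMA contrasts two sample groups per component: Δ = mean(A₂) − mean(A₁).
The null is a log-normal fitted (moment matching on logs, equivalently
MLE) to pooled |activity differences| between biological replicate pairs.
Because Δ is a difference of group means of n₁ and n₂ samples, the fitted
log-mean is shifted by log √((1/n₁ + 1/n₂)/2) — the exact variance ratio
under independent errors; without this the test is badly underpowered for
multi-sample groups. p-values are the null survival at |Δ| (two-sided by
the folding into magnitudes); significance is Benjamini–Hochberg FDR at
0.05.

Calibration caveat: when replicate scatter is Gaussian, |Δ| is half-normal
and the log-normal family fits it imperfectly (probability-integral KS
distance ≈ 0.12), in the conservative direction at small p. The p-value
uniformity property is therefore exercised with replicate differences
drawn from the assumed family; with Gaussian noise the realised null flag
rate stays well below the nominal FDR while an activity shift of 10× the
replicate sd is detected essentially always.

## Enrichment and recall

Every (iModulon, regulon) pair gets a one-sided hypergeometric tail p over
the gene universe of the expression matrix (what the decomposition
actually saw, not the whole genome), with BH correction across the full
pair grid. iModulon recall = |∩|/|iModulon| and regulon recall =
|∩|/|regulon| cut the plane into four quadrants at 0.6 (configurable; the
midline convention of the iModulon literature): well matched (both high),
regulon subset (high iModulon recall only), regulon discovery (high
regulon recall only), poorly matched.

## Operons, motifs, classification

* **Operon clustering** walks the genes of each accession in coordinate
  order and joins a gene to the current operon when the intergenic gap
  (next.start − current.end − 1) is at most the threshold (default 500 bp)
  and strands match (configurable). Overlapping genes count as gap 0. The
  result is a strict partition; raising the threshold can only merge
  operons.
* **PSSM**: per-position counts from aligned equal-length binding sites
  plus a pseudocount (default 0.5), normalised, scored as log₂
  (probability/background) in bits. The background is a required argument
  (explicit frequencies or a sequence set) because "background of the
  entire sequence" is ambiguous between sites, promoters and genome, and
  the choice shifts every score. Scanning slides the matrix at step 1 over
  both strands (reverse-complement scanning on by default, since TF sites
  are double-stranded), reporting the best window; ties break toward the
  forward strand and the smallest offset, with a 1e-9 tolerance absorbing
  summation-order rounding between analytically tied windows. Promoters
  default to the 300 bp upstream of an operon's lead gene; member genes
  inherit their operon's score.
* **Classifier**: elastic-net logistic regression (L1:L2 = 0.5) on
  standardised motif-score features. Folds are assigned in operon space —
  an operon is positive if any member gene is positive; operons are
  stratified by label and dealt round-robin — so co-transcribed genes
  (which share a promoter and hence a feature value) never straddle train
  and test. The training portion of each fold, never the test portion, is
  SMOTETomek-rebalanced: SMOTE interpolates minority points along segments
  to one of their 5 nearest minority neighbours, then Tomek links (mutual
  nearest neighbours of opposite class) are removed, both endpoints. The
  penalty weight is chosen per fold by inner 3-fold CV over a log grid
  (1e-3–1e2). AUC is computed by the Mann–Whitney rank formulation; folds
  whose test portion holds a single class are excluded from the mean with
  a warning. The resampler is implemented in-package (interpolation +
  exhaustively-testable Tomek definition) and validated against O(n²)
  brute-force neighbour oracles in the tests.

## The synthetic generator

`generate_compendium` plants K disjoint gene modules (half the genes are
members; weights ±Uniform(1.5, 2.5)) with i.i.d. standard-normal
condition-level activities shared across replicates, replicate-level
activity jitter, and Gaussian gene-level noise on the logTPM scale.
Defaults emulate a bacterial compendium of 50 conditions × 2 replicates
chunked into 13 projects (first condition of each project is its
reference) with 35 modules and replicate correlation 0.9 — the scale of a
single-organism public compendium. The jitter variance is solved
numerically so that the *expected* within-condition Pearson correlation
across genes equals `replicate_rho` exactly (the naive first-order
solution undershoots by ≈ 0.04 because the realised signal variance is
right-skewed across conditions); if the requested measurement noise alone
exceeds the implied budget, jitter is zero and the achieved correlation
falls short. `generate_genome` lays evenly sized operons head-to-tail
with exact within/between gaps, fixed-length 300 bp uniform-background
promoters, and optionally plants one motif instance (PWM sample or
consensus) per selected operon at a recorded offset. `generate_trn_table`
derives regulons that keep a chosen fraction of each module plus a chosen
number of non-members, so recall values are known by construction.

What the generator does **not** emulate: count-level (negative binomial)
noise and library-size effects, overlapping or nested regulons,
condition-dependent module activity structure beyond i.i.d. draws,
genome-scale gene-length and GC heterogeneity, and motif variants beyond
a single planted instance per promoter. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not performance on real compendia, where replicate noise is
heavier-tailed and modules overlap.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so each stage
remains sharply identifiable: compendia of 150–500 genes (2000 for the
correlation-convergence check), 10–20 conditions × 2–3 replicates, 4–8
planted modules, 10 ICA restarts; genomes of 45–200 genes in 15–60
operons; classifier experiments with 60 operons (15 positive, consensus
sites planted) and 5–20 permutation seeds; DIMA calibration over 30–50
runs of 10 components. Production defaults (100 restarts, 30–100 sweep)
are exposed on every entry point.

## Known limitations

* The robustness-clustering reconstruction (DBSCAN, eps 0.2, ≥ 50%
  restart support, centrotype representative) is one concrete choice among
  several used in the robust-ICA literature; component counts near the
  support boundary can differ between implementations.
* Explained variance uses the Frobenius-residual definition throughout;
  for non-orthogonal component subsets the per-component values do not
  sum to the joint value.
* The DIMA null ignores between-condition biological variability — it
  measures replicate-level scatter only, so contrasts across very
  different media are anti-conservative in principle; with the group-size
  scaling disabled the test is strictly conservative instead.
* Single-feature classification (best motif score) cannot separate
  regulons whose sites differ only in context; the feature matrix accepts
  arbitrary extra columns for richer models.
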