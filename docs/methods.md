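# Methods

This note documents the models, conventions, and numerical choices
behind each stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one reasonable
implementation existed.

## Consensus somatic variants

SNV consensus is an exact set intersection on (chromosome, 1-based
position, reference base, alternate base); annotation (predicted
impact, gene) is carried from the first caller's record. Germline
subtraction removes tumor calls whose key appears in a wildtype
(strain background) call set and is idempotent by construction.

Structural-variant consensus interprets the positional tolerance as
*both breakpoints independently* within the margin (100 bp for
deletions/duplications/inversions, 1,000 bp for translocations). This
is the stricter, symmetric reading of a length-difference tolerance
and makes the merged set well defined. Matching is one-to-one and
greedy: candidate pairs are ordered by |ΔposA| + |ΔposB|, ties broken
by the leftmost first-caller call, and consumed so that each call
matches at most once. On realistic jitter this greedy scheme
reproduces exhaustive minimum-distance pairing exactly (tested against
a quadratic oracle). The merged call takes the first caller's
coordinates and the pair's minimum MAPQ — a deterministic,
conservative quality summary. Filters (length > 10 kb, MAPQ ≥ 60,
wildtype subtraction under the same positional rule) commute, so their
order is irrelevant. Translocations have no length minimum, use
MAPQ ≥ 50, and must intersect an orthogonal per-sample gene-break list
by gene name.

With independent per-caller breakpoint jitter of sd σ, the
caller-vs-caller offset has sd σ√2, so a 100 bp margin retains an
event with probability ≈ (2Φ(100/(σ√2)) − 1)² per breakpoint pair —
≈ 0.999 at σ = 20 bp but only ≈ 0.96 at σ = 30 bp. Recall guarantees
are therefore stated for σ ≤ 20 bp.

Integer copy number from a segment log2 ratio is
round(ploidy · 2^log2) with half-up rounding, floored at zero;
baseline ploidy is 2 everywhere (sex chromosomes are treated as
autosomes unless the caller of the function chooses otherwise).

Conserved mutations: a gene counts for a subtype when the fraction of
that subtype's tumors carrying at least one MODERATE or HIGH impact
call in the gene is ≥ 0.66 (inclusive). Cross-subtype structure is
returned as exact Venn counts.

## Copy-number / expression correlation

Correlations are computed only for genes with a discrete copy change —
at least one sample at |CN − 2| ≥ 1 — mirroring the fact that a
constant regressor has no defined correlation; such genes emit
explicitly undefined records that downstream summaries exclude.
Kendall's τ-b (tie-corrected) comes from scipy; Pearson's r is
computed on (integer CN, expression) pairs. Significance flags are
inclusive thresholds, τ ≥ 0.3 and r ≥ 0.7; they are track-coloring
conventions, not hypothesis tests.

Differential expression is a per-gene pooled-variance two-sided
Student's t-test; the log-fold change is the group mean difference,
assuming log-scale input. Genes with zero variance in both groups get
p = 1 when the means agree (and p = 0 otherwise). No multiple-testing
correction is applied by default because the integrative gene set is a
screening step, not an inference; the p cutoff is a parameter.

The integrative gene set takes genes significant (p < 0.05) in at
least one pairwise subtype contrast that also lie in a conserved
copy-number event — same-sign |ΔCN| ≥ 1 in ≥ 66% of at least one
subtype's samples, reusing the conservation fraction defined for
mutations since no separate CNV criterion is specified anywhere — and
maps them through a mouse→human homolog table, dropping unmapped
genes. All knobs (p cutoff, conservation fraction, homolog table) are
arguments.

Ward clustering is scipy's Ward linkage on Euclidean distance with
scipy's deterministic leaf ordering. PCA standardizes features to zero
mean and unit variance, drops zero-variance features with a warning,
and always reports two components with their explained-variance
fractions.

## Single-sample GSEA

For a sample, genes are ranked by descending expression with ties
broken by gene symbol, making scores deterministic. Walking the ranked
list, an in-set gene at rank i adds |x_i|^α normalized over the in-set
genes, and an out-of-set gene subtracts 1/(N − m); the enrichment
score is the sum of the running sum over all N positions (the
integrated form appropriate for single-sample scoring). α defaults to
0.75, the conventional single-sample weighting; at α = 0 the score is
a pure rank statistic and invariant to monotone transforms of the
expression. The degenerate full-universe set has no out-of-set
penalty and returns the integrated cumulative weight sum. The rank
statistic is the expression value itself, so inputs are assumed
log-like. Matrix normalization divides all scores by the global
(max − min); the volcano comparison (mean difference and two-sided
t-test, significant iff |Δ| ≥ 0.4 and p ≤ 0.05, uncorrected) is
usually run on normalized scores.

## Mutational signatures

Catalogs use the 96 trinucleotide channels in lexicographic order
(A[C>A]A … T[T>G]T) under the pyrimidine-reference convention;
purine-reference substitutions are reverse-complemented together with
their context.

Refitting normalizes a catalog row to frequencies and reconstructs it
as a nonnegative mixture of signature profiles with weights
constrained to sum to at most one. Signatures enter by forward
selection: at each step the candidate whose inclusion most reduces the
squared reconstruction error joins, and selection stops when the
improvement falls below `tol` (default 1e-3). Weights below `cutoff`
(default 0.06) are then discarded, the survivors refit once, and the
retained weights renormalized to one; the reported residual SSE is
that of the survivor fit, and the SSE trajectory across accepted steps
(non-increasing by construction) is attached to the result. The inner
weight fit uses NNLS with an SLSQP fallback when the simplex
constraint binds; any solver reaching the same SSE is equivalent. No
trinucleotide-abundance (exome/genome opportunity) renormalization is
applied; profiles are taken as given.

## Batch adjustment

Per-gene location/scale adjustment with parametric empirical-Bayes
shrinkage. Data are standardized by the batch-size-weighted grand mean
and the pooled within-batch variance; per batch, the additive effect
γ̂ (batch mean of Z) gets a normal prior and the multiplicative effect
δ̂² (batch variance of Z) an inverse-gamma prior, hyperparameters by
method of moments across genes, iterated to a 1e-4 fixed point. The
adjusted data are (Z − γ*)/δ* restored to the original scale. Genes
with zero pooled variance are dropped with a warning; a single batch
returns the input unchanged.

Two deliberate choices: (i) after restoration each gene is recentered
to its pre-adjustment grand mean, making grand-mean preservation exact
rather than approximate (EB shrinkage otherwise leaves a small
location residual); (ii) no biological covariates enter the model, so
effect sizes are only guaranteed preserved when class proportions are
balanced across batches — the setting in which the pipeline uses it.
Shrinkage deliberately does not remove the portion of an observed
batch-mean difference attributable to sampling noise, so per-gene
post-adjustment residuals scale like f·se(γ̂); removal guarantees are
stated for the gene-averaged residual. When batch scales differ, the
output lives on the pooled scale, which rescales standardized effect
sizes accordingly.

## Subtype classifier

Feature elimination: an RBF-kernel SVM exposes no coefficients, so
features are ranked by permutation importance on the held-out fold,
averaged over a stratified K-fold (default 10 folds, 3 permutation
repeats), and the least important feature is removed each round. The
returned subset maximizes mean CV accuracy, ties going to fewer
features; the full accuracy curve is returned alongside.

The ensemble is five base learners — logistic regression (unit
regularization), RBF-SVM with probability outputs, 100-tree random
forest, 100-round gradient boosting, single-hidden-layer (64) MLP —
with widely used default hyperparameters, all exposed. Each of 15
instantiations draws an independent stratified 70/30 shuffle split
preserving class proportions, fits all learners on the training part,
and averages their class probabilities with equal weights on the test
part (soft voting; never hard votes). Scalar metrics (accuracy,
support-weighted F1, multiclass MCC) are computed per instantiation
and averaged; the confusion matrix is summed across instantiations and
pooled metrics recomputed from it are also reported, since both
conventions are defensible. The canonical class order (BASAL,
CLAUDIN_LOW, HER2, LUMA, LUMB, NORMAL) is the single tie-break
authority: argmax ties resolve to the earlier class.

Multiclass MCC is (c·s − Σ p_k t_k)/√((s² − Σ p_k²)(s² − Σ t_k²)) with
c the trace, s the total, and p/t the predicted/true marginals,
returning 0 when a factor under the root vanishes. Weighted F1 is the
support-weighted mean of per-class F1 with 0 for undefined classes.
Both are cross-checked against scikit-learn in the test suite.

Assignment averages probabilities over all learners of all
instantiations (75 probability vectors by default); mouse data must be
batch-adjusted jointly with the training data and restricted to the
model's features beforehand, and missing features raise with the gene
list.

## Survival

The product-limit estimator processes events before censorings at
tied times. Greenwood's formula gives Var Ŝ(t); pointwise 95% bands
use the complementary log-log transform; the median is the first event
time with Ŝ ≤ 0.5 (step-function convention, no interpolation) and its
CI inverts the pointwise band (Brookmeyer–Crowley): the first times at
which the lower and upper bands reach 0.5. The two-group comparison is
the standard log-rank χ² (1 df) via lifelines; a group with zero
events warns but still yields a statistic. The estimator itself is
cross-checked against lifelines in the tests.

## Synthetic cohorts

The generators define the study conditions and are pure functions of
(config, seed): one root seed plus a fixed stream tag per generator,
so outputs are bit-identical across runs and independent across
generators. Defaults mirror the motivating design: three histological
subtypes with 14 expression samples each (42 total, matching a 9-tumor
WGS / 42-sample expression cohort shape), conserved whole-block
copy-number deltas of +2, +1, and −1 (the chromosome-scale gains seen
in the microacinar-like class), expression coupled at 2 units per copy,
two-caller SV call sets with 20 bp breakpoint jitter, a 70/30
two-signature mutation mixture of 5,000 mutations, and two survival
arms at 87.7 / 163.5 month medians with 30% censoring — magnitudes a
genomics practitioner would call realistic for log-scale microarray
data and breast-cancer cohorts.

Construction guarantees that make oracle tests exact: truth SV events
and caller-private false positives sit on a 3 Mb coordinate grid, so
nothing can cross-match under a ≤ 1 kb rule and false positives are
≥ 10 kb from any truth breakpoint; breakpoint jitter rounds to integer
bp and clamps at 1; copy-number "varying" genes receive a balanced
per-group gain/loss pattern so they can never look subtype-conserved,
making integrative gene-set recovery exact; synthetic signature
profiles concentrate 70% of their mass on six channels disjoint
between signatures, so mixtures are identifiable. Survival censoring
is exponential with rate chosen so the expected censored fraction
equals `censor_rate`.

What the generators do not emulate: probe-level microarray artifacts,
read-level sequencing noise, correlated gene-gene structure,
subclonality or contamination, non-exponential survival, and real
COSMIC signature profiles (the shipped profiles are synthetic and
labelled as such). Passing tests therefore demonstrate correctness of
the algorithms under their stated statistical assumptions, not
robustness to every artifact of real data.

## Problem sizes

The test suite and the acceptance script run the classifier stage at
n = 600 (6 classes × 100) with 3σ class separation, RFECV recovery on
8 informative + 24 noise genes at n = 150 over multiple seeds with
5-fold CV, signature recovery at 10,000 mutations over 20 seeds, batch
adjustment at 300 genes × 300 samples, and survival power at 500 per
arm — sizes chosen so every stage's statistical claim is comfortably
powered on a single CPU.

## Known limitations

Batch adjustment without covariates can attenuate biology when class
proportions are batch-confounded. The greedy SV matcher is quadratic
in calls per chromosome pair — fine for WGS SV call sets (hundreds),
not for millions of records. ssGSEA normalization couples scores
across the whole matrix, so adding samples changes normalized values.
RFECV with permutation importance is stochastic in its importance
estimates; the returned curve should be inspected rather than trusted
blindly near plateaus. The refit cutoff 0.06 means true exposures
below ~6% are systematically reported as absent.
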