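# Methods

This note documents the models behind `braindeconv`: what the synthetic
benchmark emulates, how each estimator and test is defined, the numerical
choices made where the design was open, and what the package's passing
tests do and do not establish about real tissue data.

## The synthetic benchmark

The generator emulates the "artificial mixture" design used to benchmark
deconvolution when ground-truth proportions are known: draw cells with
replacement from an annotated single-cell population, average their counts
to form a pseudo-bulk sample, and keep the realised cell fractions as
truth.

**Population** (`generate_population`). Per-gene baseline means are
log-normal (location chosen so the median mean is ~3 counts, σ = 1), i.e.
heavy-tailed positive, as empirical expression distributions are. Each of
the `markers_per_type` planted markers of type *k* has its mean multiplied
by `fold_change` (default 8) in type *k* only, so marker sets are disjoint
and the enrichment invariant holds by construction. Cell counts are
Poisson around the type means. The default population has 1576 cells —
the size of the annotated nucleus population this design is modelled on —
with a geometric frequency profile (0.40, 0.26, 0.17, 0.11, 0.07 for five
types): one dominant neuron-like class down to a rare endothelial-like
class, matching the rank order reported for cortex.

**Mixtures** (`make_pseudobulk`). Uniform resampling from a fixed pool
would give every sample nearly the same composition, which makes
correlation-based evaluation meaningless. Each sample therefore first
draws target weights from a Dirichlet with parameter
`concentration × population frequency` (concentration 10 by default, giving
a neuron-proportion SD of ~0.15 across samples), then draws
`cells_per_sample` cells (default 500) type-by-type with replacement. The
recorded truth is the realised fraction of drawn cells, whose column sums
are exactly one (to machine precision in floating point). This Dirichlet
layer is an addition relative to plain pool resampling and is recorded in
the dataset manifest.

**Read noise** (`add_nb_noise`, `estimate_dispersion`). Counts are
negative binomial with E = μ and Var = μ + φμ² (φ = 0 degenerates to
Poisson; μ = 0 always yields 0). The default φ of 0.2 is a typical bulk
RNA-seq overdispersion. The estimator is deliberately simple: per-gene
method-of-moments φ̂_g = max(0, (s²−m)/m²) over genes with mean > 1,
summarised by the median — robust to the heavy right tail of moment
estimators and accurate to a few percent at 5000 genes × 70 samples (the
median of the per-gene sampling distribution sits slightly below φ, ~3 %
at n = 70).

**Measured proportions** (`simulate_ihc`). Immunostain-based counting
measures each cell type independently, so per-sample sums only scatter
around one. Each entry is multiplied by an independent unit-mean
log-normal factor with coefficient of variation `cv` (default 0.2), and
columns are not renormalised. Multiplicative noise preserves zeros.

**Phenotypes and genotypes.** `simulate_phenotype` builds a trait as
effect × standardised proportion of one cell type, plus optional direct
per-gene terms and Gaussian noise — the structure that produces
composition-driven false associations. `simulate_genotypes` draws additive
dosages Binomial(2, MAF) and adds γ·(dosage × proportion) to planted
genes' expression.

**What the generator does not model:** ambient RNA, doublets, batch
structure, per-cell-type RNA content differences, cell-recovery biases of
nucleus isolation, and the spatial/hemispheric sampling variability that
separates a measured IHC section from the sequenced tissue. Passing tests
therefore demonstrate correctness of the algorithms and their behaviour
under controlled noise — not the accuracy attainable on post-mortem
tissue, where reported correlations are substantially lower than the
0.94–0.98 this clean benchmark yields.

## Marker selection

Differential expression is a one-vs-rest Welch t-test per gene on log2
CPM (pseudo-count 1), BH-corrected within each contrast. Markers are the
top-k genes (default 100) by log2 fold-change (difference of log2-CPM
means) among those with FDR < 0.05 and positive fold-change; ties break by
smaller FDR, then gene identifier. This replaces precision-weighted
linear-model DE (TMM + voom) with a dependency-free procedure that keeps
the selection rule's structure — an FDR gate followed by fold-change
ranking. The one-vs-rest contrast (type k vs pooled others) is a choice;
pairwise-max contrasts would be stricter for closely related types.

`remove_overlapping_markers` drops any gene present in ≥ 2 lists from all
of them (idempotent). `filter_subtype_markers` keeps a subtype marker only
if its parent-type mean exceeds `min_fold` (default 2) times the maximum
mean across the other major types — the guard needed before adding
neuronal subtype lists, which often contain genes that are in fact highest
in glia.

## Estimators

All matrix estimators operate on linear-scale expression. Input whose
maximum is below 30 is rejected as probably log-transformed; this
heuristic is deliberate rather than silent unlogging.

**DSA-style.** With fully type-specific markers, the marker-average matrix
factorises as M = diag(s) P where s_k is the expression scale of type-k
markers in pure type-k material and P is the proportion matrix. Because
P's columns sum to one, x = 1/s solves the linear system Mᵀx = 1; it is
recovered by non-negative least squares on that ones-vector system
(identical to the original constrained quadratic program on consistent
systems), and P = diag(x) M is clipped at zero and renormalised per
sample. The solve is exact on noiseless identifiable systems (verified to
1e-9 in the tests) and scale-equivariant: multiplying all libraries by a
constant leaves P unchanged.

**NNLS.** Signature regression with X the per-type mean marker profiles
from the reference; rank-deficient signatures (collinear cell types) are
rejected with the condition number. An all-zero coefficient vector falls
back to uniform proportions with a warning.

**log-mean.** p̃_kj = 2^(z_kj − o_k) with z the per-type marker mean of
log2(bulk+1) and o the same statistic on the pure reference profile,
normalised over k. This is a simplified relative of published log-scale
estimators; the quantile-based offset tuning of those methods is
deliberately omitted, which is why the method is named "logmean" rather
than claiming fidelity to any of them.

**Single-marker baseline.** Raw expression rows of one gene per type,
explicitly flagged as not being proportions — a lone gene only tracks
relative abundance and inherits that gene's full measurement noise, which
is what makes it a useful lower-bound comparator.

## Evaluation

Correlation p-values use the t approximation with n−2 df (the tests check
it against a 10⁵-draw permutation null at n = 20 to within 0.02). The
critical correlation r\* = t\*/√(n−2+t\*²) at n = 70, one-sided α = 0.05
is 0.198 — the origin of the "r > 0.2" rule for 70-sample cohorts. The
one-sided convention is used because only positive tracking of a cell
type's abundance counts as success; `sided` exposes both.

The MSE permutation test permutes the predicted row's sample labels
within each cell type (preserving the type's marginal distribution) and
uses the add-one estimator p = (1+b)/(B+1), so p is never zero and valid
under the null (KS-checked over 200 replicates). Default B = 10 000.

The PVE regression fits each gene on the proportion rows plus an
intercept. Exact-simplex tables make the intercept redundant, so the
largest-mean type is dropped as the reference category — the fitted
subspace, hence R², is unchanged. Any remaining collinearity is an error
reported with the design's condition number. Under the global null the
mean R² is K/(n−1), which the tests verify.

## Downstream analyses

**Phenotype association.** Per-gene OLS of expression on the phenotype,
optionally plus proportion covariates (reference type dropped).
"Signed p-value" is sign(coefficient) × (−log10 p). Significance is
Bonferroni at α/G per model; genes are classified both /
unadjusted_only / adjusted_only / neither. On a purely
composition-mediated phenotype the adjusted model removes essentially all
unadjusted hits (the acceptance run measures the removed fraction at 1.0).

**Interaction eQTL.** y = intercept + αg + βc + γ(g×c) by OLS; the
interaction p-value is the two-sided t-test on γ̂. The p-value is
invariant under affine rescaling of c, so proportion estimates and raw
single-gene proxies are comparable on an equal footing; the power
difference between them is driven entirely by how noisily each tracks the
true proportion. The cis window is ±1 Mb around the TSS, boundary
inclusive, 1-based positions. FDR control is global BH across all SNP ×
gene × cell-type tests at threshold 0.1. Monomorphic SNPs and
zero-variance proportions are rejected per test and skipped (with a
count) during scans. The power benchmark plants γ = 2.5 at n = 70 with
unit residual noise — a moderate interaction giving mid-range power for
the multi-gene estimate, where the ordering against the single-marker
proxy is informative.

## Numerical choices and degenerate inputs

- Zero-variance detection uses range == 0 rather than a std threshold
  (a constant float array's computed std can be a nonzero epsilon).
- Estimated proportion tables must satisfy the simplex to 1e-9; measured
  tables are only checked for non-negativity.
- Seeds are explicit everywhere; pipeline stages derive their seeds from
  one master seed by fixed offsets (`derive_seed`), all below 2³¹.
- The standard scenario uses 1500 genes, 1576 cells, 70 samples of 500
  cells — large enough that marker selection and deconvolution operate in
  their intended regime, small enough to rebuild from scratch in about a
  second.
- p-values are floored at the smallest positive float before log10.

## Known limitations

- No reference-free (unsupervised) deconvolution; all estimators need
  marker lists, and two need a reference expression matrix.
- No correction for per-cell-type RNA content; estimates are surfaced raw.
- Phenotype models are linear; binary diagnoses would need logistic
  models, which are out of scope.
- The eQTL scan takes an arbitrary pair list; pre-filtering to known
  main-effect eQTLs (common practice to reduce the testing burden) is the
  caller's choice.
- `run_pipeline` orchestrates the synthetic workflow only; on real data
  the individual CLI subcommands are composed manually because
  preprocessing (confound regression, normalisation) is study-specific.
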