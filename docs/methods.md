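# Methods

This note documents the models, estimators, numerical choices and known
limitations of `decnet`. Notation: B (probes × samples) bulk methylation
beta values in [0,1]; G (genes × samples) bulk expression on linear scale;
M (probes × k) cell-type methylation profiles; P (k × samples) cell-type
proportions with simplex columns; E, S (genes × k) cell-type expression
means and standard errors. Rows are features and columns are samples
throughout.

## Methylation deconvolution (stage 1)

Probe selection runs a two-sample t-test per probe for each reference
class against all others and ranks passing probes (p < 1e-5 by default) by
absolute mean beta difference, taking probes round-robin across classes up
to the requested count (500 by default, mirroring common practice for
450K-based reference panels). Panels with a single profile per class have
no within-class variance, so selection falls back to pure effect-size
ranking; this is logged.

The factorization minimizes ‖B − M·P‖²_F by alternating exactly
constrained least squares:

* P-step: per sample, min‖B[:,s] − M p‖ s.t. p ≥ 0, 1ᵀp = 1. Solved
  exactly by active-set enumeration over zero-sets (the problem is a tiny
  convex QP in k variables; enumeration is exact for the k ≤ 14 this
  package targets). A shared equality-constrained factorization handles
  all interior samples in one batch; only boundary samples enumerate.
* M-step: per probe, min‖B[p,:] − mᵀP‖ s.t. 0 ≤ m ≤ 1, solved by a batch
  unconstrained solve plus exact BVLS for violating probes.

Both constraint sets therefore hold exactly at return. Iteration stops
when the relative RSS decrease falls below `tol` (1e-6) or at `max_iter`
(2000); the best of `n_restarts` (10) Dirichlet(1)-initialized restarts is
returned, optionally plus one restart seeded from reference-profile
regression. RSS is non-increasing across half-steps; `debug=True` asserts
this every iteration. The factorization is identifiable only up to column
permutation: `match_cell_types` (Hungarian assignment on Pearson
correlations, or mean marker expression) must align columns before any
cross-run comparison.

The number of cell types is chosen by reproducibility: for each candidate
k, samples are bootstrap-resampled and refactorized, and the stability
score is the mean pairwise correlation of matched profile columns across
resamples; k* is the largest k whose score exceeds 0.9. The resampling
scheme and statistic are this package's own design; other reasonable
choices (e.g. data splitting) would serve equally.

## Expression deconvolution

Mixing is linear in proportions, so expression regression runs on
linear-scale values; log transforms are reserved for the network stage.
Per gene, e ≥ 0 minimizes ‖G[g,:] − e·P‖²; standard errors use the
unconstrained OLS formula S² = σ̂²·diag((P·Pᵀ)⁻¹) with σ̂² = RSS/ν and
ν = n − k. When a nonnegativity constraint is active the OLS formula is
kept and the entry is flagged — SEs for boundary estimates are then
approximate (a known caveat of this estimator family). Cell types with
zero proportion everywhere are dropped from the fit and reported absent.

## Iterative group fit

Given P and a gene of interest g*, samples are split at random into two
groups (balanced halves); within each group expression of g* is
deconvoluted; each sample s is assigned to the group j minimizing
d_j(s) = |Σ_c P[c,s]·E_j[g*,c] − G[g*,s]|; deconvolution and reassignment
alternate until no sample moves (or `max_iter`). The distance is scalar on
the gene of interest by default — the quantity the grouping is defined
around; a multi-gene Euclidean distance is available via
`distance_genes`. Exact ties keep the current assignment, which prevents
two-cycle oscillation. A group shrinking to ≤ k samples (making the
within-group regression rank-deficient) triggers a restart from a fresh
random split, at most 10 times.

Consensus runs the fit an odd number of times (3 by default), aligns each
run's groups as high/low by estimated cancer-cell expression of g* (the
designated cancer cell type, else the cell type with maximal estimated
expression, logged), and takes the per-sample majority. Recursive
partitioning re-splits the low group, yielding depth+1 groups ordered by
cancer-cell gene level; the natural comparison pair is the first vs the
last group. Ranking comparisons split samples into three equal thirds
(remainder to the middle bin; boundary ties resolve by sample ID) and
report shared/exclusive counts for the top and bottom bins.

## Differential expression from deconvoluted profiles

Per gene and cell type, t = (m_hi − m_lo)/√(s_hi² + s_lo²) with
Welch–Satterthwaite degrees of freedom built from the two groups' residual
dofs (configurable to ν_hi + ν_lo). Zero-SE pairs with equal means give
t = 0, p = 1; with unequal means the p-value is a 0 sentinel and the row is
flagged degenerate. Genes with a zero mean in one group get a half-minimum
pseudo-value for the fold change and are flagged, so the FC filter stays
applicable. BH adjustment is the standard step-up procedure
(statsmodels); calls require q < 0.05 and |log2 FC| ≥ 1 by default.
Set-overlap enrichment is the upper-tail hypergeometric probability
P(X ≥ x) with N = |universe|, K = |target|, n = |query|.

## Network stage

Variables are log2(expression + 1) for the gene subset plus the raw
proportion rows of P as covariate-flagged nodes (pseudocount 1 chosen for
the usual reason: zeros must map to finite values; results are insensitive
for the expression scales simulated here). All k rows are included by
default — the lasso penalty tolerates the simplex collinearity — with an
option to drop one cell type. The graphical lasso runs on the correlation
matrix at penalty λ; if exact collinearity makes the solver fail, the
correlation matrix is shrunk toward the identity by the smallest of
(1e-3, 1e-2, 0.1) that converges, with a warning. Edges are the
off-diagonal support of Θ (|Θᵢⱼ| > 1e-10); weights are signed partial
correlations. Covariate stripping removes covariate rows/columns of Θ, ρ
and the adjacency without refitting, so gene–gene entries are bit
identical before and after.

StARS selects λ by refitting on 20 random subsamples of size ⌊10√n⌋ per
penalty; per-edge selection frequencies f give instability 2f(1−f),
averaged over pairs and monotonized along the path; the selected λ is the
smallest penalty whose monotonized instability stays ≤ 0.05 (the densest
graph that is still stable). A fixed λ (0.125 is the package default for
the pipeline) bypasses selection.

Strong edges exceed µ_w + σ_w, where µ_w and σ_w are the mean and sample
SD of the signed weights of *existing* (nonzero) edges — zero entries of a
lasso-trimmed precision matrix are non-edges, not zero-weight edges. The
connectedness statistic for a node subset is its induced edge count,
referenced to n_perm uniform random subsets of equal size,
p = (1 + #{null ≥ obs})/(n_perm + 1). This is a deliberately simple,
reproducible module statistic; it is not an implementation of
information-theoretic module scoring methods and does not reproduce their
p-values.

## Simulator

`generate_reference_panel` builds k separable methylation archetypes: each
class owns ⌊n_probes/(2k)⌋ probes at beta ≈ 0.9 (±0.03 jitter) against
≈ 0.1 elsewhere; remaining probes share a Beta(2,2) background. Expression
profiles are lognormal; the gene of interest is expressed only in cancer
cells, at 10 (low variant) vs 10×`variant_fold` (high variant); the two
variants share the cancer methylation archetype. `simulate_mixtures` draws
per-sample proportions from Dirichlet(α), α = (1,…,1) by default (uniform
on the simplex), applies mean-preserving Beta noise per probe and sample
(mean = reference beta, concentration s = 100 by default; s is a
precision, larger is quieter), and mixes expression with the *same*
proportion vector per sample (noiseless by default; optional Poisson
resampling). The default study design used in validation is the
4-reference panel with 2 cancer variants × 50 mixtures each.

The simulator emulates: distinct methylation archetypes, purity-confounded
bulk expression, matched multi-omic mixing, bounded beta noise. It does
not emulate: read-level RNA-seq sampling, probe-level technical artifacts
(cross-reactivity, SNPs — these are consumed as external blocklists),
within-class biological heterogeneity of real reference profiles, or
archetypes with realistic correlated CpG structure. Passing recovery tests
here therefore demonstrates correctness of the estimators under the stated
generative model, not performance on real 450K/RNA-seq data.

The purity-confounding scenario (`simulate_purity_confounding`) uses three
cell types with Dirichlet(2,2,1) proportions and two genes expressed each
in a different cell type with 10% multiplicative noise; at λ = 0.2 the
spurious bulk-level edge appears essentially always without covariate
nodes and is suppressed with them. The conditioning is linear while the
log transform of a linear mixture is mildly nonlinear, so very low gene
noise combined with extreme purity ranges can leave a small residual
partial correlation — an inherent limitation of linear covariate
adjustment, which the chosen scenario sizes keep below the penalty.

## Validation studies and problem sizes

The benchmark suite (`decnet.benchmarks`, run by `scripts/acceptance.py`
and the acceptance tests) uses: noiseless k=3 recovery at 120 probes × 40
samples; the 4-reference noisy study at 100 mixtures with s = 100;
grouping accuracy over 100 mixtures with 3-run consensus plus 20 repeated
splits scored by pairwise adjusted Rand index; differential testing with
40 planted 2.5-fold cancer-cell changes among 200 genes (30 samples per
group, 10% multiplicative noise) and a 1000-gene null arm with per-gene
constant noise (the variance model the per-gene regression assumes, so the
null arm calibrates the t machinery itself); chain-graph recovery at
p = 30, n = 500 with a 10-point StARS path; confounding suppression over
10 seeds; connectedness calibration on Erdős–Rényi graphs (planted
5-clique, and 100 random 21-node query sets tested for p-value uniformity
— query sets of this size give the permutation statistic a support wide
enough for a meaningful Kolmogorov–Smirnov comparison).

## Known limitations

* SEs under active nonnegativity constraints are approximate (flagged).
* Stage-1 restarts make the factorization stochastic; the consensus and
  matching layers, not the raw factorization, are the stable interface.
* The stability statistic for choosing k and the connectedness statistic
  are package-defined stand-ins for method-specific criteria used in
  applied work; they are documented, simple, and reproducible, but not
  interchangeable with those methods' outputs.
* Multiplicative measurement noise mildly inflates the nominal type-I
  error of the per-gene t-tests (the regression assumes constant per-gene
  variance); with 10% noise the inflation is ≤ ~2 percentage points at
  α = 0.05.
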