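# decnet

Cell-type deconvolution of bulk tumor profiles and composition-aware gene
network inference.

## The problem

Bulk tumor molecular profiles mix signals from cancer, stromal, immune and
other cell types in sample-specific proportions. For a gene of interest
(e.g. *MSLN* in pancreatic ductal adenocarcinoma), a high bulk expression
value is ambiguous: cancer cells may express more of the gene, or the tumor
may simply be purer. This confounds both differential expression between
tumor groups and co-expression network inference.

`decnet` addresses this in two stages:

**Stage 1 — deconvolution and gene-centered grouping.** Bulk DNA
methylation B (probes × samples, beta values) is factored as B ≈ M·P by
alternating constrained least squares, with M ∈ [0,1] (cell-type
methylation profiles) and the columns of P on the probability simplex
(cell-type proportions per sample). Informative probes are chosen from a
labeled reference panel by one-vs-rest t-tests. With P fixed, bulk
expression is regressed per gene, e ≥ 0 in min‖G[g,·] − e·P‖², giving
cell-type expression means E and OLS standard errors S. The *iterative
group fit* then partitions samples by cancer-cell-intrinsic expression of a
gene of interest: split samples at random, deconvolute expression within
each group, reassign every sample to the group whose profiles — mixed by
the sample's own composition — better predict its observed bulk value of
the gene, and repeat until labels stabilize; several runs are combined by
majority vote after aligning groups as high/low by estimated cancer-cell
expression. Groups are compared per cell type with t-tests built from
(E, S), Benjamini–Hochberg correction, and a fold-change filter.

**Stage 2 — composition-aware network.** A Gaussian graphical model is
estimated by the graphical lasso over log2-transformed expression of the
differential genes, with the cell-proportion rows of P included as
covariate-flagged nodes so composition-driven dependencies attach to the
covariates instead of appearing as spurious gene–gene edges; the covariate
nodes are then stripped (no refit). Edge weights are signed regularized
partial correlations ρᵢⱼ = −Θᵢⱼ/√(ΘᵢᵢΘⱼⱼ). The penalty may be fixed or
selected by stability (StARS). Module statistics: strong edges (weight >
µ_w + σ_w over existing edges), a permutation edge-count connectedness test
for node subsets, and hypergeometric enrichment of a node's neighbors in a
target gene set.

A mixture simulator with full ground truth (shared Dirichlet proportions
between matched methylation and expression mixtures, mean-preserving Beta
noise on beta values, two cancer variants differing in one gene) backs all
validation.

## Worked example

```bash
python examples/02_gene_centered_grouping.py
```

```
gene of interest: gene_0000
iterations per run: [5, 4, 5], converged: [True, True, True]
cancer-cell expression by group: {'high': 100.00000000000003, 'low': 10.0}
consensus accuracy vs simulated variants: 100.00%
```

100 simulated mixtures carry a cancer-cell gene level of 100 (50 samples)
or 10 (50 samples), hidden behind random purity. Each of the three runs
converges within a few iterations; the estimated cancer-cell expression per
group recovers the simulated 10-fold difference, and every sample lands in
its true variant group. `examples/` contains one script per capability
(deconvolution, grouping, differential testing, network confounding, full
pipeline); `decnet --help` lists the equivalent shell subcommands.

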