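"""Group tumors by cancer-cell-intrinsic expression of a gene of interest.

Bulk expression confounds intrinsic expression with tumor purity; the
iterative group fit separates samples by what cancer cells themselves
express.  Ground truth from the simulator scores the result.
"""

from decnet import consensus_grouping, generate_reference_panel, simulate_mixtures

panel = generate_reference_panel(k=4, n_probes=400, n_genes=60, variant_fold=10, seed=1)
_, expr, truth = simulate_mixtures(panel, n_per_variant=50, noise_precision=100, seed=2)

res = consensus_grouping(
    expr, truth.P_true, gene=panel.variant_gene,
    n_runs=3, seed=5, cancer_cell_type="cancer",
)
acc = (
    (truth.assigned_variant == "cancer_hi") == (res.consensus_labels == "high")
).mean()
print(f"gene of interest: {panel.variant_gene}")
print(f"iterations per run: {res.n_iterations_per_run}, converged: {res.converged}")
print(f"cancer-cell expression by group: {res.group_gene_levels}")
print(f"consensus accuracy vs simulated variants: {acc:.2%}")
print("the high/low levels recover the simulated 10-fold difference; accuracy is the")
print("fraction of samples assigned to their true expression variant")
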