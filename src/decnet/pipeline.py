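"""End-to-end orchestration of the two-stage analysis.

Stage 1: probe filtering, informative-probe selection, methylation
deconvolution into cell-type profiles and proportions, cell-type labeling,
and gene-centered iterative grouping of samples into high/low groups by
cancer-cell-intrinsic expression of the gene of interest, followed by
per-group expression deconvolution and cell-type-specific differential
expression.  Stage 2: a graphical-lasso GGM over the differentially
expressed genes with cell-proportion covariate nodes, covariate stripping,
strong-edge calling, the gene's neighbor subgraph, and connectedness of the
DE gene sets.

Inputs come either from TSV files or from the built-in mixture simulator
(exactly one of the two).  Every run is reproducible from (config, seed);
artifacts are stamped with a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .differential import call_de, celltype_t_test
from .expression import CellTypeExpression, deconvolve_expression
from .grouping import HIGH, LOW, GroupingResult, consensus_grouping, recursive_partition
from .methylation import (
    choose_num_celltypes,
    deconvolve_methylation,
    match_cell_types,
    select_informative_probes,
)
from .network import (
    GGMNetwork,
    ConnectednessResult,
    connectedness_test,
    edge_enrichment,
    export_network,
    fit_ggm,
    neighbor_subgraph,
    stars_select,
    strip_covariate_nodes,
    strong_edges,
)
from .preprocess import filter_probes, filter_probes_by_covariates, load_blocklist

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for :func:`run_pipeline`.

    Exactly one of ``simulate`` (simulator parameters) or ``inputs`` (file
    paths) must be provided.
    """

    seed: int = 0
    outdir: str = "decnet_out"
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None
    gene: str | None = None
    k: int | None = None
    k_range: list[int] | None = None
    n_informative_probes: int = 500
    n_restarts: int = 10
    grouping: dict[str, Any] = field(default_factory=dict)
    de: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'simulate' or 'inputs'")
        if self.k is None and self.k_range is None:
            raise ValueError("provide k or k_range")
        fc = self.de.get("fold_change", 2.0)
        q = self.de.get("q_threshold", 0.05)
        if fc < 1 or not (0 < q < 1):
            raise ValueError("invalid differential-expression thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run (also persisted under ``outdir``)."""

    config_hash: str
    proportions: pd.DataFrame
    cell_type_assignment: dict[str, str] | None
    grouping: GroupingResult
    groups: list[list[str]]
    expr_by_group: dict[str, CellTypeExpression]
    de_tables: dict[str, pd.DataFrame]
    de_genes: dict[str, dict[str, list[str]]]
    network: GGMNetwork
    network_full: GGMNetwork
    strong_edges: pd.DataFrame
    neighbor_net: GGMNetwork
    connectedness: dict[str, ConnectednessResult]
    selected_lambda: float
    report: dict[str, Any]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    for key in ("methylation", "expression", "reference_meth"):
        if key not in paths:
            raise ValueError(f"inputs must define {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"input stage: missing file {paths[key]}")
    meth = sim.read_matrix_tsv(paths["methylation"])
    expr = sim.read_matrix_tsv(paths["expression"])
    refs = sim.read_matrix_tsv(paths["reference_meth"])
    labels = paths.get("reference_labels") or list(refs.columns)
    blocklists = [load_blocklist(p) for p in paths.get("blocklists", [])]
    covariates = (
        sim.read_matrix_tsv(paths["covariates"]) if paths.get("covariates") else None
    )
    chromosomes = None
    if paths.get("probe_chromosomes"):
        chromosomes = pd.read_csv(
            paths["probe_chromosomes"], sep="\t", index_col=0
        ).iloc[:, 0]
    return meth, expr, refs, labels, blocklists, covariates, chromosomes, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run both stages end to end and persist all artifacts.

    See the module docstring for the stage sequence.  Raises with the stage
    name on failure; artifacts produced before the failure remain on disk.
    """
    cfg_hash = config.hash()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict[str, Any] = {"config_hash": cfg_hash, "seed": config.seed}

    # ------------------------------------------------------------ inputs
    truth = None
    if config.simulate is not None:
        p = dict(config.simulate)
        n_per_variant = p.pop("n_per_variant", 50)
        noise = p.pop("noise_precision", 100.0)
        alpha = p.pop("alpha", None)
        panel = sim.generate_reference_panel(seed=int(rng.integers(2**31 - 1)), **p)
        meth, expr, truth = sim.simulate_mixtures(
            panel,
            n_per_variant=n_per_variant,
            alpha=alpha,
            noise_precision=noise,
            seed=int(rng.integers(2**31 - 1)),
        )
        refs = panel.meth_profiles
        ref_labels = list(panel.class_labels)
        blocklists, covariates, chromosomes = [], None, None
        gene = config.gene or panel.variant_gene
        sim.write_truth(truth, outdir / "truth")
    else:
        meth, expr, refs, ref_labels, blocklists, covariates, chromosomes, _ = (
            _load_inputs(config)
        )
        gene = config.gene
        if gene is None:
            raise ValueError("config.gene is required with file inputs")

    # -------------------------------------------------------- preprocess
    meth_f, flog = filter_probes(
        meth,
        blocklists=blocklists,
        drop_missing=True,
        drop_sex_chromosomes=chromosomes is not None,
        chromosomes=chromosomes,
    )
    if covariates is not None:
        meth_f, clog = filter_probes_by_covariates(meth_f, covariates)
        report["covariate_filtered"] = clog.n_covariate_associated
    report["probes_after_filtering"] = meth_f.shape[0]

    # --------------------------------------- probe selection + stage 1
    probes = select_informative_probes(
        refs, ref_labels, n_probes=config.n_informative_probes
    )
    probes = [p for p in probes if p in meth_f.index]
    report["informative_probes"] = len(probes)
    B = meth_f.loc[probes]

    if config.k is not None:
        k = config.k
    else:
        k, stability = choose_num_celltypes(
            B, config.k_range, seed=int(rng.integers(2**31 - 1))
        )
        report["stability_scores"] = {int(kk): v for kk, v in stability.items()}
    report["k"] = k

    decon = deconvolve_methylation(
        B, k, n_restarts=config.n_restarts, seed=int(rng.integers(2**31 - 1))
    )
    report["stage1_rss"] = decon.rss

    # ------------------------------------------------- cell-type labels
    cancer_label = None
    class_refs = refs.T.groupby(ref_labels).mean().T  # class-mean reference profiles
    match = match_cell_types(decon.M, class_refs)
    assignment = match.assignment
    P = decon.P.rename(index=assignment)
    if sim.CANCER in P.index:
        cancer_label = sim.CANCER
    _write_tsv(P.T, outdir / "proportions.tsv", cfg_hash, "sample")

    # ---------------------------------------------- gene-centered stage
    g_opts = dict(config.grouping)
    depth = g_opts.get("depth", 1)
    n_runs = g_opts.get("n_runs", 3)
    grouping = consensus_grouping(
        expr, P, gene, n_runs=n_runs,
        seed=int(rng.integers(2**31 - 1)), cancer_cell_type=cancer_label,
    )
    if depth > 1:
        groups = recursive_partition(
            expr, P, gene, depth=depth, n_runs=n_runs,
            seed=int(rng.integers(2**31 - 1)), cancer_cell_type=cancer_label,
        )
    else:
        cl = grouping.consensus_labels
        groups = [cl.index[cl == HIGH].tolist(), cl.index[cl == LOW].tolist()]
    _write_tsv(
        pd.DataFrame(
            {
                "consensus": grouping.consensus_labels,
                "agreement": grouping.agreement,
            }
        ),
        outdir / "grouping.tsv",
        cfg_hash,
        "sample",
    )
    report["grouping_iterations"] = grouping.n_iterations_per_run
    report["n_groups"] = len(groups)

    # --------------------------- per-group expression deconvolution + DE
    hi_samples, lo_samples = groups[0], groups[-1]
    expr_by_group = {
        HIGH: deconvolve_expression(expr[hi_samples], P[hi_samples]),
        LOW: deconvolve_expression(expr[lo_samples], P[lo_samples]),
    }
    fc = config.de.get("fold_change", 2.0)
    qthr = config.de.get("q_threshold", 0.05)
    de_tables: dict[str, pd.DataFrame] = {}
    de_genes: dict[str, dict[str, list[str]]] = {}
    for ct in P.index:
        table = celltype_t_test(expr_by_group[HIGH], expr_by_group[LOW], ct)
        up, down = call_de(table, fold_change=fc, q_threshold=qthr)
        de_tables[ct] = table
        de_genes[ct] = {"up": up, "down": down}
        _write_tsv(table, outdir / f"de_{ct}.tsv", cfg_hash, "gene")
    report["de_counts"] = {
        ct: {d: len(v) for d, v in dd.items()} for ct, dd in de_genes.items()
    }

    # ------------------------------------------------- stage 2: network
    all_de = sorted({g for dd in de_genes.values() for v in dd.values() for g in v})
    subset = sorted(set(all_de) | {gene})
    if len(subset) < 2:  # fall back to most variable genes so stage 2 can run
        var = expr.var(axis=1).sort_values(ascending=False)
        subset = sorted(set(var.index[: min(30, len(var))]) | {gene})
        logger.info("too few DE genes for a network; using top variable genes")
    n_opts = dict(config.network)
    lam = n_opts.get("lam")
    lambda_path = n_opts.get("lambda_path")
    if lambda_path:
        from .network import _variables_from_inputs

        X, names, _ = _variables_from_inputs(
            expr, subset, P, n_opts.get("pseudocount", 1.0), True, False
        )
        data = pd.DataFrame(X, index=names, columns=expr.columns)
        data = data[data.std(axis=1) > 0] if (data.std(axis=1) == 0).any() else data
        lam, instab = stars_select(
            data,
            lambda_path,
            n_subsamples=n_opts.get("n_subsamples", 20),
            instability_threshold=n_opts.get("instability_threshold", 0.05),
            seed=int(rng.integers(2**31 - 1)),
        )
        report["stars_instability"] = {float(k_): v for k_, v in instab.items()}
    elif lam is None:
        lam = 0.125  # stability-selected penalty carried as the package default
    report["lambda"] = float(lam)

    net_full = fit_ggm(
        expr, subset, P, lam=lam, pseudocount=n_opts.get("pseudocount", 1.0)
    )
    net = strip_covariate_nodes(net_full)
    strong = strong_edges(net)
    export_network(net, outdir, prefix="network")
    report["network_nodes"] = net.n_nodes
    report["network_edges"] = net.n_edges
    report["strong_edges"] = len(strong)

    neighbor = neighbor_subgraph(net, gene, order=1)
    report["gene_neighbors"] = neighbor.n_nodes - 1

    connectedness: dict[str, ConnectednessResult] = {}
    for ct, dd in de_genes.items():
        genes_ct = [g for g in dd["up"] + dd["down"] if g in net.node_names]
        if len(genes_ct) >= 2:
            connectedness[ct] = connectedness_test(
                net, genes_ct, n_perm=n_opts.get("n_perm", 10_000),
                seed=int(rng.integers(2**31 - 1)),
            )
    report["connectedness_p"] = {ct: r.p for ct, r in connectedness.items()}

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return PipelineResult(
        config_hash=cfg_hash,
        proportions=P,
        cell_type_assignment=assignment,
        grouping=grouping,
        groups=groups,
        expr_by_group=expr_by_group,
        de_tables=de_tables,
        de_genes=de_genes,
        network=net,
        network_full=net_full,
        strong_edges=strong,
        neighbor_net=neighbor,
        connectedness=connectedness,
        selected_lambda=float(lam),
        report=report,
    )
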