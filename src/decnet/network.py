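"""Sparse Gaussian graphical models over deconvolution-aware expression data.

A GGM is fit by the graphical lasso on the correlation matrix of
log2-transformed expression for a gene subset, with the per-sample cell-type
proportions included as covariate-flagged nodes so that edges induced purely
by composition (tumor purity) are absorbed by the covariates rather than
appearing as spurious gene-gene partial correlations.  After fitting, the
covariate nodes are stripped (no refit).  Edge weights are signed
regularized partial correlations rho_ij = -Theta_ij / sqrt(Theta_ii
Theta_jj).  The penalty can be fixed or selected by stability (StARS);
module-level statistics are a permutation edge-count connectedness test and
hypergeometric edge enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from .differential import EnrichmentResult, hypergeom_overlap

_EDGE_TOL = 1e-10


@dataclass
class GGMNetwork:
    """A fitted Gaussian graphical model.

    ``theta`` is the penalized precision matrix, ``pcor`` the partial
    correlations derived from it, ``adjacency`` the boolean edge support
    (off-diagonal nonzeros of theta).  ``covariate_mask`` flags
    cell-proportion nodes.
    """

    node_names: list[str]
    covariate_mask: np.ndarray  # bool per node
    lam: float
    theta: np.ndarray
    pcor: np.ndarray
    adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def node_index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"node {name!r} not in network") from None

    def edge_weights(self) -> np.ndarray:
        """Signed weights (partial correlations) of existing edges, each once."""
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu]
        return self.pcor[iu][mask]

    def edge_weight_stats(self) -> tuple[float, float]:
        """(mu, sigma) over signed weights of existing edges."""
        w = self.edge_weights()
        if w.size == 0:
            return np.nan, np.nan
        return float(w.mean()), float(w.std(ddof=1)) if w.size > 1 else 0.0

    def edge_list(self) -> pd.DataFrame:
        """All edges as (node_a, node_b, weight), upper triangle once."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju]
        return pd.DataFrame(
            {
                "node_a": [self.node_names[i] for i in iu[mask]],
                "node_b": [self.node_names[j] for j in ju[mask]],
                "weight": self.pcor[iu, ju][mask],
            }
        )

    def subset(self, indices: Sequence[int]) -> "GGMNetwork":
        idx = np.asarray(indices)
        return GGMNetwork(
            node_names=[self.node_names[i] for i in idx],
            covariate_mask=self.covariate_mask[idx],
            lam=self.lam,
            theta=self.theta[np.ix_(idx, idx)],
            pcor=self.pcor[np.ix_(idx, idx)],
            adjacency=self.adjacency[np.ix_(idx, idx)],
        )


@dataclass
class ConnectednessResult:
    """Permutation test of how densely a node subset is wired internally."""

    node_set: list[str]
    observed: int
    n_perm: int
    p: float
    null_mean: float


def partial_correlations(theta: np.ndarray) -> np.ndarray:
    """rho_ij = -theta_ij / sqrt(theta_ii * theta_jj), with unit diagonal."""
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def _variables_from_inputs(
    G: pd.DataFrame,
    gene_subset: Sequence[str],
    P: pd.DataFrame | None,
    pseudocount: float,
    include_covariates: bool,
    drop_one_celltype: bool,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise ValueError("gene_subset must be nonempty")
    missing = [g for g in gene_subset if g not in G.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    X = np.log2(G.loc[gene_subset].to_numpy(dtype=float) + pseudocount)
    names = list(gene_subset)
    cov_mask = np.zeros(len(names), dtype=bool)
    if P is not None and include_covariates:
        Puse = P.iloc[:-1] if drop_one_celltype and P.shape[0] > 1 else P
        X = np.vstack([X, Puse.to_numpy(dtype=float)])
        names += [str(c) for c in Puse.index]
        cov_mask = np.concatenate([cov_mask, np.ones(Puse.shape[0], dtype=bool)])
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in network input variables")
    return X, names, cov_mask


def fit_ggm_data(
    data: pd.DataFrame,
    lam: float,
    covariate_names: Sequence[str] = (),
) -> GGMNetwork:
    """Graphical lasso on an already-transformed variables x samples matrix.

    Standardization happens internally (the lasso runs on the correlation
    matrix); rows named in ``covariate_names`` are flagged as covariate
    nodes.  :func:`fit_ggm` wraps this with the log2 expression transform.
    """
    if lam <= 0:
        raise ValueError("penalty lam must be positive")
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in network input variables")
    names = [str(n) for n in data.index]
    cov_mask = np.array([n in set(covariate_names) for n in names])
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping zero-variance variables: {[n for n, k in zip(names, keep) if not k]}"
        )
        X = X[keep]
        names = [n for n, k in zip(names, keep) if k]
        cov_mask = cov_mask[keep]
    corr = np.corrcoef(X)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    theta = _glasso_with_shrinkage(corr, lam)
    adjacency = np.abs(theta) > _EDGE_TOL
    np.fill_diagonal(adjacency, False)
    return GGMNetwork(
        node_names=names,
        covariate_mask=cov_mask,
        lam=float(lam),
        theta=theta,
        pcor=partial_correlations(theta),
        adjacency=adjacency,
    )


def _glasso_with_shrinkage(corr: np.ndarray, lam: float) -> np.ndarray:
    """Graphical lasso with a shrinkage fallback for singular correlation input.

    Exactly collinear variables (e.g. proportion rows summing to one) can
    make the solver fail; the correlation matrix is then shrunk toward the
    identity by the smallest amount that lets it converge.
    """
    p = corr.shape[0]
    for eps in (0.0, 1e-3, 1e-2, 0.1):
        c = (1.0 - eps) * corr + eps * np.eye(p)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, theta = graphical_lasso(c, alpha=lam, max_iter=500)
        except FloatingPointError:
            continue
        if eps > 0:
            warnings.warn(
                f"correlation matrix shrunk by {eps} toward identity for a "
                "solvable graphical lasso (collinear variables present)"
            )
        return (theta + theta.T) / 2.0
    raise FloatingPointError("graphical lasso failed even after shrinkage")


def fit_ggm(
    G: pd.DataFrame,
    gene_subset: Sequence[str],
    P: pd.DataFrame | None = None,
    lam: float = 0.125,
    pseudocount: float = 1.0,
    include_covariates: bool = True,
    drop_one_celltype: bool = False,
) -> GGMNetwork:
    """Graphical-lasso GGM over log2 expression plus proportion covariate nodes.

    Variables are log2(expression + ``pseudocount``) for ``gene_subset``
    rows of ``G`` (genes x samples), plus the rows of ``P`` as
    covariate-flagged nodes.  All variables are standardized and the lasso
    runs on their correlation matrix at penalty ``lam``.  Zero-variance
    variables are dropped with a warning.
    """
    if G.shape[1] <= 2:
        raise ValueError("need more than 2 samples")
    X, names, cov_mask = _variables_from_inputs(
        G, gene_subset, P, pseudocount, include_covariates, drop_one_celltype
    )
    data = pd.DataFrame(X, index=names, columns=G.columns)
    return fit_ggm_data(
        data, lam, covariate_names=[n for n, c in zip(names, cov_mask) if c]
    )


def stars_select(
    data: pd.DataFrame,
    lambda_path: Sequence[float],
    n_subsamples: int = 20,
    instability_threshold: float = 0.05,
    seed: int | None = None,
) -> tuple[float, pd.Series]:
    """Penalty selection by the Stability Approach to Regularization Selection.

    ``data`` is variables x samples (already on the scale the final fit
    will use).  For each penalty, the graph is refit on ``n_subsamples``
    random subsamples of size floor(10 * sqrt(n)); per-edge selection
    frequencies f give edge instability 2 f (1 - f), averaged over pairs.
    The selected penalty is the smallest one whose monotonized instability
    stays within ``instability_threshold`` (the densest graph that is still
    stable); if none qualifies the largest penalty is returned with a
    warning.  Returns (lambda, per-penalty instability).
    """
    path = sorted(set(float(l) for l in lambda_path), reverse=True)
    if not path or path[-1] <= 0:
        raise ValueError("lambda_path must contain positive penalties")
    X = data.to_numpy(dtype=float)
    p, n = X.shape
    if n < 20:
        raise ValueError("StARS needs at least 20 samples")
    b = min(int(np.floor(10.0 * np.sqrt(n))), n - 1)
    rng = np.random.default_rng(seed)
    subsamples = [rng.choice(n, size=b, replace=False) for _ in range(n_subsamples)]

    iu = np.triu_indices(p, k=1)
    instab = {}
    for lam in path:
        freq = np.zeros(len(iu[0]))
        for cols in subsamples:
            corr = np.corrcoef(X[:, cols])
            corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
            np.fill_diagonal(corr, 1.0)
            theta = _glasso_with_shrinkage(corr, lam)
            freq += (np.abs(theta[iu]) > _EDGE_TOL).astype(float)
        f = freq / n_subsamples
        instab[lam] = float(np.mean(2.0 * f * (1.0 - f)))

    selected = None
    running_max = 0.0
    for lam in path:  # decreasing penalty = densifying graph
        running_max = max(running_max, instab[lam])
        if running_max <= instability_threshold:
            selected = lam
    if selected is None:
        warnings.warn(
            "no penalty met the instability threshold; returning the largest"
        )
        selected = path[0]
    return selected, pd.Series(instab, name="instability")


def strip_covariate_nodes(net: GGMNetwork) -> GGMNetwork:
    """Remove covariate nodes and their edges; gene-gene entries kept as-is (no refit)."""
    if not net.covariate_mask.any():
        warnings.warn("network has no covariate nodes; returning it unchanged")
        return replace(net)
    return net.subset(np.nonzero(~net.covariate_mask)[0])


def strong_edges(net: GGMNetwork, n_sd: float = 1.0) -> pd.DataFrame:
    """Edges whose signed weight exceeds the mean edge weight by ``n_sd`` SDs."""
    edges = net.edge_list()
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges; no strong-edge statistics possible")
        return edges.iloc[0:0]
    mu, sigma = net.edge_weight_stats()
    return edges[edges["weight"] > mu + n_sd * sigma].reset_index(drop=True)


def connectedness_test(
    net: GGMNetwork,
    node_set: Sequence[str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> ConnectednessResult:
    """Permutation test of the edge count induced by a node subset.

    The observed statistic is the number of edges among ``node_set``; the
    null resamples ``n_perm`` uniform node subsets of equal size from the
    whole network.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    node_set = list(dict.fromkeys(node_set))
    m = len(node_set)
    if m < 2:
        raise ValueError("node_set needs at least 2 nodes")
    if m > net.n_nodes:
        raise ValueError("node_set larger than the network")
    idx = np.array([net.node_index(s) for s in node_set])
    A = net.adjacency.astype(np.int8)
    observed = int(A[np.ix_(idx, idx)].sum()) // 2

    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, net.n_nodes))
    picks = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = np.empty(n_perm, dtype=np.int64)
    batch = max(1, 2_000_000 // (m * m))
    for start in range(0, n_perm, batch):
        sel = picks[start : start + batch]
        sub = A[sel[:, :, None], sel[:, None, :]]
        null[start : start + len(sel)] = sub.sum(axis=(1, 2)) // 2
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return ConnectednessResult(
        node_set=node_set,
        observed=observed,
        n_perm=n_perm,
        p=float(p),
        null_mean=float(null.mean()),
    )


def edge_enrichment(
    net: GGMNetwork, node: str, target_set: Sequence[str]
) -> EnrichmentResult:
    """Hypergeometric enrichment of a node's neighbors within a target gene set."""
    i = net.node_index(node)
    others = [n for n in net.node_names if n != node]
    target = [t for t in dict.fromkeys(target_set) if t != node]
    missing = set(target) - set(others)
    if missing:
        raise ValueError(f"target genes absent from network: {sorted(missing)[:5]}")
    neighbors = [net.node_names[j] for j in np.nonzero(net.adjacency[i])[0]]
    return hypergeom_overlap(neighbors, target, others)


def to_networkx(net: GGMNetwork) -> nx.Graph:
    g = nx.Graph()
    for name, cov in zip(net.node_names, net.covariate_mask):
        g.add_node(name, covariate=bool(cov))
    for _, row in net.edge_list().iterrows():
        g.add_edge(row["node_a"], row["node_b"], weight=float(row["weight"]))
    return g


def neighbor_subgraph(net: GGMNetwork, node: str, order: int = 1) -> GGMNetwork:
    """Induced subnetwork on a node and everything within graph distance ``order``."""
    net.node_index(node)  # existence check
    if order < 0:
        raise ValueError("order must be >= 0")
    g = to_networkx(net)
    dist = nx.single_source_shortest_path_length(g, node, cutoff=order)
    keep = [i for i, n in enumerate(net.node_names) if n in dist]
    return net.subset(keep)


def export_network(net: GGMNetwork, directory: str | Path, prefix: str = "network") -> None:
    """Write a weighted edge list (with strong-edge flags) and a node table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edges = net.edge_list()
    if len(edges) >= 2:
        mu, sigma = net.edge_weight_stats()
        edges["strong"] = edges["weight"] > mu + sigma
    else:
        edges["strong"] = False
    edges.to_csv(directory / f"{prefix}_edges.tsv", sep="\t", index=False)
    nodes = pd.DataFrame(
        {"node": net.node_names, "covariate": net.covariate_mask}
    )
    nodes.to_csv(directory / f"{prefix}_nodes.tsv", sep="\t", index=False)
    nx.write_graphml(to_networkx(net), directory / f"{prefix}.graphml")
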