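"""Iterative partitioning of samples by cancer-cell-intrinsic gene expression.

Bulk expression of a gene of interest confounds intrinsic expression with
tumor purity: a high bulk value can reflect high expression inside cancer
cells or simply a purer tumor.  The iterative group fit disentangles the
two.  Samples are split at random into two groups; cell-type expression is
deconvoluted within each group against the fixed proportion matrix; each
sample is then reassigned to the group whose deconvoluted profiles, mixed
by the sample's own composition, best predict its observed bulk value of
the gene; deconvolution and reassignment alternate until labels are stable.
Several independent runs are combined by majority vote after aligning
groups by estimated cancer-cell expression of the gene (high vs low).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CellTypeExpression, deconvolve_expression

logger = logging.getLogger(__name__)

HIGH, LOW = "high", "low"


@dataclass
class GroupingResult:
    """Consensus sample grouping around a gene of interest."""

    gene: str
    labels_per_run: pd.DataFrame  # samples x runs, values 'high'/'low'
    consensus_labels: pd.Series  # sample -> 'high'/'low'
    agreement: pd.Series  # sample -> fraction of runs agreeing with consensus
    n_iterations_per_run: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    group_gene_levels: dict[str, float] = field(default_factory=dict)
    cancer_cell_type: str | None = None


def _check_gene(G: pd.DataFrame, gene: str) -> None:
    if gene not in G.index:
        raise ValueError(f"gene {gene!r} not present in the expression matrix")


def _group_predictions(
    G: pd.DataFrame,
    P: pd.DataFrame,
    labels: np.ndarray,
    distance_genes: list[str],
) -> tuple[np.ndarray, list[CellTypeExpression]]:
    """Within-group deconvolution and per-sample predicted bulk values.

    Returns (pred, fits) with pred[j] the genes x samples prediction of
    group j's profiles mixed by every sample's composition.
    """
    Gd = G.loc[distance_genes]
    Pmat = P.to_numpy()
    preds = []
    fits = []
    for j in (0, 1):
        cols = G.columns[labels == j]
        fit = deconvolve_expression(Gd[cols], P[cols])
        E = np.zeros((len(distance_genes), P.shape[0]))
        idx = [list(P.index).index(c) for c in fit.E.columns]
        E[:, idx] = fit.E.to_numpy()
        preds.append(E @ Pmat)
        fits.append(fit)
    return np.stack(preds), fits


def iterative_group_fit(
    G: pd.DataFrame,
    P: pd.DataFrame,
    gene: str,
    seed: int | None = None,
    max_iter: int = 100,
    distance_genes: Sequence[str] | None = None,
    max_restarts: int = 10,
    debug: bool = False,
) -> tuple[np.ndarray, int, bool]:
    """One run of the iterative group fit; returns (labels, n_iter, converged).

    Labels are 0/1 group indices over ``G.columns``.  The fit distance is
    |predicted - observed| bulk value of ``gene`` (a multi-gene Euclidean
    distance is available via ``distance_genes``).  A group shrinking to
    k samples or fewer triggers a restart from a fresh random split.
    """
    _check_gene(G, gene)
    if list(G.columns) != list(P.columns):
        raise ValueError("expression and proportion matrices must share sample columns")
    dist_genes = list(distance_genes) if distance_genes else [gene]
    for g in dist_genes:
        _check_gene(G, g)
    n = G.shape[1]
    k = P.shape[0]
    if n < 2 * (k + 1):
        raise ValueError(
            f"need at least {2 * (k + 1)} samples to form two groups of > {k}"
        )
    rng = np.random.default_rng(seed)
    obs = G.loc[dist_genes].to_numpy()

    for restart in range(max_restarts + 1):
        perm = rng.permutation(n)
        labels = np.zeros(n, dtype=int)
        labels[perm[n // 2 :]] = 1
        if max_iter == 0:
            return labels, 0, False
        prev_total = np.inf
        failed = False
        for it in range(1, max_iter + 1):
            pred, _ = _group_predictions(G, P, labels, dist_genes)
            d = np.sqrt(((pred - obs[None, :, :]) ** 2).sum(axis=1))  # 2 x n
            new_labels = np.where(d[1] < d[0], 1, 0)
            ties = d[0] == d[1]
            new_labels[ties] = labels[ties]  # keep current group on exact ties
            if debug:
                total = float(d[new_labels, np.arange(n)].sum())
                assert total <= prev_total + 1e-6 * max(prev_total, 1.0)
                prev_total = total
            if np.array_equal(new_labels, labels):
                return labels, it, True
            if min((new_labels == 0).sum(), (new_labels == 1).sum()) <= k:
                logger.info(
                    "group collapsed below k+1 samples at iteration %d; restarting", it
                )
                failed = True
                break
            labels = new_labels
        if not failed:
            return labels, max_iter, False
    raise RuntimeError(
        f"iterative group fit failed: groups collapsed in all {max_restarts} restarts"
    )


def _cancer_gene_level(
    G: pd.DataFrame,
    P: pd.DataFrame,
    cols: pd.Index,
    gene: str,
    cancer_cell_type: str | None,
) -> float:
    """Estimated cancer-cell expression of ``gene`` within one sample group."""
    fit = deconvolve_expression(G.loc[[gene]][cols], P[cols])
    row = fit.E.loc[gene]
    if cancer_cell_type is not None and cancer_cell_type in row.index:
        return float(row[cancer_cell_type])
    return float(row.max())


def consensus_grouping(
    G: pd.DataFrame,
    P: pd.DataFrame,
    gene: str,
    n_runs: int = 3,
    seed: int | None = None,
    cancer_cell_type: str | None = None,
    max_iter: int = 100,
    distance_genes: Sequence[str] | None = None,
) -> GroupingResult:
    """Majority-vote consensus over independent iterative group fits.

    Each run's two groups are aligned across runs by the estimated
    cancer-cell expression of ``gene`` (the group with the greater value is
    'high'); the per-sample consensus label is the majority over runs.
    ``cancer_cell_type`` names the proportion row holding cancer cells; when
    absent the cell type with maximal estimated gene expression is used
    (logged).
    """
    if n_runs % 2 == 0:
        raise ValueError("n_runs must be odd for a strict majority vote")
    if cancer_cell_type is None:
        logger.info("no designated cancer cell type; using the max-expression cell type")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)

    samples = G.columns
    runs = {}
    n_iters: list[int] = []
    converged: list[bool] = []
    for r, s in enumerate(run_seeds):
        labels, n_iter, conv = iterative_group_fit(
            G, P, gene, seed=int(s), max_iter=max_iter, distance_genes=distance_genes
        )
        n_iters.append(n_iter)
        converged.append(conv)
        levels = [
            _cancer_gene_level(G, P, samples[labels == j], gene, cancer_cell_type)
            for j in (0, 1)
        ]
        hi = int(np.argmax(levels))
        runs[f"run{r}"] = pd.Series(
            np.where(labels == hi, HIGH, LOW), index=samples
        )
    if not any(converged):
        raise RuntimeError("no grouping run converged")
    if not all(converged):
        logger.warning("%d of %d runs did not converge", n_runs - sum(converged), n_runs)

    labels_df = pd.DataFrame(runs)
    votes = (labels_df == HIGH).sum(axis=1)
    consensus = pd.Series(np.where(votes * 2 > n_runs, HIGH, LOW), index=samples)
    agreement = (labels_df.eq(consensus, axis=0)).mean(axis=1)

    levels = {
        lab: _cancer_gene_level(
            G, P, samples[consensus == lab], gene, cancer_cell_type
        )
        for lab in (HIGH, LOW)
        if (consensus == lab).any()
    }
    return GroupingResult(
        gene=gene,
        labels_per_run=labels_df,
        consensus_labels=consensus,
        agreement=agreement,
        n_iterations_per_run=n_iters,
        converged=converged,
        group_gene_levels=levels,
        cancer_cell_type=cancer_cell_type,
    )


def recursive_partition(
    G: pd.DataFrame,
    P: pd.DataFrame,
    gene: str,
    depth: int = 2,
    seed: int | None = None,
    n_runs: int = 3,
    cancer_cell_type: str | None = None,
) -> list[list[str]]:
    """Split samples, then recursively re-split the low group.

    Returns ``depth + 1`` sample groups ordered from highest to lowest
    cancer-cell gene level (fewer when a low group becomes too small to
    split, logged).  The natural comparison pair is the first vs the last
    group.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    k = P.shape[0]
    groups: list[list[str]] = []
    current = list(G.columns)
    rng = np.random.default_rng(seed)
    for level in range(depth):
        if len(current) < 2 * (k + 1):
            logger.info(
                "group of %d samples too small to split at depth %d; stopping",
                len(current), level,
            )
            break
        res = consensus_grouping(
            G[current],
            P[current],
            gene,
            n_runs=n_runs,
            seed=int(rng.integers(2**31 - 1)),
            cancer_cell_type=cancer_cell_type,
        )
        hi = res.consensus_labels.index[res.consensus_labels == HIGH].tolist()
        lo = res.consensus_labels.index[res.consensus_labels == LOW].tolist()
        groups.append(hi)
        current = lo
    groups.append(current)
    return groups


def tercile_concordance(
    scores_a: pd.Series, scores_b: pd.Series
) -> dict[str, dict[str, int]]:
    """Overlap of the top and bottom thirds of two sample rankings.

    Both rankings are split into three equal-size bins (remainder samples
    go to the middle bin); ties at bin boundaries resolve deterministically
    by sample ID.  Returns shared and method-exclusive counts for the top
    and bottom bins — the Euler-diagram numbers of a two-method comparison.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("rankings must cover the same sample set")
    n = len(scores_a)
    third = n // 3

    def bins(scores: pd.Series) -> tuple[set, set]:
        # descending by score; ties resolve deterministically by sample ID
        df = scores.rename("s").rename_axis("sample").reset_index()
        df = df.sort_values(["sample"]).sort_values(
            ["s"], ascending=False, kind="stable"
        )
        ordered = df["sample"].tolist()
        return set(ordered[:third]), set(ordered[n - third :])

    top_a, bot_a = bins(scores_a)
    top_b, bot_b = bins(scores_b)
    return {
        "top": {
            "shared": len(top_a & top_b),
            "only_a": len(top_a - top_b),
            "only_b": len(top_b - top_a),
        },
        "bottom": {
            "shared": len(bot_a & bot_b),
            "only_a": len(bot_a - bot_b),
            "only_b": len(bot_b - bot_a),
        },
    }
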