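"""Reference-guided methylation deconvolution.

Stage 0 selects informative probes from a class-labeled reference panel by
one-vs-rest t-tests; stage 1 factors the bulk beta-value matrix B (probes x
samples) into cell-type methylation profiles M (entries in [0, 1]) and
per-sample proportions P (columns on the probability simplex) by
alternating exactly-constrained least squares, minimizing ||B - M P||_F^2.
The factorization is identifiable only up to column permutation;
:func:`match_cell_types` aligns estimated columns to labeled references
before any cross-run comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from ._solvers import box_lstsq_batch, simplex_lstsq_batch

logger = logging.getLogger(__name__)


@dataclass
class MethDeconvResult:
    """Stage-1 factorization output."""

    M: pd.DataFrame  # probes x k, beta values
    P: pd.DataFrame  # k x samples, simplex columns
    restart_rss: list[float] = field(default_factory=list)
    rss: float = np.nan
    n_iter: int = 0
    converged: bool = True


@dataclass
class CellTypeMatch:
    """One-to-one assignment of estimated columns to reference labels."""

    assignment: dict[str, str]  # estimated column -> reference label
    scores: pd.DataFrame  # estimated columns x reference labels
    ambiguous: list[str] = field(default_factory=list)


def select_informative_probes(
    profiles: pd.DataFrame,
    class_labels: Sequence[str],
    n_probes: int = 500,
    p_threshold: float = 1e-5,
) -> list[str]:
    """Choose discriminative probes by one-vs-rest tests, round-robin across classes.

    ``profiles`` is probes x reference profiles with ``class_labels`` giving
    each profile's class.  With >= 2 profiles per class a two-sample t-test
    (class vs rest) is run per probe and probes at p < ``p_threshold`` are
    ranked by absolute mean beta difference; with singleton classes the
    method falls back to pure effect-size ranking (logged).  The top probes
    are taken round-robin across classes until ``n_probes`` unique probes
    are collected; fewer are returned with a warning when the supply runs
    out.
    """
    labels = np.asarray(class_labels)
    if profiles.shape[1] != len(labels):
        raise ValueError("class_labels must align with profile columns")
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 reference classes")
    X = profiles.to_numpy()
    counts = {c: int((labels == c).sum()) for c in classes}
    use_ttest = all(v >= 2 for v in counts.values()) and profiles.shape[1] - min(
        counts.values()
    ) >= 2
    if not use_ttest:
        logger.info(
            "singleton reference classes present; ranking probes by effect size only"
        )

    ranked: dict[str, list[str]] = {}
    for c in classes:
        own = labels == c
        diff = X[:, own].mean(axis=1) - X[:, ~own].mean(axis=1)
        if use_ttest:
            t, p = stats.ttest_ind(X[:, own], X[:, ~own], axis=1)
            passing = np.nan_to_num(p, nan=1.0) < p_threshold
        else:
            passing = np.abs(diff) > 0
        order = np.argsort(-np.abs(diff), kind="stable")
        ranked[c] = [profiles.index[i] for i in order if passing[i]]

    selected: list[str] = []
    seen: set[str] = set()
    pos = {c: 0 for c in classes}
    while len(selected) < n_probes:
        progressed = False
        for c in classes:
            lst = ranked[c]
            while pos[c] < len(lst) and lst[pos[c]] in seen:
                pos[c] += 1
            if pos[c] < len(lst):
                probe = lst[pos[c]]
                selected.append(probe)
                seen.add(probe)
                pos[c] += 1
                progressed = True
                if len(selected) >= n_probes:
                    break
        if not progressed:
            break
    if not selected:
        warnings.warn("no informative probes found (reference classes indistinguishable)")
    elif len(selected) < n_probes:
        warnings.warn(
            f"only {len(selected)} informative probes available "
            f"(requested {n_probes})"
        )
    return selected


def fit_proportions(B: pd.DataFrame, M: pd.DataFrame) -> pd.DataFrame:
    """Per-sample simplex-constrained regression of bulk betas on fixed profiles."""
    common = B.index.intersection(M.index)
    P = simplex_lstsq_batch(M.loc[common].to_numpy(), B.loc[common].to_numpy())
    return pd.DataFrame(P, index=M.columns, columns=B.columns)


def _als_factorize(
    B: np.ndarray,
    P0: np.ndarray,
    tol: float,
    max_iter: int,
    debug: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Alternating constrained least squares from an initial P (k x n)."""
    P = P0
    prev_rss = np.inf
    converged = False
    n_iter = 0
    M = np.empty((B.shape[0], P.shape[0]))
    for n_iter in range(1, max_iter + 1):
        # M-step: per-probe box-constrained regression on shared design P'
        M = box_lstsq_batch(P.T, B.T).T
        if debug:
            rss_m = float(((B - M @ P) ** 2).sum())
            assert rss_m <= prev_rss + 1e-9 * max(prev_rss, 1.0)
        # P-step: per-sample simplex-constrained regression on shared design M
        P = simplex_lstsq_batch(M, B)
        rss = float(((B - M @ P) ** 2).sum())
        if debug:
            assert rss <= prev_rss + 1e-9 * max(prev_rss, 1.0)
        if np.isfinite(prev_rss) and prev_rss - rss <= tol * max(prev_rss, 1e-300):
            converged = True
            prev_rss = rss
            break
        prev_rss = rss
    return M, P, prev_rss, n_iter, converged


def deconvolve_methylation(
    B: pd.DataFrame,
    k: int,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int | None = None,
    init_M: pd.DataFrame | None = None,
    debug: bool = False,
) -> MethDeconvResult:
    """Factor bulk betas into cell-type profiles and simplex proportions.

    Runs ``n_restarts`` alternating-least-squares fits from Dirichlet-random
    initial proportions (plus one reference-seeded restart when ``init_M``
    is given) and returns the best by residual sum of squares.  Both
    constraint sets (M in [0, 1], P columns on the simplex) hold exactly at
    return.
    """
    n_probes, n_samples = B.shape
    X = B.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("beta matrix must be finite (filter missing probes first)")
    if k == 1:
        M = X.mean(axis=1, keepdims=True)
        return MethDeconvResult(
            M=pd.DataFrame(np.clip(M, 0, 1), index=B.index, columns=["ct1"]),
            P=pd.DataFrame(np.ones((1, n_samples)), index=["ct1"], columns=B.columns),
            restart_rss=[float(((X - M) ** 2).sum())],
            rss=float(((X - M) ** 2).sum()),
            converged=True,
        )
    if k >= min(n_probes, n_samples):
        raise ValueError(f"k={k} must be smaller than min(n_probes, n_samples)")

    rng = np.random.default_rng(seed)
    best = None
    restart_rss: list[float] = []
    inits: list[np.ndarray] = []
    if init_M is not None:
        inits.append(fit_proportions(B, init_M).to_numpy())
    while len(inits) < max(n_restarts, len(inits)):
        inits.append(rng.dirichlet(np.ones(k), size=n_samples).T)
    for P0 in inits:
        M, P, rss, n_iter, conv = _als_factorize(X, P0, tol, max_iter, debug=debug)
        restart_rss.append(rss)
        if best is None or rss < best[2]:
            best = (M, P, rss, n_iter, conv)
    M, P, rss, n_iter, conv = best
    if not conv:
        warnings.warn("methylation deconvolution did not converge in any restart")
    ct_names = [f"ct{i + 1}" for i in range(k)]
    return MethDeconvResult(
        M=pd.DataFrame(M, index=B.index, columns=ct_names),
        P=pd.DataFrame(P, index=ct_names, columns=B.columns),
        restart_rss=restart_rss,
        rss=rss,
        n_iter=n_iter,
        converged=conv,
    )


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlations between two matrices."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.sqrt((Ac**2).sum(axis=0))
    sb = np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (Ac.T @ Bc) / np.outer(sa, sb)
    return np.nan_to_num(C, nan=0.0)


def match_cell_types(
    estimated: pd.DataFrame,
    references: pd.DataFrame,
    tolerance: float = 1e-6,
) -> CellTypeMatch:
    """Assign estimated profile columns to reference labels by maximal total correlation.

    One-to-one matching via the Hungarian algorithm on the Pearson
    correlation matrix over the shared feature space; an estimated column
    whose best and second-best labels score within ``tolerance`` is flagged
    ambiguous.  Ties break by column order.
    """
    common = estimated.index.intersection(references.index)
    if len(common) < 3:
        raise ValueError("estimated and reference profiles share too few features")
    C = _pearson_matrix(
        estimated.loc[common].to_numpy(), references.loc[common].to_numpy()
    )
    scores = pd.DataFrame(C, index=estimated.columns, columns=references.columns)
    ri, ci = linear_sum_assignment(-C)
    assignment = {
        str(estimated.columns[i]): str(references.columns[j]) for i, j in zip(ri, ci)
    }
    ambiguous = []
    for i in ri:
        row = np.sort(C[i])[::-1]
        if len(row) > 1 and row[0] - row[1] < tolerance:
            ambiguous.append(str(estimated.columns[i]))
    if ambiguous:
        logger.info("ambiguous cell-type assignment for columns %s", ambiguous)
    return CellTypeMatch(assignment=assignment, scores=scores, ambiguous=ambiguous)


def match_cell_types_by_markers(
    expr_estimated: pd.DataFrame,
    markers: Mapping[str, Sequence[str]],
) -> CellTypeMatch:
    """Assign estimated expression columns to labels by mean marker expression."""
    score = np.zeros((expr_estimated.shape[1], len(markers)))
    labels = list(markers)
    for j, lab in enumerate(labels):
        genes = [g for g in markers[lab] if g in expr_estimated.index]
        if not genes:
            raise ValueError(f"no marker genes for label {lab!r} present in profiles")
        score[:, j] = expr_estimated.loc[genes].mean(axis=0).to_numpy()
    ri, ci = linear_sum_assignment(-score)
    scores = pd.DataFrame(score, index=expr_estimated.columns, columns=labels)
    assignment = {
        str(expr_estimated.columns[i]): labels[j] for i, j in zip(ri, ci)
    }
    return CellTypeMatch(assignment=assignment, scores=scores)


def _matched_mean_corr(M1: np.ndarray, M2: np.ndarray) -> float:
    """Mean Pearson correlation of optimally matched columns of two profile estimates."""
    C = _pearson_matrix(M1, M2)
    ri, ci = linear_sum_assignment(-C)
    return float(C[ri, ci].mean())


def choose_num_celltypes(
    B: pd.DataFrame,
    k_range: Sequence[int],
    n_boot: int = 10,
    seed: int | None = None,
    stability_floor: float = 0.9,
    n_restarts: int = 2,
    max_iter: int = 500,
) -> tuple[int, dict[int, float]]:
    """Pick the number of cell types by reproducibility of stage-1 profiles.

    For each candidate k the samples are bootstrap-resampled ``n_boot``
    times and factorized; the stability score is the mean pairwise Pearson
    correlation of matched estimated profile columns across resamples.  The
    chosen k* is the largest k whose score exceeds ``stability_floor`` (the
    most detailed decomposition that is still reproducible); if none
    qualifies the best-scoring k is returned with a warning.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be nonempty")
    rng = np.random.default_rng(seed)
    n = B.shape[1]
    scores: dict[int, float] = {}
    for k in k_range:
        if k == 1:
            scores[k] = 1.0  # single column always matches itself
            continue
        Ms = []
        for _ in range(n_boot):
            cols = rng.integers(0, n, size=n)
            res = deconvolve_methylation(
                B.iloc[:, cols],
                k,
                n_restarts=n_restarts,
                max_iter=max_iter,
                seed=int(rng.integers(2**31 - 1)),
            )
            Ms.append(res.M.to_numpy())
        pair_scores = [
            _matched_mean_corr(Ms[i], Ms[j]) for i, j in combinations(range(n_boot), 2)
        ]
        scores[k] = float(np.mean(pair_scores))
    passing = [k for k in k_range if scores[k] > stability_floor]
    if passing:
        k_star = max(passing)
    else:
        k_star = max(scores, key=scores.get)
        warnings.warn(
            f"no k reached stability floor {stability_floor}; returning best k={k_star}"
        )
    return k_star, scores
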