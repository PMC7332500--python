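"""Cell-type-specific differential expression from deconvoluted profiles.

Groups of samples are compared per gene within one cell type using t-tests
built from the deconvolution stage's estimated means and standard errors
(rather than from per-sample values, which do not exist after
deconvolution).  Degrees of freedom follow Welch-Satterthwaite on the two
groups' residual dofs.  Calls combine a Benjamini-Hochberg q-value cutoff
with a fold-change filter; set-overlap enrichment uses the hypergeometric
upper tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap between a query and a target gene set."""

    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p: float


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p-values must not contain NaN")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def celltype_t_test(
    expr_hi,
    expr_lo,
    cell_type: str,
    df_method: str = "welch-satterthwaite",
) -> pd.DataFrame:
    """Per-gene t-tests between two groups' deconvoluted profiles of one cell type.

    ``expr_hi`` / ``expr_lo`` are :class:`~decnet.expression.CellTypeExpression`
    results carrying means ``E``, standard errors ``S`` and residual dof
    ``nu``.  Returns one row per gene with t, df, p, BH q and log2
    fold-change (half-minimum pseudo-value when one mean is zero, flagged).
    """
    if df_method not in ("welch-satterthwaite", "sum"):
        raise ValueError("df_method must be 'welch-satterthwaite' or 'sum'")
    genes = expr_hi.E.index
    if not genes.equals(expr_lo.E.index):
        raise ValueError("the two groups must share the same gene index")
    for grp in (expr_hi, expr_lo):
        if cell_type not in grp.E.columns:
            raise ValueError(f"cell type {cell_type!r} absent from a group")
        if grp.nu < 1:
            raise ValueError("residual degrees of freedom must be >= 1 for inference")

    m1 = expr_hi.E[cell_type].to_numpy()
    m0 = expr_lo.E[cell_type].to_numpy()
    s1 = expr_hi.S[cell_type].to_numpy()
    s0 = expr_lo.S[cell_type].to_numpy()
    nu1, nu0 = float(expr_hi.nu), float(expr_lo.nu)

    var = s1**2 + s0**2
    degenerate = var == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(var)
        if df_method == "sum":
            df = np.full_like(t, nu1 + nu0)
        else:
            df = var**2 / (s1**4 / nu1 + s0**4 / nu0)
    t = np.where(degenerate & (m1 == m0), 0.0, t)
    df = np.where(degenerate, nu1 + nu0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero SEs with unequal means: certainty sentinel, flagged for the caller
    zero_se_diff = degenerate & (m1 != m0)
    if zero_se_diff.any():
        warnings.warn(
            f"{int(zero_se_diff.sum())} genes have zero standard error in both "
            "groups with unequal means; their p-values are 0 sentinels"
        )
        p = np.where(zero_se_diff, 0.0, p)
        t = np.where(zero_se_diff, np.inf * np.sign(m1 - m0), t)

    both_pos = (m1 > 0) & (m0 > 0)
    pos = np.concatenate([m1[m1 > 0], m0[m0 > 0]])
    pseudo = 0.5 * pos.min() if pos.size else 1.0
    with np.errstate(divide="ignore"):
        log2fc = np.log2(np.maximum(m1, pseudo) / np.maximum(m0, pseudo))

    active = None
    if expr_hi.active_constraints is not None and expr_lo.active_constraints is not None:
        active = (
            expr_hi.active_constraints[cell_type].to_numpy()
            | expr_lo.active_constraints[cell_type].to_numpy()
        )

    out = pd.DataFrame(
        {
            "gene": genes,
            "cell_type": cell_type,
            "mean_hi": m1,
            "mean_lo": m0,
            "se_hi": s1,
            "se_lo": s0,
            "t": t,
            "df": df,
            "p": p,
            "log2fc": log2fc,
            "fc_pseudo": ~both_pos,
            "degenerate": zero_se_diff,
        }
    ).set_index("gene")
    if active is not None:
        out["active_constraint"] = active
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def call_de(
    records: pd.DataFrame,
    fold_change: float = 2.0,
    q_threshold: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Split genes into up/down calls at q < ``q_threshold`` and |FC| >= ``fold_change``."""
    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    lfc = np.log2(fold_change)
    sig = records["q"] < q_threshold
    up = records.index[sig & (records["log2fc"] >= lfc)].tolist()
    down = records.index[sig & (records["log2fc"] <= -lfc)].tolist()
    return up, down


def hypergeom_overlap(
    query: Iterable[str], target: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric probability of the observed set overlap.

    P(X >= x) for X ~ Hypergeom(N=|universe|, K=|target|, n=|query|) with
    x = |query & target|.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    query = set(query)
    target = set(target)
    if not query <= universe or not target <= universe:
        raise ValueError("query and target must be subsets of the universe")
    x = len(query & target)
    N, K, n = len(universe), len(target), len(query)
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return EnrichmentResult(
        overlap=x, query_size=n, set_size=K, universe_size=N, p=min(p, 1.0)
    )
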