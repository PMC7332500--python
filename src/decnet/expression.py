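"""Cell-type-specific expression estimation given fixed proportions.

With proportions P (cell types x samples) fixed by the methylation stage,
each gene's bulk values G[g, :] are regressed on P under a nonnegativity
constraint: min ||G[g, :] - e P||^2, e >= 0.  Standard errors come from the
ordinary least-squares covariance formula sigma^2 diag((P P')^-1) with
sigma^2 = RSS / (n - k); entries pinned at zero by the constraint are
flagged, and their SEs keep the unconstrained formula (a documented caveat
of this estimator).  Mixing is linear, so estimation runs on linear-scale
expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solvers import nnls_batch


@dataclass
class CellTypeExpression:
    """Estimated per-cell-type expression means and standard errors."""

    E: pd.DataFrame  # genes x cell types, means (>= 0 when constrained)
    S: pd.DataFrame  # genes x cell types, standard errors
    nu: int  # residual degrees of freedom, n_samples - k
    n_samples: int
    active_constraints: pd.DataFrame | None = None  # genes x cell types, bool
    absent_cell_types: list[str] | None = None


def deconvolve_expression(
    G: pd.DataFrame,
    P: pd.DataFrame,
    nonnegative: bool = True,
) -> CellTypeExpression:
    """Estimate cell-type expression means and SEs from bulk values and proportions.

    ``G`` is genes x samples (linear scale), ``P`` cell types x samples with
    matching sample columns.  Cell types absent from every sample (zero row
    in P, making P P' singular) are dropped from the fit and reported in
    ``absent_cell_types``.
    """
    if list(G.columns) != list(P.columns):
        if set(G.columns) == set(P.columns):
            P = P[G.columns]
        else:
            raise ValueError("expression and proportion matrices must share samples")
    n = G.shape[1]
    k_all = P.shape[0]
    if n <= k_all:
        raise ValueError(f"need more samples ({n}) than cell types ({k_all})")

    absent = P.index[(P.to_numpy() ** 2).sum(axis=1) < 1e-24].tolist()
    if absent:
        warnings.warn(f"cell types absent from all samples: {absent}")
        P = P.drop(index=absent)
    k = P.shape[0]
    A = P.to_numpy().T  # n x k design
    Y = G.to_numpy().T  # n x genes

    if nonnegative:
        E, active = nnls_batch(A, Y)
    else:
        E, *_ = np.linalg.lstsq(A, Y, rcond=None)
        active = np.zeros_like(E, dtype=bool)
    resid = Y - A @ E
    nu = n - k
    sigma2 = (resid**2).sum(axis=0) / nu
    try:
        xtx_inv_diag = np.diag(np.linalg.inv(A.T @ A))
    except np.linalg.LinAlgError:
        xtx_inv_diag = np.diag(np.linalg.pinv(A.T @ A))
    S = np.sqrt(np.outer(xtx_inv_diag, sigma2))

    cols = list(P.index)
    return CellTypeExpression(
        E=pd.DataFrame(E.T, index=G.index, columns=cols),
        S=pd.DataFrame(S.T, index=G.index, columns=cols),
        nu=nu,
        n_samples=n,
        active_constraints=pd.DataFrame(active.T, index=G.index, columns=cols),
        absent_cell_types=absent or None,
    )


def reconstruct_bulk(expr: CellTypeExpression, P: pd.DataFrame) -> pd.DataFrame:
    """Predicted bulk matrix E @ P (genes x samples)."""
    missing = [c for c in expr.E.columns if c not in P.index]
    if missing:
        raise ValueError(f"proportion matrix lacks cell types: {missing}")
    Psub = P.loc[list(expr.E.columns)]
    return pd.DataFrame(
        expr.E.to_numpy() @ Psub.to_numpy(), index=expr.E.index, columns=P.columns
    )


def write_celltype_expression(expr: CellTypeExpression, directory, prefix: str = "expr") -> None:
    """Write means and SEs as TSVs plus a small metadata record."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr.E.to_csv(directory / f"{prefix}_means.tsv", sep="\t", index_label="gene")
    expr.S.to_csv(directory / f"{prefix}_se.tsv", sep="\t", index_label="gene")
    if expr.active_constraints is not None:
        expr.active_constraints.to_csv(
            directory / f"{prefix}_active_constraints.tsv", sep="\t", index_label="gene"
        )
    meta = {
        "nu": expr.nu,
        "n_samples": expr.n_samples,
        "absent_cell_types": expr.absent_cell_types,
    }
    (directory / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))
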