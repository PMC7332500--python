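"""Small constrained least-squares solvers used by the deconvolution stages.

All problems here are tiny convex QPs in k variables (k = number of cell
types, typically 2-8), solved exactly:

* simplex-constrained  min ||A x - b||  s.t. x >= 0, sum(x) = 1
* box-constrained      min ||A x - b||  s.t. lo <= x <= hi
* nonnegative          min ||A x - b||  s.t. x >= 0

The simplex solver enumerates active sets, which is exact for the small k
this package targets.  Batch wrappers share one unconstrained factorization
across columns and fall back to the exact solver only where a constraint is
violated.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import optimize

_FEAS_TOL = 1e-10
_MAX_ENUM_K = 14


def _eq_constrained_ls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least squares under the single equality constraint sum(x) = 1.

    Solves the KKT system; works for rank-deficient A via lstsq on the
    bordered matrix.
    """
    k = A.shape[1]
    Q = A.T @ A
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * Q
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * A.T @ b, [1.0]])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    return sol[:k]


def simplex_lstsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact solution of min ||A x - b|| s.t. x >= 0, 1'x = 1.

    Enumerates zero-sets (active nonnegativity constraints); the global
    optimum of this convex QP is the feasible candidate with least objective.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    k = A.shape[1]
    if k == 1:
        return np.ones(1)
    if k > _MAX_ENUM_K:
        raise ValueError(f"simplex_lstsq supports at most {_MAX_ENUM_K} variables, got {k}")

    x0 = _eq_constrained_ls(A, b)
    if np.all(x0 >= -_FEAS_TOL):
        x0 = np.clip(x0, 0.0, None)
        return x0 / x0.sum()

    best_x = None
    best_obj = np.inf
    idx = np.arange(k)
    # zero out progressively larger subsets; at least one coordinate stays free
    for n_zero in range(1, k):
        for zeros in combinations(idx, n_zero):
            free = np.setdiff1d(idx, zeros, assume_unique=True)
            xf = _eq_constrained_ls(A[:, free], b)
            if np.any(xf < -_FEAS_TOL):
                continue
            x = np.zeros(k)
            x[free] = np.clip(xf, 0.0, None)
            x /= x.sum()
            obj = float(np.sum((A @ x - b) ** 2))
            if obj < best_obj - 1e-15:
                best_obj = obj
                best_x = x
    if best_x is None:  # pragma: no cover - vertices are always feasible
        j = int(np.argmin(np.sum((A - b[:, None]) ** 2, axis=0)))
        best_x = np.zeros(k)
        best_x[j] = 1.0
    return best_x


def simplex_lstsq_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise simplex_lstsq: min ||A X - B|| with each column of X on the simplex."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    k = A.shape[1]
    n = B.shape[1]
    if k == 1:
        return np.ones((1, n))
    # shared KKT factorization for the equality-only relaxation
    Q = A.T @ A
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * Q
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.vstack([2.0 * A.T @ B, np.ones((1, n))])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    X = sol[:k, :]
    bad = np.any(X < -_FEAS_TOL, axis=0)
    X = np.clip(X, 0.0, None)
    X /= X.sum(axis=0, keepdims=True)
    for j in np.nonzero(bad)[0]:
        X[:, j] = simplex_lstsq(A, B[:, j])
    return X


def box_lstsq_batch(
    A: np.ndarray, B: np.ndarray, lo: float = 0.0, hi: float = 1.0
) -> np.ndarray:
    """Column-wise min ||A x - b|| s.t. lo <= x <= hi (exact, BVLS fallback)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    X, *_ = np.linalg.lstsq(A, B, rcond=None)
    bad = np.any((X < lo - _FEAS_TOL) | (X > hi + _FEAS_TOL), axis=0)
    X = np.clip(X, lo, hi)
    for j in np.nonzero(bad)[0]:
        res = optimize.lsq_linear(A, B[:, j], bounds=(lo, hi), method="bvls")
        X[:, j] = np.clip(res.x, lo, hi)
    return X


def nnls_batch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise nonnegative least squares.

    Returns (X, active) where active[i, j] marks coefficients pinned at zero
    by the nonnegativity constraint.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    X, *_ = np.linalg.lstsq(A, B, rcond=None)
    bad = np.any(X < -_FEAS_TOL, axis=0)
    X = np.clip(X, 0.0, None)
    active = np.zeros_like(X, dtype=bool)
    for j in np.nonzero(bad)[0]:
        xj, _ = optimize.nnls(A, B[:, j])
        X[:, j] = xj
        active[:, j] = xj == 0.0
    return X, active
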