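"""Non-negative least squares for many right-hand sides.

Solves ``min_X ||A X - B||_F  s.t.  X >= 0`` column by column using block
principal pivoting on the normal equations (Kim & Park 2011), with columns
sharing a passive set solved in one batched linear solve.  Columns that fail
to converge (near-singular normal equations) fall back to
:func:`scipy.optimize.nnls`.

This is the exact per-column solver behind both the alternating NMF updates
and the cross-entity reconstruction step.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize

__all__ = ["nnls_multi"]

# dual feasibility slack; keeps tiny negative round-off from forcing pivots
_FEAS_TOL = 1e-12


def _solve_groups(G: np.ndarray, H: np.ndarray, F: np.ndarray, cols: np.ndarray,
                  X: np.ndarray, Y: np.ndarray) -> None:
    """Refresh primal/dual variables of ``cols`` given passive sets ``F``.

    Columns with identical passive sets are solved together. X and Y are
    updated in place; passive duals and active primals are pinned to zero.
    """
    k = G.shape[0]
    weights = (1 << np.arange(k, dtype=np.uint64))
    keys = weights @ F[:, cols].astype(np.uint64)
    for key in np.unique(keys):
        grp = cols[keys == key]
        passive = F[:, grp[0]]
        if not passive.any():
            X[:, grp] = 0.0
            Y[:, grp] = -H[:, grp]
            continue
        Gpp = G[np.ix_(passive, passive)]
        try:
            sol = np.linalg.solve(Gpp, H[np.ix_(passive, grp)])
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(Gpp, H[np.ix_(passive, grp)], rcond=None)[0]
        X[:, grp] = 0.0
        X[np.ix_(passive, grp)] = sol
        Y[:, grp] = G[:, passive] @ sol - H[:, grp]
        Y[np.ix_(passive, grp)] = 0.0


def nnls_multi(A: np.ndarray, B: np.ndarray, max_pivots: int = 200) -> np.ndarray:
    """Solve ``min ||A X - B||_F`` with ``X >= 0``.

    Parameters
    ----------
    A : (m, k) design matrix.
    B : (m, n) stacked right-hand sides.
    max_pivots : pivot-iteration cap before falling back per column.

    Returns
    -------
    X : (k, n) non-negative solution, each column an exact NNLS optimum.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        return nnls_multi(A, B[:, None], max_pivots)[:, 0]
    m, k = A.shape
    n = B.shape[1]
    G = A.T @ A
    H = A.T @ B

    X = np.zeros((k, n))
    Y = -H.copy()
    F = np.zeros((k, n), dtype=bool)          # passive (unconstrained) sets
    alpha = np.full(n, 3, dtype=int)          # backup-rule credit
    beta = np.full(n, k + 1, dtype=int)       # best infeasibility seen

    for _ in range(max_pivots):
        infeas = (F & (X < -_FEAS_TOL)) | (~F & (Y < -_FEAS_TOL))
        n_infeas = infeas.sum(axis=0)
        pending = np.flatnonzero(n_infeas)
        if pending.size == 0:
            break
        for j in pending:
            if n_infeas[j] < beta[j]:
                beta[j] = n_infeas[j]
                alpha[j] = 3
                F[:, j] ^= infeas[:, j]
            elif alpha[j] >= 1:
                alpha[j] -= 1
                F[:, j] ^= infeas[:, j]
            else:
                # backup rule: flip only the highest infeasible index
                i = np.max(np.flatnonzero(infeas[:, j]))
                F[i, j] = ~F[i, j]
        _solve_groups(G, H, F, pending, X, Y)
    else:
        # scalar fallback for any still-infeasible column
        infeas = (F & (X < -_FEAS_TOL)) | (~F & (Y < -_FEAS_TOL))
        for j in np.flatnonzero(infeas.any(axis=0)):
            X[:, j], _ = scipy.optimize.nnls(A, B[:, j])

    np.maximum(X, 0.0, out=X)
    return X
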