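"""Non-negative matrix factorization of envelope matrices.

An envelope matrix ``E`` (muscles x timepoints) is factorized as
``E ~ W @ C`` with non-negative spatial synergy vectors ``W`` (muscles x k,
each column scaled to a maximum weight of 1) and activation coefficients
``C`` (k x timepoints).  Reconstruction quality is summarized by the total
variance accounted for,

    tVAF = 100 * (1 - ||E - W C||_F^2 / ||E||_F^2),

with an uncentered total sum of squares.  Because the factorization is a
non-convex problem solved from random starts, each fit is repeated from
several seeded initializations and the restart with the highest tVAF is
kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nnls import nnls_multi

__all__ = [
    "SynergyDecomposition",
    "TvafCurve",
    "tvaf",
    "normalize_decomposition",
    "nmf",
    "tvaf_curve",
]


@dataclass
class SynergyDecomposition:
    """One selected NMF solution for a participant x task envelope matrix."""

    W: np.ndarray                  # (m, k), columns max-normalized to 1
    C: np.ndarray                  # (k, n)
    k: int
    tvaf: float                    # percent
    restarts: int
    best_restart_seed: int
    converged: bool
    iterations_used: int
    participant_id: str | None = None
    task_id: str | None = None
    residual_history: list[float] = field(default_factory=list, repr=False)

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class TvafCurve:
    """tVAF as a function of the number of extracted synergies."""

    tvaf_by_k: np.ndarray                        # index 0 -> k=1
    decompositions: list[SynergyDecomposition]
    participant_id: str | None = None
    task_id: str | None = None
    monotonicity_adjusted_k: list[int] = field(default_factory=list)

    def __getitem__(self, k: int) -> SynergyDecomposition:
        """Decomposition at synergy count ``k`` (1-based)."""
        return self.decompositions[k - 1]

    @property
    def k_max(self) -> int:
        return len(self.tvaf_by_k)


def tvaf(E: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Total variance accounted for, in percent.

    Uncentered: ``100 * (1 - ||E - WC||_F^2 / ||E||_F^2)``.  Not clamped;
    pathological factors can give negative values.
    """
    E = np.asarray(E, dtype=float)
    sst = float(np.sum(E * E))
    if sst == 0.0:
        raise ValueError("tVAF undefined: envelope matrix has zero Frobenius norm")
    sse = float(np.sum((E - W @ C) ** 2))
    return 100.0 * (1.0 - sse / sst)


def normalize_decomposition(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each synergy vector to a maximum weight of 1.

    The matching activation-coefficient row is multiplied by the same factor
    so that the product ``W @ C`` is unchanged.
    """
    W = np.asarray(W, dtype=float)
    C = np.asarray(C, dtype=float)
    scales = W.max(axis=0)
    bad = np.flatnonzero(scales <= 0)
    if bad.size:
        raise ValueError(f"synergy vector {bad[0]} is all zero; cannot max-normalize")
    return W / scales, C * scales[:, None]


def _anls_run(E: np.ndarray, k: int, rng: np.random.Generator, max_iter: int,
              tol: float, track_residuals: bool) -> tuple[np.ndarray, np.ndarray, bool, int, list[float]]:
    """One alternating-NNLS run from a random start.

    Each half-update is an exact non-negative least-squares solve, so the
    Frobenius residual is non-increasing except at the rare reseeding of a
    synergy that collapsed to zero.
    """
    m, n = E.shape
    # uniform on (0, 1]
    W = 1.0 - rng.random((m, k))
    C = 1.0 - rng.random((k, n))
    norm_E = np.linalg.norm(E)
    prev = np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = nnls_multi(W, E)
        dead = ~C.any(axis=1)
        if dead.any():
            C[dead] = 1e-4 * (1.0 - rng.random((int(dead.sum()), n)))
        W = nnls_multi(C.T, E.T).T
        dead = ~W.any(axis=0)
        if dead.any():
            W[:, dead] = 1e-4 * (1.0 - rng.random((m, int(dead.sum()))))
        res = float(np.linalg.norm(E - W @ C))
        if track_residuals:
            history.append(res)
        if abs(prev - res) < tol * max(norm_E, np.finfo(float).tiny):
            converged = True
            break
        prev = res
    return W, C, converged, it, history


def nmf(E: np.ndarray, k: int, restarts: int = 50, seed: int = 0,
        max_iter: int = 500, tol: float = 1e-6, solver: str = "anls",
        track_residuals: bool = False) -> SynergyDecomposition:
    """Best-of-restarts NMF at a fixed synergy count.

    Parameters
    ----------
    E : (m, n) non-negative envelope matrix.
    k : number of synergies, ``1 <= k <= min(m, n)``.
    restarts : independent random initializations; the solution with the
        highest tVAF is returned.
    seed : base seed; restart ``r`` draws from ``SeedSequence([seed, r])``,
        so results are reproducible and restarts are independent.
    solver : ``"anls"`` (exact alternating NNLS, default) or ``"mu"``
        (multiplicative updates).
    """
    E = np.asarray(E, dtype=float)
    m, n = E.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} out of range for a {m}x{n} matrix")
    if np.any(E < 0):
        raise ValueError("envelope matrix must be non-negative")
    if solver not in ("anls", "mu"):
        raise ValueError(f"unknown solver {solver!r}")

    best: SynergyDecomposition | None = None
    for r in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        if solver == "anls":
            W, C, converged, it, history = _anls_run(E, k, rng, max_iter, tol,
                                                     track_residuals)
        else:
            W, C, converged, it, history = _mu_run(E, k, rng, max_iter, tol,
                                                   track_residuals)
        t = tvaf(E, W, C)
        if best is None or t > best.tvaf:
            W, C = normalize_decomposition(np.maximum(W, 0), C)
            best = SynergyDecomposition(
                W=W, C=C, k=k, tvaf=t, restarts=restarts, best_restart_seed=r,
                converged=converged, iterations_used=it,
                residual_history=history)
    assert best is not None
    return best


def _mu_run(E, k, rng, max_iter, tol, track_residuals):
    """Lee-Seung multiplicative updates (fallback solver)."""
    m, n = E.shape
    eps = 1e-12
    W = 1.0 - rng.random((m, k))
    C = 1.0 - rng.random((k, n))
    norm_E = np.linalg.norm(E)
    prev = np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C *= (W.T @ E) / (W.T @ W @ C + eps)
        W *= (E @ C.T) / (W @ C @ C.T + eps)
        res = float(np.linalg.norm(E - W @ C))
        if track_residuals:
            history.append(res)
        if abs(prev - res) < tol * max(norm_E, np.finfo(float).tiny):
            converged = True
            break
        prev = res
    return W, C, converged, it, history


def tvaf_curve(E: np.ndarray, restarts: int = 50, seed: int = 0,
               k_max: int | None = None, max_iter: int = 500, tol: float = 1e-6,
               solver: str = "anls", participant_id: str | None = None,
               task_id: str | None = None) -> TvafCurve:
    """Fit NMF for k = 1 .. m-1 and record the tVAF curve.

    The curve is enforced to be non-decreasing: a drop at k+1 (a restart
    stuck in a poor local minimum) triggers one re-run with fresh restart
    seeds; if the value is still lower it is replaced by the value at k and
    the index is flagged in ``monotonicity_adjusted_k``.
    """
    E = np.asarray(E, dtype=float)
    m = E.shape[0]
    if k_max is None:
        k_max = m - 1
    if not 1 <= k_max <= min(m, E.shape[1]):
        raise ValueError(f"k_max={k_max} out of range")
    decomps: list[SynergyDecomposition] = []
    values = np.empty(k_max)
    adjusted: list[int] = []
    for k in range(1, k_max + 1):
        d = nmf(E, k, restarts=restarts, seed=seed + k, max_iter=max_iter,
                tol=tol, solver=solver)
        if k > 1 and d.tvaf < values[k - 2]:
            retry = nmf(E, k, restarts=restarts, seed=seed + k + 104729,
                        max_iter=max_iter, tol=tol, solver=solver)
            if retry.tvaf > d.tvaf:
                d = retry
            if d.tvaf < values[k - 2]:
                d.tvaf = float(values[k - 2])
                adjusted.append(k)
        d.participant_id = participant_id
        d.task_id = task_id
        values[k - 1] = d.tvaf
        decomps.append(d)
    return TvafCurve(tvaf_by_k=values, decompositions=decomps,
                     participant_id=participant_id, task_id=task_id,
                     monotonicity_adjusted_k=adjusted)
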