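"""Similarity metrics and synergy alignment.

Three metrics quantify how alike two synergies are:

* cosine similarity (CosSim) between weight vectors or coefficient rows,
  threshold 0.8;
* Pearson's r between weight vectors, thresholded at the two-tailed
  critical value for the muscle count (0.623 for 16 muscles at p = 0.01);
* the maximum cross-correlation r_max between activation waveforms over a
  bounded lag window, threshold 0.9.

Because NMF returns synergies in arbitrary order, comparisons across
participants first align synergies to a reference participant by greedy
cosine matching (take the globally most similar remaining pair, repeat).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .factorization import SynergyDecomposition

__all__ = [
    "cos_sim",
    "pearson_r",
    "critical_r",
    "xcorr_rmax",
    "greedy_match",
    "optimal_match",
    "reorder_to_reference",
    "pairwise_interparticipant",
    "COSSIM_THRESHOLD",
    "RMAX_THRESHOLD",
]

COSSIM_THRESHOLD = 0.8
RMAX_THRESHOLD = 0.9


def cos_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors; in [0, 1] for non-negative input."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def pearson_r(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError("vectors must have equal length")
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    return float(scipy.stats.pearsonr(u, v).statistic)


def critical_r(n_observations: int, alpha: float = 0.01) -> float:
    """Two-tailed critical value of Pearson's r.

    Inverts the central t distribution with ``n - 2`` degrees of freedom:
    ``r_crit = t / sqrt(t^2 + df)``.  For 16 paired observations (one per
    muscle) at alpha = 0.01 this gives 0.623.
    """
    if n_observations < 3:
        raise ValueError("need at least 3 observations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n_observations - 2
    t = scipy.stats.t.ppf(1 - alpha / 2, df)
    return float(t / np.sqrt(t * t + df))


def xcorr_rmax(c1: np.ndarray, c2: np.ndarray, max_lag_fraction: float = 0.1,
               block_length: int | None = None) -> tuple[float, int]:
    """Maximum lagged Pearson correlation between two activation waveforms.

    A positive lag means ``c2`` is delayed relative to ``c1``.  The lag
    window is ``round(max_lag_fraction * block_length)`` samples (the full
    series length if ``block_length`` is None); correlations are computed
    on the overlapping region only.  Ties are broken toward the smallest
    |lag|, negative lag first; zero-variance overlaps are skipped.
    """
    c1 = np.asarray(c1, dtype=float).ravel()
    c2 = np.asarray(c2, dtype=float).ravel()
    n = c1.size
    if c2.size != n or n < 3:
        raise ValueError("waveforms must have equal length >= 3")
    basis = block_length if block_length is not None else n
    max_lag = int(round(max_lag_fraction * basis))
    best: tuple[float, int] | None = None
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l >= 0)):
        if lag >= 0:
            a, b = c1[: n - lag] if lag else c1, c2[lag:]
        else:
            a, b = c1[-lag:], c2[: n + lag]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(scipy.stats.pearsonr(a, b).statistic)
        if best is None or r > best[0]:
            best = (r, lag)
    if best is None:
        raise ValueError("no lag with non-degenerate overlap")
    return best


def greedy_match(ref: np.ndarray, other: np.ndarray,
                 metric=cos_sim) -> np.ndarray:
    """Greedy one-to-one column assignment of ``other`` onto ``ref``.

    Repeatedly accepts the globally most similar remaining (reference,
    other) column pair; ties break toward the lowest reference index, then
    the lowest other index.  Returns ``perm`` with ``perm[j]`` = column of
    ``other`` assigned to reference column ``j``.
    """
    k = ref.shape[1]
    if other.shape[1] != k:
        raise ValueError("matrices must have the same number of columns")
    S = np.array([[metric(ref[:, i], other[:, j]) for j in range(k)]
                  for i in range(k)])
    perm = np.full(k, -1, dtype=int)
    free_r, free_o = set(range(k)), set(range(k))
    for _ in range(k):
        i, j = max(((i, j) for i in sorted(free_r) for j in sorted(free_o)),
                   key=lambda ij: (S[ij], -ij[0], -ij[1]))
        perm[i] = j
        free_r.remove(i)
        free_o.remove(j)
    return perm


def optimal_match(ref: np.ndarray, other: np.ndarray,
                  metric=cos_sim) -> tuple[np.ndarray, float]:
    """Exhaustive assignment maximizing total similarity (oracle, k <= 8)."""
    k = ref.shape[1]
    if k > 8:
        raise ValueError("exhaustive matching limited to k <= 8")
    S = np.array([[metric(ref[:, i], other[:, j]) for j in range(k)]
                  for i in range(k)])
    best_perm, best_total = None, -np.inf
    for p in itertools.permutations(range(k)):
        total = sum(S[i, p[i]] for i in range(k))
        if total > best_total:
            best_total, best_perm = total, p
    return np.array(best_perm), float(best_total)


def apply_permutation(d: SynergyDecomposition, perm: np.ndarray) -> SynergyDecomposition:
    """Reorder synergies of a decomposition (W columns and C rows together)."""
    out = SynergyDecomposition(
        W=d.W[:, perm].copy(), C=d.C[perm].copy(), k=d.k, tvaf=d.tvaf,
        restarts=d.restarts, best_restart_seed=d.best_restart_seed,
        converged=d.converged, iterations_used=d.iterations_used,
        participant_id=d.participant_id, task_id=d.task_id)
    return out


def reorder_to_reference(decompositions: dict[str, SynergyDecomposition],
                         reference: str) -> tuple[dict[str, SynergyDecomposition],
                                                  dict[str, np.ndarray]]:
    """Align every participant's synergies to a reference participant.

    Greedy CosSim matching of synergy-vector columns; W columns and C rows
    are permuted together so comparable synergies share an index across
    participants.
    """
    ref = decompositions[reference]
    ks = {d.k for d in decompositions.values()}
    if len(ks) != 1:
        raise ValueError(f"synergy counts differ across participants: {sorted(ks)}")
    reordered, perms = {}, {}
    for pid, d in decompositions.items():
        perm = (np.arange(d.k) if pid == reference
                else greedy_match(ref.W, d.W))
        perms[pid] = perm
        reordered[pid] = apply_permutation(d, perm)
    return reordered, perms


@dataclass
class _Thresholds:
    cossim: float
    r: float
    rmax: float


def pairwise_interparticipant(decompositions: dict[str, SynergyDecomposition],
                              alpha: float = 0.01,
                              cossim_threshold: float = COSSIM_THRESHOLD,
                              rmax_threshold: float = RMAX_THRESHOLD,
                              max_lag_fraction: float = 0.1,
                              block_length: int | None = 100,
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs synergy similarity for one task (synergies pre-aligned).

    For every unordered participant pair and synergy index, computes CosSim
    and Pearson r on synergy vectors, and CosSim and r_max on activation
    coefficients.  Returns a tidy per-pair table and a per-synergy summary
    of averages with threshold verdicts (7 participants give 21 pairs).
    """
    pids = sorted(decompositions)
    ks = {decompositions[p].k for p in pids}
    if len(ks) != 1:
        raise ValueError("all decompositions must share the same synergy count")
    k = ks.pop()
    m = decompositions[pids[0]].W.shape[0]
    thr = _Thresholds(cossim=cossim_threshold, r=critical_r(m, alpha),
                      rmax=rmax_threshold)

    rows = []
    for pa, pb in itertools.combinations(pids, 2):
        da, db = decompositions[pa], decompositions[pb]
        for s in range(k):
            rmax, lag = xcorr_rmax(da.C[s], db.C[s], max_lag_fraction,
                                   block_length)
            rows.extend([
                dict(participant_a=pa, participant_b=pb, synergy=s,
                     part="W", metric="cossim",
                     value=cos_sim(da.W[:, s], db.W[:, s]),
                     threshold=thr.cossim, lag=np.nan),
                dict(participant_a=pa, participant_b=pb, synergy=s,
                     part="W", metric="pearson_r",
                     value=pearson_r(da.W[:, s], db.W[:, s]),
                     threshold=thr.r, lag=np.nan),
                dict(participant_a=pa, participant_b=pb, synergy=s,
                     part="C", metric="cossim",
                     value=cos_sim(da.C[s], db.C[s]),
                     threshold=thr.cossim, lag=np.nan),
                dict(participant_a=pa, participant_b=pb, synergy=s,
                     part="C", metric="xcorr_rmax", value=rmax,
                     threshold=thr.rmax, lag=lag),
            ])
    pairs = pd.DataFrame(rows)
    pairs["similar"] = pairs["value"] > pairs["threshold"]

    summary = (pairs.groupby(["synergy", "part", "metric"], as_index=False)
               .agg(mean_value=("value", "mean"), sd_value=("value", "std"),
                    threshold=("threshold", "first"), n_pairs=("value", "size")))
    summary["similar"] = summary["mean_value"] > summary["threshold"]
    return pairs, summary
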