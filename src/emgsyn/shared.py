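"""Shared versus task-specific synergies across tasks.

Two synergy vectors from different tasks count as shared when their Pearson
r exceeds the critical value for the muscle count (0.623 for 16 muscles at
p = 0.01), matched one-to-one greedily by descending r.  The relative count

    pct_shared = 100 * n_shared / (k1 + k2 - n_shared)

normalizes by the union of synergies of the two tasks.  The sharedOA
variant compares every task at the common study-wide rank (NoSoA); the
sharedIND variant uses each task's own NoS.  A synergy counts as shared
across all three tasks only when the three pairwise matchings agree
transitively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factorization import SynergyDecomposition
from .reconstruction import _similarity_rows, reconstruct_C, reconstruct_W
from .similarity import cos_sim, critical_r, greedy_match, pearson_r

__all__ = [
    "SharedSynergyResult",
    "count_shared",
    "pct_shared",
    "shared_oa",
    "shared_ind",
    "all_task_shared",
    "cross_task_reconstruction",
]


@dataclass
class SharedSynergyResult:
    task_pair: tuple[str, str]
    method: str                       # "sharedOA" | "sharedIND"
    k1: int
    k2: int
    n_shared: int
    pct_shared: float
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    participant_id: str | None = None


def count_shared(W1: np.ndarray, W2: np.ndarray,
                 r_threshold: float | None = None
                 ) -> tuple[int, list[tuple[int, int, float]]]:
    """Greedy one-to-one count of above-threshold synergy-vector pairs.

    Pearson r is computed for every column pair; pairs are accepted in
    descending r (ties toward the lowest index pair) while r exceeds the
    threshold, removing both synergies once matched.
    """
    W1 = np.asarray(W1, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    if W1.shape[0] != W2.shape[0]:
        raise ValueError("muscle counts differ between the two tasks")
    if r_threshold is None:
        r_threshold = critical_r(W1.shape[0], 0.01)
    k1, k2 = W1.shape[1], W2.shape[1]
    R = np.array([[pearson_r(W1[:, i], W2[:, j]) for j in range(k2)]
                  for i in range(k1)])
    pairs: list[tuple[int, int, float]] = []
    free1, free2 = set(range(k1)), set(range(k2))
    while free1 and free2:
        i, j = max(((i, j) for i in sorted(free1) for j in sorted(free2)),
                   key=lambda ij: (R[ij], -ij[0], -ij[1]))
        if R[i, j] <= r_threshold:
            break
        pairs.append((i, j, float(R[i, j])))
        free1.remove(i)
        free2.remove(j)
    return len(pairs), pairs


def pct_shared(n_shared: int, k1: int, k2: int) -> float:
    """Relative shared-synergy count, ``100 * n / (k1 + k2 - n)``."""
    if not 0 <= n_shared <= min(k1, k2):
        raise ValueError("n_shared must lie in [0, min(k1, k2)]")
    denom = k1 + k2 - n_shared
    if denom <= 0:
        raise ValueError("k1 + k2 - n_shared must be positive")
    return 100.0 * n_shared / denom


def _shared_pairwise(decomps: dict[str, SynergyDecomposition], method: str,
                     r_threshold: float | None,
                     participant_id: str | None) -> list[SharedSynergyResult]:
    results = []
    for t1, t2 in itertools.combinations(sorted(decomps), 2):
        W1, W2 = decomps[t1].W, decomps[t2].W
        n, pairs = count_shared(W1, W2, r_threshold)
        results.append(SharedSynergyResult(
            task_pair=(t1, t2), method=method,
            k1=W1.shape[1], k2=W2.shape[1], n_shared=n,
            pct_shared=pct_shared(n, W1.shape[1], W2.shape[1]),
            matched_pairs=pairs, participant_id=participant_id))
    return results


def all_task_shared(results: list[SharedSynergyResult]) -> list[tuple[int, ...]]:
    """Synergies shared consistently across all three tasks.

    For tasks (A, B, C): synergy ``a`` of A qualifies when its partners
    ``b = match_AB(a)`` and ``c = match_AC(a)`` are themselves matched to
    each other in the (B, C) comparison.  Returns (a, b, c) index tuples.
    """
    by_pair = {r.task_pair: r for r in results}
    tasks = sorted({t for r in results for t in r.task_pair})
    if len(tasks) != 3 or len(by_pair) != 3:
        raise ValueError("expected pairwise results for exactly 3 tasks")
    tA, tB, tC = tasks
    mAB = {i: j for i, j, _ in by_pair[(tA, tB)].matched_pairs}
    mAC = {i: j for i, j, _ in by_pair[(tA, tC)].matched_pairs}
    mBC = {(i, j) for i, j, _ in by_pair[(tB, tC)].matched_pairs}
    out = []
    for a, b in mAB.items():
        if a in mAC and (b, mAC[a]) in mBC:
            out.append((a, b, mAC[a]))
    return out


def shared_oa(decomps_at_nosoa: dict[str, SynergyDecomposition],
              r_threshold: float | None = None,
              participant_id: str | None = None) -> list[SharedSynergyResult]:
    """Shared-synergy counts with every task at the common rank NoSoA."""
    ks = {d.k for d in decomps_at_nosoa.values()}
    if len(ks) != 1:
        raise ValueError("sharedOA requires every task decomposed at NoSoA")
    return _shared_pairwise(decomps_at_nosoa, "sharedOA", r_threshold,
                            participant_id)


def shared_ind(decomps_at_nos: dict[str, SynergyDecomposition],
               r_threshold: float | None = None,
               participant_id: str | None = None) -> list[SharedSynergyResult]:
    """Shared-synergy counts with each task at its own NoS."""
    return _shared_pairwise(decomps_at_nos, "sharedIND", r_threshold,
                            participant_id)


def cross_task_reconstruction(decomps: dict[str, SynergyDecomposition],
                              envelopes: dict[str, np.ndarray],
                              max_lag_fraction: float = 0.1,
                              block_length: int | None = 100) -> pd.DataFrame:
    """Reconstruct each task's factors from the other tasks' counterparts.

    To refit task A's coefficients from task B's synergy vectors, B's W is
    first preordered by greedy CosSim matching of B's activation
    coefficients onto A's (synergies are ordered per task, not across
    tasks); symmetrically, B's C is preordered by the CosSim of the two
    tasks' synergy vectors before refitting A's W.  With three tasks this
    yields two reconstructions per task and direction.
    """
    tasks = sorted(decomps)
    rows: list[dict] = []
    for target, source in itertools.permutations(tasks, 2):
        E = np.asarray(envelopes[target], dtype=float)
        dt, ds = decomps[target], decomps[source]
        # C_rec from source W, preordered by coefficient similarity
        perm = greedy_match(dt.C.T, ds.C.T)
        C_rec, t_c = reconstruct_C(E, ds.W[:, perm])
        base = dict(target=target, source=source, direction="C_from_W",
                    tvaf_rec=t_c, tvaf_own=dt.tvaf)
        rows.extend(_similarity_rows(base, dt.C, C_rec, "C",
                                     max_lag_fraction, block_length))
        # W_rec from source C, preordered by synergy-vector similarity
        perm = greedy_match(dt.W, ds.W)
        W_rec, t_w = reconstruct_W(E, ds.C[perm])
        base = dict(target=target, source=source, direction="W_from_C",
                    tvaf_rec=t_w, tvaf_own=dt.tvaf)
        rows.extend(_similarity_rows(base, dt.W, W_rec, "W",
                                     max_lag_fraction, block_length))
    return pd.DataFrame(rows)
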