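"""Cross-entity reconstruction with non-negative least squares.

One participant's (or task's) synergy vectors W can be tested on another
entity's envelope matrix by holding W fixed and refitting the activation
coefficients with NNLS (and symmetrically: fixing C and refitting W).  The
tVAF of the refit, tVAF_rec, measures how well the fixed structure explains
the new data; it can never exceed the target's own jointly optimized tVAF.
A chance floor, tVAF_rand, repeats the procedure with seeded uniform random
matrices aligned to the real source by greedy cosine matching.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._nnls import nnls_multi
from .factorization import SynergyDecomposition, tvaf
from .similarity import cos_sim, greedy_match, pearson_r, xcorr_rmax

__all__ = [
    "reconstruct_C",
    "reconstruct_W",
    "cross_participant_study",
    "randomized_null",
]


def reconstruct_C(E_target: np.ndarray, W_fixed: np.ndarray) -> tuple[np.ndarray, float]:
    """Refit activation coefficients with the synergy vectors held fixed.

    Each column of C_rec solves ``min ||E_col - W_fixed c||, c >= 0``
    exactly; columns are independent given the fixed design.
    """
    W_fixed = np.asarray(W_fixed, dtype=float)
    E_target = np.asarray(E_target, dtype=float)
    if not W_fixed.any(axis=0).all():
        j = int(np.flatnonzero(~W_fixed.any(axis=0))[0])
        raise ValueError(f"fixed synergy vector {j} is all zero")
    C_rec = nnls_multi(W_fixed, E_target)
    return C_rec, tvaf(E_target, W_fixed, C_rec)


def reconstruct_W(E_target: np.ndarray, C_fixed: np.ndarray) -> tuple[np.ndarray, float]:
    """Refit synergy vectors with the activation coefficients held fixed.

    The transposed problem of :func:`reconstruct_C`.
    """
    C_fixed = np.asarray(C_fixed, dtype=float)
    E_target = np.asarray(E_target, dtype=float)
    if not C_fixed.any(axis=1).all():
        j = int(np.flatnonzero(~C_fixed.any(axis=1))[0])
        raise ValueError(f"fixed activation coefficient {j} is all zero")
    W_rec = nnls_multi(C_fixed.T, E_target.T).T
    return W_rec, tvaf(E_target, W_rec, C_fixed)


def _similarity_rows(base: dict, original: np.ndarray, recovered: np.ndarray,
                     part: str, max_lag_fraction: float,
                     block_length: int | None) -> list[dict]:
    """Per-synergy similarity between an original factor and its refit.

    Synergy vectors are compared with CosSim and Pearson r; activation
    coefficients with CosSim and lagged cross-correlation r_max.  A factor
    that collapsed to zero in the refit gets NaN similarities.
    """
    rows = []
    k = original.shape[1] if part == "W" else original.shape[0]
    for s in range(k):
        u = original[:, s] if part == "W" else original[s]
        v = recovered[:, s] if part == "W" else recovered[s]
        row = dict(base, synergy=s, part=part)
        try:
            row["cossim"] = cos_sim(u, v)
        except ValueError:
            row["cossim"] = np.nan
        try:
            if part == "W":
                row["pearson_r"] = pearson_r(u, v)
            else:
                row["xcorr_rmax"], row["lag"] = xcorr_rmax(
                    u, v, max_lag_fraction, block_length)
        except ValueError:
            row["pearson_r" if part == "W" else "xcorr_rmax"] = np.nan
        rows.append(row)
    return rows


def cross_participant_study(decompositions: dict[str, SynergyDecomposition],
                            envelopes: dict[str, np.ndarray],
                            max_lag_fraction: float = 0.1,
                            block_length: int | None = 100) -> pd.DataFrame:
    """Reconstruct every participant from every other participant.

    For each ordered (target, source) pair the target's W is refit from the
    source's C and the target's C from the source's W (7 participants give
    6 reconstructions per participant and direction).  Records tVAF_rec and
    per-synergy similarity of the refit factor to the target's original.
    Synergies must already be aligned across participants.
    """
    pids = sorted(decompositions)
    rows: list[dict] = []
    for target, source in itertools.permutations(pids, 2):
        E = np.asarray(envelopes[target], dtype=float)
        dt, ds = decompositions[target], decompositions[source]
        W_rec, t_w = reconstruct_W(E, ds.C)
        base = dict(target=target, source=source, direction="W_from_C",
                    tvaf_rec=t_w, tvaf_own=dt.tvaf)
        rows.extend(_similarity_rows(base, dt.W, W_rec, "W",
                                     max_lag_fraction, block_length))
        C_rec, t_c = reconstruct_C(E, ds.W)
        base = dict(target=target, source=source, direction="C_from_W",
                    tvaf_rec=t_c, tvaf_own=dt.tvaf)
        rows.extend(_similarity_rows(base, dt.C, C_rec, "C",
                                     max_lag_fraction, block_length))
    return pd.DataFrame(rows)


def random_like(shape: tuple[int, int], rng: np.random.Generator,
                as_W: bool) -> np.ndarray:
    """Seeded uniform(0,1) stand-in factor; W-style columns max-normalized."""
    M = rng.random(shape)
    if as_W:
        M = M / M.max(axis=0)
    return M


def randomized_null(target: SynergyDecomposition, E_target: np.ndarray,
                    sources: list[SynergyDecomposition], fixed_part: str,
                    seed: int, n_random: int | None = None,
                    max_lag_fraction: float = 0.1,
                    block_length: int | None = 100) -> pd.DataFrame:
    """Chance floor for the reconstruction: seeded random fixed factors.

    One random matrix per real source (so tVAF_rand averages are comparable
    with tVAF_rec averages), each preordered against the corresponding real
    source's factor by greedy cosine matching before the NNLS refit.
    """
    if fixed_part not in ("W", "C"):
        raise ValueError("fixed_part must be 'W' or 'C'")
    if n_random is None:
        n_random = len(sources)
    E_target = np.asarray(E_target, dtype=float)
    rows: list[dict] = []
    for i in range(n_random):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        src = sources[i % len(sources)]
        if fixed_part == "W":
            R = random_like(src.W.shape, rng, as_W=True)
            perm = greedy_match(src.W, R)
            R = R[:, perm]
            C_rec, t = reconstruct_C(E_target, R)
            base = dict(target=target.participant_id, source=f"random_{i}",
                        direction="C_from_W", tvaf_rand=t, tvaf_own=target.tvaf)
            rows.extend(_similarity_rows(base, target.C, C_rec, "C",
                                         max_lag_fraction, block_length))
        else:
            R = random_like(src.C.shape, rng, as_W=False)
            perm = greedy_match(src.C.T, R.T)
            R = R[perm]
            W_rec, t = reconstruct_W(E_target, R)
            base = dict(target=target.participant_id, source=f"random_{i}",
                        direction="W_from_C", tvaf_rand=t, tvaf_own=target.tvaf)
            rows.extend(_similarity_rows(base, target.W, W_rec, "W",
                                         max_lag_fraction, block_length))
    return pd.DataFrame(rows)
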