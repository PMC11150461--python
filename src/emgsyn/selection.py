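"""Choosing the number of synergies and variability summaries.

Two criteria applied jointly to a monotone tVAF curve pick the number of
synergies (NoS) per participant x task: the smallest k whose tVAF exceeds
90% AND whose next synergy adds no more than 1 percentage point.  The
study-wide count (NoSoA) is the rounded mean NoS over every participant and
task, used so cross-entity comparisons operate at equal rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .factorization import TvafCurve

__all__ = ["NosResult", "select_nos", "nosoa", "coefficient_of_variation"]


@dataclass
class NosResult:
    nos: int
    criterion1_k: int | None       # smallest k with tVAF > threshold
    criterion2_satisfied_at_nos: bool
    tvaf_at_nos: float
    participant_id: str | None = None
    task_id: str | None = None
    tvaf_at_nosoa: float | None = None   # filled once NoSoA is known
    fallback: bool = False               # no k met both criteria


def _curve_values(curve) -> tuple[np.ndarray, str | None, str | None]:
    if isinstance(curve, TvafCurve):
        return np.asarray(curve.tvaf_by_k, dtype=float), curve.participant_id, curve.task_id
    return np.asarray(curve, dtype=float), None, None


def select_nos(curve, tvaf_threshold: float = 90.0,
               increment_threshold: float = 1.0) -> NosResult:
    """Apply the dual tVAF criteria to a (monotone non-decreasing) curve.

    NoS is the smallest k with ``tvaf(k) > tvaf_threshold`` and, unless k is
    the last point of the curve, ``tvaf(k+1) - tvaf(k) <= increment_threshold``.
    If no k satisfies both, the curve's last k is returned with
    ``fallback=True``.
    """
    values, pid, tid = _curve_values(curve)
    if values.size == 0:
        raise ValueError("empty tVAF curve")
    k_last = values.size
    crit1 = next((k for k in range(1, k_last + 1)
                  if values[k - 1] > tvaf_threshold), None)
    for k in range(1, k_last + 1):
        if values[k - 1] <= tvaf_threshold:
            continue
        if k == k_last or values[k] - values[k - 1] <= increment_threshold:
            return NosResult(nos=k, criterion1_k=crit1,
                             criterion2_satisfied_at_nos=(k < k_last),
                             tvaf_at_nos=float(values[k - 1]),
                             participant_id=pid, task_id=tid)
    return NosResult(nos=k_last, criterion1_k=crit1,
                     criterion2_satisfied_at_nos=False,
                     tvaf_at_nos=float(values[-1]),
                     participant_id=pid, task_id=tid, fallback=True)


def nosoa(nos_values: Iterable) -> int:
    """Study-wide synergy count: mean NoS rounded half-up."""
    vals = [v.nos if isinstance(v, NosResult) else float(v) for v in nos_values]
    if not vals:
        raise ValueError("no NoS values given")
    return int(math.floor(np.mean(vals) + 0.5))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1) divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(arr.std(ddof=1) / mean)
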