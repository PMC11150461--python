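"""Raw EMG to concatenated, amplitude-normalized envelope matrices.

Processing chain per channel: 4th-order Butterworth band-pass 10-400 Hz
applied forward and backward (zero lag, effective order 8), demean,
full-wave rectify, 4th-order Butterworth low-pass 6 Hz (again zero lag),
clip at zero.  The analyzed phase of each trial is then time-normalized to
100 points, trials are concatenated per task, and each muscle row is
divided by its maximum over ALL tasks of the participant, so a value of 1
marks that muscle's peak activation anywhere in the session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

__all__ = [
    "EnvelopeMatrix",
    "envelope",
    "time_normalize",
    "process_trial",
    "assemble",
    "POINTS_PER_PHASE",
]

POINTS_PER_PHASE = 100


@dataclass
class EnvelopeMatrix:
    """Concatenated normalized envelopes of one participant x task."""

    E: np.ndarray                      # (muscles, trials * 100), in [0, 1]
    muscle_names: list[str]
    trial_boundaries: list[int]        # start column of each trial block
    normalization_factors: np.ndarray  # per-muscle divisor (cross-task max)
    participant_id: str | None = None
    task_id: str | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trial_boundaries)

    def trial_block(self, t: int) -> np.ndarray:
        s = self.trial_boundaries[t]
        return self.E[:, s:s + POINTS_PER_PHASE]


def _sos(order: int, cutoff, fs: float, btype: str) -> np.ndarray:
    return scipy.signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def envelope(raw: np.ndarray, sampling_rate: float, band: tuple[float, float] = (10.0, 400.0),
             order: int = 4, lowpass: float = 6.0) -> np.ndarray:
    """Linear envelope of one raw EMG channel.

    Band-pass -> demean -> full-wave rectify -> low-pass, every filter
    zero-lag (forward-backward).  Small negative excursions introduced by
    low-pass filtering the rectified signal are clipped to zero.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("envelope expects a single channel (1-D series)")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw signal contains non-finite samples")
    if sampling_rate <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz cannot represent the "
            f"{band[1]} Hz band edge")
    if sampling_rate < 850:
        warnings.warn(
            f"sampling rate {sampling_rate} Hz puts the {band[1]} Hz band edge "
            "very close to Nyquist; filter response will be distorted",
            stacklevel=2)

    sos_bp = _sos(order, band, sampling_rate, "bandpass")
    sos_lp = _sos(order, lowpass, sampling_rate, "lowpass")
    padlen = 3 * (max(sos_bp.shape[0], sos_lp.shape[0]) * 2 + 1)
    if raw.size <= padlen or raw.size <= 3 * order:
        raise ValueError(
            f"signal of {raw.size} samples is too short for stable "
            f"bidirectional filtering (needs > {padlen})")

    x = scipy.signal.sosfiltfilt(sos_bp, raw)
    x = x - x.mean()
    x = np.abs(x)
    x = scipy.signal.sosfiltfilt(sos_lp, x)
    return np.maximum(x, 0.0)


def time_normalize(series: np.ndarray, events: tuple[int, int],
                   n_points: int = POINTS_PER_PHASE) -> np.ndarray:
    """Resample the analyzed phase onto ``n_points`` uniform samples.

    Linear interpolation on a grid spanning [start, end] inclusive, so the
    first and last output samples equal the input at the event samples.
    """
    series = np.asarray(series, dtype=float)
    start, end = events
    if not (0 <= start < end <= series.size - 1):
        raise ValueError(f"events {events} outside signal of {series.size} samples")
    if end - start < 2:
        raise ValueError("analyzed phase must span at least 2 samples")
    grid = np.linspace(start, end, n_points)
    return np.interp(grid, np.arange(series.size), series)


def process_trial(signals: np.ndarray, events: tuple[int, int],
                  sampling_rate: float, **filter_kwargs) -> np.ndarray:
    """Envelope + phase time-normalization for all channels of one trial."""
    signals = np.asarray(signals, dtype=float)
    return np.vstack([
        time_normalize(envelope(ch, sampling_rate, **filter_kwargs), events)
        for ch in signals
    ])


def assemble(trials_by_task: dict[str, list[np.ndarray]],
             muscle_names: list[str],
             participant_id: str | None = None) -> dict[str, EnvelopeMatrix]:
    """Concatenate trials per task and amplitude-normalize across tasks.

    ``trials_by_task`` maps task id -> list of (muscles x 100) processed
    envelopes for ONE participant.  Each muscle row is divided by that
    muscle's maximum over every trial of every task, so the global maximum
    of each muscle across the returned matrices is exactly 1 (a single
    task's matrix may peak below 1).
    """
    if not trials_by_task:
        raise ValueError("no tasks given")
    m = len(muscle_names)
    for task, trials in trials_by_task.items():
        if not trials:
            raise ValueError(f"task {task!r} has no trials")
        for arr in trials:
            if arr.shape[0] != m:
                raise ValueError(
                    f"task {task!r}: trial has {arr.shape[0]} muscles, "
                    f"expected {m}")
            if np.any(arr < 0):
                raise ValueError(f"task {task!r}: negative envelope values")

    stacked = {task: np.hstack(trials) for task, trials in trials_by_task.items()}
    factors = np.max(np.column_stack([E.max(axis=1) for E in stacked.values()]),
                     axis=1)
    zero = np.flatnonzero(factors == 0)
    if zero.size:
        names = ", ".join(muscle_names[i] for i in zero)
        raise ValueError(
            f"muscle(s) {names} are all-zero across every task; amplitude "
            "normalization is undefined")

    out: dict[str, EnvelopeMatrix] = {}
    for task, E in stacked.items():
        n_trials = len(trials_by_task[task])
        out[task] = EnvelopeMatrix(
            E=E / factors[:, None],
            muscle_names=list(muscle_names),
            trial_boundaries=[POINTS_PER_PHASE * t for t in range(n_trials)],
            normalization_factors=factors.copy(),
            participant_id=participant_id,
            task_id=task,
        )
    return out
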