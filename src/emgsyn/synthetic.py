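"""Synthetic raw-EMG generator with known synergy structure.

Emulates the study design the pipeline targets: 7 participants x 3 tasks x
6 trials of 16-channel surface EMG at 1000 Hz, with an analyzed movement
phase per trial.  Every dataset is built from known ground truth:

* per-task synergy-vector templates (muscles x k, column max 1), some of
  which are declared shared across tasks and therefore reuse the identical
  template column;
* per-participant variants of those templates (multiplicative perturbation,
  renormalized), giving tunable inter-participant similarity;
* burst-like activation coefficients (sums of Gaussian bursts on the
  100-point phase) with per-trial timing jitter and amplitude variation;
* raw signals synthesized as band-limited white-noise carriers (20-380 Hz)
  amplitude-modulated by the intended envelope upsampled to the analyzed
  window, so the band-pass/rectify/low-pass preprocessing stage has
  realistic work to do.

Everything is driven by one integer seed and is bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "RawTrial",
    "generate_dataset",
    "write_dataset",
    "expected_weight_matrix",
    "MUSCLE_NAMES_16",
]

# SENIAM-style lower-limb montage, front (f) then back (b) leg
_BASE_MUSCLES = ["vast_lat", "sem_tend", "gastr_lat", "glut_med",
                 "soleus", "tib_ant", "bic_fem", "rect_fem"]
MUSCLE_NAMES_16 = [f"{m}_f" for m in _BASE_MUSCLES] + [f"{m}_b" for m in _BASE_MUSCLES]


@dataclass
class GeneratorConfig:
    """Study-design knobs of the generator (defaults mirror the emulated study)."""

    participants: int = 7
    tasks: int = 3
    trials_per_task: int = 6
    muscles: int = 16
    k_per_task: int = 4              # true synergies per task
    n_shared_all: int = 1            # synergies shared across ALL tasks
    participant_variation: float = 0.25   # SD of multiplicative weight perturbation
    envelope_noise_sd: float = 0.05       # additive, fraction of trial peak
    timing_jitter_sd: float = 0.0         # burst-center jitter, % of phase
    trial_amplitude_sd: float = 0.1       # per-trial burst-amplitude variation
    sampling_rate: float = 1000.0
    trial_samples: int = 1400
    events: tuple[int, int] = (200, 1200)
    baseline_level: float = 0.02          # resting modulation floor
    phase_points: int = 100
    task_names: tuple[str, ...] | None = None
    seed: int = 0

    def resolved_task_names(self) -> list[str]:
        if self.task_names is not None:
            return list(self.task_names)
        return [f"task{t + 1}" for t in range(self.tasks)]

    def validate(self) -> None:
        for name in ("participants", "tasks", "trials_per_task", "muscles",
                     "k_per_task", "trials_per_task"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_shared_all <= self.k_per_task:
            raise ValueError("n_shared_all must lie in [0, k_per_task]")
        for name in ("participant_variation", "envelope_noise_sd",
                     "timing_jitter_sd", "trial_amplitude_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        s, e = self.events
        if not 0 <= s < e <= self.trial_samples:
            raise ValueError(f"events {self.events} outside trial of "
                             f"{self.trial_samples} samples")


@dataclass
class RawTrial:
    participant_id: str
    task_id: str
    trial_id: int
    signals: np.ndarray              # (muscles, trial_samples)
    sampling_rate: float
    events: tuple[int, int]


@dataclass
class GroundTruth:
    """The generator's hidden state, for recovery scoring."""

    config: GeneratorConfig
    seed: int
    muscle_names: list[str]
    shared_map: dict[int, list[str]]                       # synergy idx -> tasks sharing it
    W_true: dict[tuple[str, str], np.ndarray]              # (pid, task) -> (m, k)
    C_true: dict[tuple[str, str, int], np.ndarray] = field(repr=False, default_factory=dict)
    intended_envelopes: dict[tuple[str, str, int], np.ndarray] = field(repr=False, default_factory=dict)

    def participants(self) -> list[str]:
        return sorted({p for p, _ in self.W_true})

    def tasks(self) -> list[str]:
        return self.config.resolved_task_names()


def _draw_template(rng: np.random.Generator, m: int) -> np.ndarray:
    """One synergy-vector template: a few dominant muscles over a weak floor."""
    w = rng.uniform(0.0, 0.15, m)
    dom = rng.choice(m, size=rng.integers(3, 5), replace=False)
    w[dom] = rng.uniform(0.6, 1.0, dom.size)
    return w / w.max()


def _task_templates(rng: np.random.Generator, cfg: GeneratorConfig
                    ) -> tuple[list[np.ndarray], dict[int, list[str]]]:
    """Study-level templates per task with declared sharing.

    Synergy indices 0..n_shared_all-1 reuse one template column across all
    tasks; the rest are task-specific.  Task-specific templates are
    redrawn (up to a cap) until every undeclared cross/within-task pair is
    well below the sharing threshold, so the declared structure is the only
    structure present.
    """
    m, k = cfg.muscles, cfg.k_per_task
    shared = [_draw_template(rng, m) for _ in range(cfg.n_shared_all)]
    templates = []
    for _ in range(cfg.tasks):
        W = np.empty((m, k))
        for j in range(cfg.n_shared_all):
            W[:, j] = shared[j]
        templates.append(W)

    def corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    existing = list(shared)
    for W in templates:
        for j in range(cfg.n_shared_all, k):
            for _ in range(200):
                cand = _draw_template(rng, m)
                if all(corr(cand, e) < 0.35 for e in existing):
                    break
            W[:, j] = cand
            existing.append(cand)
        # every recorded muscle participates meaningfully in >= 1 synergy
        # (a montage records movement-relevant muscles; near-silent rows
        # would be carrier-noise-dominated and unrecoverable by design);
        # boosts go into task-specific columns so declared sharing stays
        # bitwise exact across tasks
        if k > cfg.n_shared_all:
            quiet = np.flatnonzero(W.max(axis=1) < 0.3)
            for i in quiet:
                W[i, rng.integers(cfg.n_shared_all, k)] = rng.uniform(0.3, 0.6)
    task_names = cfg.resolved_task_names()
    shared_map = {j: list(task_names) for j in range(cfg.n_shared_all)}
    return templates, shared_map


def _burst_profiles(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """Per-task burst parameters (center %, width, amplitude) per synergy.

    The shared synergies burst early (first third of the phase, the 'jump'
    role); task-specific ones are spread over the remainder.
    """
    k = cfg.k_per_task
    n_spec = k - cfg.n_shared_all
    spec_centers = np.linspace(45, 88, n_spec) if n_spec else np.empty(0)
    shared_centers = (np.linspace(16, 30, cfg.n_shared_all)
                      if cfg.n_shared_all else np.empty(0))
    params = np.empty((k, 3))
    for j in range(k):
        if j < cfg.n_shared_all:
            center = shared_centers[j] + rng.uniform(-2, 2)
        else:
            center = spec_centers[j - cfg.n_shared_all] + rng.uniform(-3, 3)
        params[j] = (center, rng.uniform(4.0, 5.5), rng.uniform(0.8, 1.2))
    return params


def _activation(params: np.ndarray, rng: np.random.Generator,
                cfg: GeneratorConfig) -> np.ndarray:
    """One trial's activation coefficients from the burst profiles.

    Gaussian bursts with tails truncated to exact zero below 2% of the
    burst amplitude: real activation bursts switch off between subtasks,
    and the resulting anchor windows (times where a single synergy is
    active) make the ground-truth factors identifiable.
    """
    t = np.arange(cfg.phase_points)
    C = np.empty((params.shape[0], cfg.phase_points))
    for j, (center, width, amp) in enumerate(params):
        c = center + rng.normal(0, cfg.timing_jitter_sd)
        a = amp * max(1.0 + rng.normal(0, cfg.trial_amplitude_sd), 0.05)
        burst = a * np.exp(-0.5 * ((t - c) / width) ** 2)
        burst[burst < 0.02 * a] = 0.0
        C[j] = burst
    return C


def _carrier(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance zero-mean band-limited (20-380 Hz) noise carrier."""
    sos = scipy.signal.butter(4, (20.0, min(380.0, 0.45 * fs)), btype="bandpass",
                              fs=fs, output="sos")
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    x -= x.mean()
    return x / x.std()


def generate_dataset(config: GeneratorConfig | None = None,
                     seed: int | None = None
                     ) -> tuple[list[RawTrial], GroundTruth]:
    """Generate a full synthetic study.

    Deterministic for a fixed ``seed`` (defaults to ``config.seed``).
    Each trial's analyzed segment, once envelope-processed, approximates
    ``W_true @ C_true`` for that trial up to a common modulation constant.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    if cfg.muscles == 16:
        muscle_names = MUSCLE_NAMES_16
    else:
        muscle_names = [f"muscle_{i + 1:02d}" for i in range(cfg.muscles)]

    rng_design = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    templates, shared_map = _task_templates(rng_design, cfg)
    bursts = [_burst_profiles(rng_design, cfg) for _ in range(cfg.tasks)]
    # shared synergies keep one burst profile across tasks (same subtask)
    for t in range(1, cfg.tasks):
        bursts[t][: cfg.n_shared_all] = bursts[0][: cfg.n_shared_all]

    task_names = cfg.resolved_task_names()
    gt = GroundTruth(config=cfg, seed=seed, muscle_names=list(muscle_names),
                     shared_map=shared_map, W_true={})
    trials: list[RawTrial] = []
    start, end = cfg.events
    win = end - start

    for p in range(cfg.participants):
        pid = f"P{p + 1:02d}"
        rng_p = np.random.default_rng(np.random.SeedSequence([seed, 1000 + p]))
        # participant-specific weight perturbation, coherent across tasks
        # for shared synergies (the perturbed shared column is reused)
        pert_shared = None
        for t, task in enumerate(task_names):
            W = templates[t].copy()
            for j in range(W.shape[1]):
                if j < cfg.n_shared_all:
                    if pert_shared is None:
                        pert_shared = []
                    if len(pert_shared) <= j:
                        factor = np.clip(
                            1.0 + rng_p.normal(0, cfg.participant_variation,
                                               cfg.muscles), 0.05, None)
                        pert_shared.append(factor)
                    factor = pert_shared[j]
                else:
                    factor = np.clip(
                        1.0 + rng_p.normal(0, cfg.participant_variation,
                                           cfg.muscles), 0.05, None)
                col = W[:, j] * factor
                W[:, j] = col / col.max()
            gt.W_true[(pid, task)] = W
            for tr in range(cfg.trials_per_task):
                rng_t = np.random.default_rng(
                    np.random.SeedSequence([seed, p, t, tr]))
                C = _activation(bursts[t], rng_t, cfg)
                E = W @ C                                      # (m, 100)
                gt.C_true[(pid, task, tr)] = C
                gt.intended_envelopes[(pid, task, tr)] = E
                peak = E.max()
                if cfg.envelope_noise_sd > 0 and peak > 0:
                    E = np.maximum(
                        E + rng_t.normal(0, cfg.envelope_noise_sd * peak,
                                         E.shape), 0.0)
                # upsample envelope onto the analyzed window
                grid = np.linspace(0, cfg.phase_points - 1, win)
                sig = np.empty((cfg.muscles, cfg.trial_samples))
                for i in range(cfg.muscles):
                    amp = np.full(cfg.trial_samples,
                                  cfg.baseline_level * max(peak, 1e-12))
                    amp[start:end] += np.interp(
                        grid, np.arange(cfg.phase_points), E[i])
                    sig[i] = _carrier(rng_t, cfg.trial_samples,
                                      cfg.sampling_rate) * amp
                trials.append(RawTrial(pid, task, tr, sig,
                                       cfg.sampling_rate, cfg.events))
    return trials, gt


def expected_weight_matrix(gt: GroundTruth, pid: str, task: str) -> np.ndarray:
    """Ground-truth W on the scale the pipeline actually recovers.

    Amplitude normalization divides each muscle row of the envelope by its
    cross-task maximum, which rescales the rows of the effective weight
    matrix; this applies the same row scaling to ``W_true`` and re-imposes
    the column-max-1 convention, making it directly comparable with a
    decomposition of the preprocessed data.
    """
    maxima = np.zeros(gt.config.muscles)
    for (p, _t, _tr), E in gt.intended_envelopes.items():
        if p == pid:
            maxima = np.maximum(maxima, E.max(axis=1))
    if np.any(maxima == 0):
        raise ValueError("a muscle is silent in every intended envelope")
    W = gt.W_true[(pid, task)] / maxima[:, None]
    return W / W.max(axis=0)


# ---------------------------------------------------------------------------
# on-disk layout: one delimited-text file per trial + JSON manifest


def write_dataset(trials: list[RawTrial], gt: GroundTruth, outdir: str | Path,
                  delimiter: str = "\t") -> Path:
    """Write trials as per-trial TSV (header = muscle names) + manifest.json.

    Ground truth is serialized alongside as ground_truth.json.  Returns the
    manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in trials:
        fname = f"{tr.participant_id}_{tr.task_id}_trial{tr.trial_id + 1}.tsv"
        header = delimiter.join(gt.muscle_names)
        np.savetxt(outdir / fname, tr.signals.T, delimiter=delimiter,
                   header=header, comments="", fmt="%.6e")
        entries.append(dict(participant=tr.participant_id, task=tr.task_id,
                            trial=tr.trial_id, path=fname,
                            events=list(tr.events)))
    manifest = dict(sampling_rate=gt.config.sampling_rate,
                    muscles=gt.muscle_names, trials=entries)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))

    gt_json = dict(
        seed=gt.seed,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(gt.config).items()},
        shared_map={str(k): v for k, v in gt.shared_map.items()},
        W_true={f"{p}|{t}": W.tolist() for (p, t), W in gt.W_true.items()},
        C_true={f"{p}|{t}|{tr}": C.tolist()
                for (p, t, tr), C in gt.C_true.items()},
    )
    (outdir / "ground_truth.json").write_text(json.dumps(gt_json))
    return manifest_path
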