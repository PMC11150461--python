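import numpy as np
import pytest

from emgsyn.io import PipelineConfig
from emgsyn.pipeline import preprocess_dataset
from emgsyn.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def noiseless_study():
    """One participant, 3 tasks, 6 trials, no noise/jitter: ground truth is
    recoverable, so downstream stages can be scored exactly."""
    cfg = GeneratorConfig(participants=1, tasks=3, trials_per_task=6,
                          envelope_noise_sd=0.0, timing_jitter_sd=0.0,
                          trial_amplitude_sd=0.0, seed=11)
    trials, gt = generate_dataset(cfg)
    envelopes = preprocess_dataset(trials, gt.muscle_names, PipelineConfig())
    return trials, gt, envelopes


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants, 2 tasks, moderate noise: exercises multi-participant
    alignment and reconstruction at realistic (scaled-down) conditions."""
    cfg = GeneratorConfig(participants=3, tasks=2, trials_per_task=4,
                          envelope_noise_sd=0.05, participant_variation=0.15,
                          seed=21)
    trials, gt = generate_dataset(cfg)
    envelopes = preprocess_dataset(trials, gt.muscle_names, PipelineConfig())
    return trials, gt, envelopes


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
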