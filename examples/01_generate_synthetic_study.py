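"""Generate a synthetic EMG study with known synergy structure.

Builds a small cohort (2 participants x 3 tasks x 3 trials, 16 muscles)
whose envelopes arise from 4 true synergies per task, one of which is
shared across all tasks, and writes it as per-trial TSV files plus a JSON
manifest.  The printed summary shows what downstream stages will try to
recover.
"""

from emgsyn.synthetic import GeneratorConfig, generate_dataset, write_dataset

cfg = GeneratorConfig(participants=2, tasks=3, trials_per_task=3,
                      k_per_task=4, n_shared_all=1, envelope_noise_sd=0.05,
                      seed=42)
trials, gt = generate_dataset(cfg)
manifest = write_dataset(trials, gt, "scratch_example_data")

print(f"trials written: {len(trials)} (manifest: {manifest})")
print(f"muscles: {', '.join(gt.muscle_names[:4])}, ... ({len(gt.muscle_names)} total)")
print(f"true synergies per task: {cfg.k_per_task}")
print(f"shared across all tasks: synergy indices {sorted(gt.shared_map)}")
W = gt.W_true[("P01", "task1")]
print(f"ground-truth W for P01/task1: shape {W.shape}, column maxima {W.max(axis=0)}")
# Each trial file holds 16 columns of raw-EMG-like signal at 1000 Hz; the
# events in the manifest mark the analyzed movement phase of each trial.
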