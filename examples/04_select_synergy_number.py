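"""Choose the number of synergies with the dual tVAF criteria.

Computes the tVAF curve for k = 1..8, applies the two selection rules
(tVAF > 90% and next-synergy increment <= 1 point) and summarizes the
variability of the selected counts.
"""

import numpy as np

from emgsyn.factorization import tvaf_curve
from emgsyn.io import PipelineConfig
from emgsyn.pipeline import preprocess_dataset
from emgsyn.selection import coefficient_of_variation, nosoa, select_nos
from emgsyn.synthetic import GeneratorConfig, generate_dataset

cfg = GeneratorConfig(participants=3, tasks=1, trials_per_task=4,
                      envelope_noise_sd=0.05, seed=12)
trials, gt = generate_dataset(cfg)
envelopes = preprocess_dataset(trials, gt.muscle_names, PipelineConfig())

results = []
for pid in sorted(envelopes):
    curve = tvaf_curve(envelopes[pid]["task1"].E, restarts=4, seed=0,
                       k_max=8, max_iter=250, tol=1e-5)
    res = select_nos(curve)
    results.append(res)
    print(f"{pid}: tVAF(k) = {np.round(curve.tvaf_by_k, 1)}")
    print(f"     -> NoS = {res.nos} (tVAF at NoS {res.tvaf_at_nos:.2f}%)")

counts = [r.nos for r in results]
print(f"NoSoA (rounded mean of all NoS): {nosoa(results)}")
print(f"CoV of NoS across participants: "
      f"{coefficient_of_variation(counts):.2f}")
# the generator used 4 true synergies per task, so NoS should settle at 4
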