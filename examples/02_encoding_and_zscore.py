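"""Fit and score encoding models on one simulated participant.

Voxels are generated from a versatile (basis-function) probability code at
10% signal; the matched model should score a clearly positive z-R2, while
a confidence model on the same data should score near zero.
"""

import warnings

import numpy as np

import probcode as pc

warnings.filterwarnings("ignore")

exp = pc.simulate_experiment(n_voxels=8, seed=3)
task, obs = exp.task_config, exp.observer_config

for model_class, estimate in [("versatile", "probability"),
                              ("linear", "probability"),
                              ("versatile", "confidence")]:
    spec = pc.EncodingSpec.default(model_class, estimate)
    score = pc.evaluate_encoding(exp.sessions, spec, task, obs,
                                 rng=np.random.default_rng(0))
    print(f"{spec.label:25s} mean z-R2 = {np.nanmean(score.z_r2):6.2f}")

print("\nThe generative code is versatile-probability: the matched model "
      "wins, the linear\nmodel captures only the monotone part, and the "
      "confidence model stays near chance.")
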