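"""Generate one task session and run the ideal observer on it.

The hidden probability of stimulus A follows a change-point process
(hazard 1/75 on [0.1, 0.9]); the observer tracks it with a grid posterior
and reads out a probability estimate (posterior mean) and a confidence
(-log posterior SD).
"""

import numpy as np

import probcode as pc

task = pc.TaskConfig()
seq = pc.generate_sequence(task, seed=42)
obs = pc.ObserverConfig.default(task.p_support, hazard=task.hazard)
trace, est = pc.run_ideal_observer(seq, obs)

print(f"session: {seq.n_trials} stimuli, {seq.change_points.size} change "
      f"points, {seq.report_trials.size} report periods, "
      f"{seq.duration / 60:.1f} min")
err = np.abs(est.p_hat - seq.hidden_p).mean()
print(f"mean |p_hat - hidden p| = {err:.3f} "
      "(tracking error of the optimal estimate)")
print(f"confidence range: [{est.confidence.min():.2f}, "
      f"{est.confidence.max():.2f}] (log-precision units; the encoding "
      "domain is [1.1, 2.6])")
print(f"mean surprise = {est.surprise.mean():.3f} nats; a perfectly "
      "predictable stream would approach 0")
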