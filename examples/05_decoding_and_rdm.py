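"""Decode probability bins from voxel patterns and classify the code's
geometry from its representational dissimilarity matrix (RDM).

Two synthetic participants: one with a monotone code (graded RDM expected)
and one with a bump code (identity RDM expected), both at 10% signal.
"""

import warnings

import numpy as np

import probcode as pc
from probcode.simulate import generate_participant_sessions

warnings.filterwarnings("ignore")

task = pc.TaskConfig()
obs = pc.ObserverConfig.default(task.p_support, hazard=task.hazard)
rng = np.random.default_rng(11)
spec5 = pc.EncodingSpec.default("versatile", "probability", K=5)

for code in ("monotone", "bump"):
    sessions = generate_participant_sessions(task, obs, rng)
    d = pc.build_design_matrix(sessions, spec5)
    if code == "monotone":
        W = np.column_stack([pc.draw_monotone_weights(spec5.basis, rng)
                             for _ in range(30)])
    else:
        W = np.column_stack([pc.draw_bump_weights(5, rng) for _ in range(30)])
    sig = d.X[:, d.interest_mask] @ W
    Y = sig + rng.normal(size=sig.shape) * np.sqrt(9 * sig.var(axis=0))
    for i, s in enumerate(sessions):
        s.y = Y[d.session_rows(i)]
    res = pc.decode_participant(sessions, "probability", task_config=task,
                                observer_config=obs, rng=rng)
    reg = res.regression
    print(f"{code:9s} code: accuracy = {res.accuracy:.2f} (chance 0.2), "
          f"coef_identity = {reg.coef_identity:.3f}, "
          f"coef_graded = {reg.coef_graded:.3f} -> winner: {reg.winner}")

print("\nAccuracy above 0.2 means the 5-bin patterns are informative; the "
      "winning model RDM\nclassifies the code as non-monotonic (identity) "
      "or monotonic (graded).")
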