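"""Miniature model-recovery simulation (generative x fitted z-R2 matrix).

Full desk scale is 10 experiments x 20 voxels (see the recovery CLI:
``probcode recover --n-experiments 10 --n-voxels 20 --seed 0 --out DIR``);
this example runs 3 x 6 to stay quick.
"""

import warnings

import numpy as np

import probcode as pc

warnings.filterwarnings("ignore")

r = pc.model_recovery_matrix(n_experiments=3, n_voxels=6, seed=0)
print("mean z-R2 (rows: generative, cols: fitted)")
width = max(len(s) for s in r.fit_labels)
print(" " * (width + 2) + "  ".join(f"{s:>{width}}" for s in r.fit_labels))
for g, row in zip(r.gen_labels, r.mean_z_r2):
    print(f"{g:>{width}}  " + "  ".join(f"{v:>{width}.2f}" for v in row))
print("\nfraction of experiments each fitted model scored best:")
for g, row in zip(r.gen_labels, r.frac_best):
    print(f"{g:>{width}}  " + "  ".join(f"{v:>{width}.2f}" for v in row))
print("\nDiagonal dominance = the generative model is recovered; linear "
      "fits fail on\nversatile data, and probability/confidence stay "
      "separated.")
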