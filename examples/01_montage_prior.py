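"""Electrode geometry and the inverse-distance adjacency prior.

Loads the packaged 64-channel 10-10 montage, builds the prior E and prints
a few entries showing that nearby electrode pairs get large weights.
"""

import numpy as np

import mignet as mg

layout = mg.load_builtin_montage(64)
prior = mg.build_prior_adjacency(layout)

print(f"{layout.n_channels} electrodes; first five: {layout.names[:5]}")
for a, b in [("C3", "C1"), ("C3", "CZ"), ("C3", "C4"), ("FP1", "OZ")]:
    i, j = layout.index(a), layout.index(b)
    print(f"dist({a},{b}) = {layout.distance(a, b):.3f}   E = {prior.E[i, j]:.3f}")

off = prior.E[~np.eye(64, dtype=bool)]
print(f"E entries: max {off.max():.3f} (closest pair), min {off.min():.3f} (farthest pair)")
# Large E marks neighbouring electrodes (C3-C1); distant pairs (FP1-OZ)
# start weakly connected and can only get weaker during training.
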