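"""Watch the electrode graph evolve during training and export snapshots.

Each adjacency update multiplies the geometric prior E elementwise by the
learned feature-similarity K^gamma, so edges between electrodes whose
features diverge are weakened. Snapshots are written as CSV matrices plus
BrainNet-Viewer .node/.edge text files for scalp rendering.
"""

from pathlib import Path

import numpy as np

import mignet as mg
from mignet.training import TrainConfig, train
from mignet.viz import export_adjacency_series

layout = mg.load_builtin_montage(64)
trials = mg.generate_dataset(
    mg.SyntheticConfig(trials_per_class=4, snr_db=10.0, seed=2), layout)
segs = mg.window_trials(trials)

model = mg.MotorImageryDecoder(layout, seed=0, dtype=np.float32)
train(model, segs, TrainConfig(epochs=4, update_period=1, seed=0))

E = model.adjacency.E
support = E > 0
for i, P in enumerate(model.adjacency.history, start=1):
    ratio = P[support] / E[support]
    print(f"update {i}: mean P/E {ratio.mean():.4f} "
          f"(min {ratio.min():.4f}); max violation of P<=E: "
          f"{np.max(P - E):.2e}")

out = Path("scratch_adjacency")
files = export_adjacency_series(model.adjacency.history, layout,
                                indices=[1, len(model.adjacency.history)],
                                out_dir=out, threshold_pct=90)
print(f"exported {len(files)} files to {out}/ (open .node/.edge in BrainNet Viewer)")
# P/E <= 1 always: updates can only shrink prior edges. At this desk scale
# the epoch-mean node features stay close together so shrinkage is mild;
# longer training differentiates nodes and prunes more aggressively.
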