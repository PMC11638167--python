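# mignet

Decoding four-class motor imagery (left fist, right fist, both fists, both
feet) from 64-channel EEG, for brain-computer-interface researchers who
want a graph-based decoder whose electrode connectivity is interpretable
rather than a black box.

## The model

A windowed EEG segment `x ∈ ℝ^{C×T}` (C = 64 electrodes, T = 160 samples
at 160 Hz) passes through two stages:

**Multi-scale frequency features.** Three stacks of three 1-D temporal
convolutions with kernel sizes k ∈ {3, 7, 15} and depth 3 run along the
time axis of each electrode independently (weights shared across
electrodes, same padding, residual from layer 1 to layer 3's
pre-activation):

    H_j^l   = σ(H_j^{l-1} * W_j^l + b_j^l),      H_j^{3'} = σ(preact_3 + H_j^1)

The per-scale outputs are concatenated (`X_conv ∈ ℝ^{C×T×9}`) and fused by
an attention pool: a shared MLP maps each (c, t) feature vector to logits,
a softmax over the feature axis gives convex weights W_att, and

    X_MFF[c,t] = Σ_f W_att[c,t,f] · X_conv[c,t,f]   ∈ ℝ^{C×T}.

**Dynamic graph attention.** Electrodes are graph nodes; X_MFF's rows are
the initial node features. The adjacency starts at the geometric prior

    E_uv = 1 / dist(u, v)   (normalized to max 1, zero diagonal)

built from packaged 10-10 montage coordinates. Three multi-head (Q = 4)
graph attention layers propagate features, with log P_uv added to the
attention logits so the current adjacency gates each edge. Every 10
training epochs (configurable) the adjacency is refreshed from the
epoch-mean layer-3 node features G³:

    K_uv = ξ / (‖G_u³ − G_v³‖₂^δ + ξ),        P_uv = E_uv · K_uv^γ

with γ = 1, δ = 2, ξ = 0.5 by default. Since 0 < K ≤ 1, updates can only
shrink prior edges — `0 ≤ P ≤ E` always, and no edge absent from the
geometry can appear. A linear softmax head over the flattened final node
features yields class probabilities; training is Adam (lr 0.01, weight
decay 1e-4) on cross-entropy.

The package also ships the evaluation protocol (stratified 8:2 trial
split *before* sliding-window segmentation, 160-sample windows with
stride 20, five random repeats; within- and cross-subject variants), a
synthetic MI-EEG generator with a controllable SNR dial, a PhysioNet EDF
loading path, and interpretability exports (t-SNE + silhouette per stage,
BrainNet-Viewer adjacency snapshots). The network is implemented on
numpy with reverse-mode `autograd`.

## Worked example

```bash
python examples/03_train_and_decode.py
```

trains on a small synthetic subject (32 trials, SNR +10 dB) and prints:

```
24 train / 8 test trials -> 600 / 200 segments
epoch 1: loss 9.767, train accuracy 0.262
epoch 2: loss 4.938, train accuracy 0.433
epoch 3: loss 3.053, train accuracy 0.367
epoch 4: loss 1.103, train accuracy 0.552
epoch 5: loss 0.545, train accuracy 0.698
epoch 6: loss 0.436, train accuracy 0.773
held-out segment accuracy: 0.665 (chance 0.250)
adjacency updates applied: 3
```

Held-out accuracy far above the 25% four-class chance level means the
decoder recovered the class-specific rhythms and scalp topographies from
the data; the adjacency matrix was refreshed three times (every 2 epochs
here).
`examples/` contains one script per capability: montage/prior, synthetic
data, training, adjacency evolution, t-SNE stage comparison.

A thin CLI mirrors the library: `mignet synth | prepare | train |
eval-within | eval-cross | viz-tsne | viz-adj` (see `mignet --help`);
all hyperparameters are settable by YAML config with CLI override, and
segment archives are plain NPZ files (`data [N×C×T]`, `labels`,
`subject`, `trial`, `window`).

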