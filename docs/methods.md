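# Methods

## Model

The decoder maps a windowed EEG segment (64 channels × 160 samples, 1 s at
160 Hz) to one of four motor-imagery classes. It assumes (i) the
class-discriminative information lives in band-limited oscillatory power
over sensorimotor electrodes, and (ii) the spatial covariation of those
rhythms across electrodes carries additional class information that a
graph over the electrode layout can exploit.

**Multi-scale temporal convolutions.** Each of three scales is a 3-layer
stack of 1-D convolutions along time with kernel sizes 3, 7, 15 samples
and depth 3 per layer. At 160 Hz these kernel lengths give the layers
receptive fields sensitive to progressively slower structure, so the three
stacks behave as learned filter banks over overlapping frequency ranges.
Weights are shared across electrodes and no convolution mixes electrodes:
the stage is exactly equivariant to electrode permutation, which the graph
stage relies on. Same padding preserves the 160-sample length; the first
layer's output is added to the third layer's pre-activation (residual),
and the activation σ is ELU throughout (the activation is configurable;
ELU was chosen as a smooth default and tests do not depend on the choice).

**Attention pooling.** The per-scale outputs concatenate to a 9-dim
feature vector at every (electrode, time) position. A shared 2-layer MLP
(9 → 16 → 9) produces logits that a softmax over the *feature* axis turns
into convex weights; the pooled map is the weighted average of the 9
features. A softmax over a singleton axis would be identically 1 and
could not weight anything, so the weights are per-feature by
construction. The weights are returned for inspection.

**Graph attention with a dynamic adjacency.** Electrodes are nodes; the
pooled 160-sample rows are initial node features. The adjacency prior is
E_uv = 1/dist(u, v) on packaged unit-sphere 10-10 coordinates, rescaled so
its largest off-diagonal entry is 1; the diagonal is 0 (self-influence
enters through explicit self-loops instead, avoiding the 1/0 singularity).
Normalization keeps the γ-exponentiated products on a stable scale; only
relative distances matter. Three graph-attention layers with Q = 4 heads
and hidden width 32 follow. Per head, edge logits are
LeakyReLU(a_src·Wh_u + a_dst·Wh_v) (slope 0.2) plus an additive bias
log P_uv (0 on the self-loop); softmax over each node's neighborhood
N(u) = {v : P_uv > 0} ∪ {u} yields attention that the adjacency gates
smoothly: P_uv → 0 removes the edge, and absent prior edges are masked
out entirely. Head outputs pass σ, concatenate, and project (W_O).

**Adjacency update.** Every `update_period` epochs (default 10) the
layer-3 node embeddings, averaged over all training segments of the
just-finished epoch, define a similarity K_uv = ξ/(‖G_u³−G_v³‖₂^δ + ξ)
∈ (0, 1] and the adjacency is reassigned P = E ∘ K^γ (γ = 1, δ = 2,
ξ = 0.5). The epoch-mean statistic (rather than a single batch) keeps P
from jumping with batch noise. Two invariants hold by construction and
are asserted after every update: 0 ≤ P ≤ E elementwise, and
supp(P) ⊆ supp(E) — geometry decides which edges are possible, data
decides which survive. Each update is snapshotted for the visualization
exports.

**Classifier and training.** The final node features flatten into one
linear layer + softmax. Training is Adam on cross-entropy, learning rate
0.01, with the L2-coupled weight-decay variant (decay 1e-4 added to the
gradient); an optional per-epoch learning-rate decay schedule using the
same constant is available behind a flag for users who prefer that
reading of "learning-rate decay". Default schedule is 800 epochs with
batch size 64; seeded shuffling makes runs bit-reproducible. Gradients
come from reverse-mode `autograd` over a functional parameter tree; the
convolution, ELU/LeakyReLU and softmax/attention-pool operations are
fused primitives with hand-written vector-Jacobian products (validated
against finite differences in the test suite at rtol 1e-4, and the whole
network against loop-based reference implementations at 1e-6). Model
parameters default to float64; training utilities use float32, which
roughly halves CPU time without affecting any tested property.

## Data protocol

Trials are 4 s (640 samples); windowing uses 160-sample windows with
stride 20, i.e. floor((640−160)/20)+1 = 25 windows per trial and 2,100
windows for an 84-trial subject. Train/test splits are stratified by
class at the trial level and performed **before** windowing — overlapping
windows of a single trial would otherwise leak across the split. The
train share is floor(0.8·n) per class, remainder to test. Within-subject
evaluation repeats split→window→train→test five times with derived seeds
and reports the mean per-segment accuracy (a trial-level majority-vote
accuracy is reported alongside as a clearly-labeled supplementary
metric). Cross-subject evaluation draws disjoint random subject sets (20
train / 5 test by default) per repeat.

The PhysioNet loading path reads EDF+ with mne, checks the 160 Hz rate,
reorders channels to the canonical montage order, cuts 4-s trials at T1/T2
annotation onsets, and maps runs 4/8/12 → left/right fist and 6/10/14 →
both fists/both feet (T0 rest and executed-movement runs are ignored);
subjects 88, 89, 92, 100, 104 are excluded by default for known recording
defects. The recordings are distributed already band-pass filtered to
1–35 Hz, so the loader does not filter again; a zero-phase order-4
Butterworth 1–35 Hz filter is available for raw custom inputs. Published
trial counts for this dataset are inconsistent (84 trials and 2,100
fragments per subject only reconcile as 84 trials per *subject*); the
package follows the 2,100-fragment arithmetic.

## Synthetic data

The generator emulates the recording protocol: per trial, 1/f^0.7-shaped
background noise per channel plus a class-specific band-limited
oscillation (3 random-phase sinusoids) whose amplitude falls off over the
scalp as a Gaussian (σ = 0.5 sphere units) around a class focus electrode
— C4 / C3 / CZ / FCZ for left fist / right fist / both fists / both feet,
matching the motor homunculus — with bands (8–12, 8–12, 15–22, 25–32 Hz);
the two fist classes share the mu band and are distinguished by
topography, the bimanual classes by band. `snr_db` sets the ratio of
total oscillation power to total background power. Cross-subject
variability is log-normal channel gains (σ = 0.2) and a per-subject
center-frequency jitter (σ = 1 Hz); electrode positions never move. This
is an additive event-related-synchronization proxy: it does *not* model
ERD power suppression, artifacts (blinks, EMG), volume-conduction mixing
beyond the Gaussian falloff, or non-stationarity within a trial. Passing
tests on this generator therefore demonstrate that the pipeline learns
band/topography structure under realistic noise — not that it reaches any
particular accuracy on real recordings.

The separability score used to validate the SNR dial is an ANOVA-style
variance-ratio excess, max(F − 1, 0) with
F = [tr S_b/(K−1)]/[tr S_w/(N−K)] over per-trial log band-power features:
~0 for identically distributed classes at any sample size, increasing in
SNR. It saturates once classes separate completely (around 0 dB for the
default bands), so monotonicity is only meaningful — and is only asserted
— in the responsive regime below that.

## Numerical and testing choices

Attention softmaxes use the max-subtraction stabilization; masked
(absent) edges get −∞ logits and exactly zero attention; log P uses a
1e-12 floor. Coincident electrodes make E undefined and raise an error
naming the pair. Weight initialization is Glorot-uniform from a seeded
generator, biases zero; all randomness (init, shuffling, splits, subject
draws, t-SNE) flows from explicit integer seeds, and same-seed runs are
bit-identical.

Tests that need a trained decoder run at desk scale on one CPU: 8
trials/class at +10 dB trained 6 epochs for the learning-sanity and
anchoring checks (held-out 200 segments; the p < 0.01 above-chance
threshold is ~0.32 and the decoder scores ~0.7), a matched −100 dB run
for the chance-level check, and 6 trials/class × 5 epochs × 5 seeds for
the stage-silhouette comparison. Silhouette scores are computed on the
high-dimensional flattened stage features (not the 2-D t-SNE embedding)
so the comparison is deterministic.

## Known limitations

- No GPU path; full-scale (800-epoch, 105-subject) training is out of
  desk-scale reach in pure numpy.
- The adjacency enters attention as a fixed (non-differentiated) bias
  between updates; gradients do not flow through the update rule itself.
- The montage ships as idealized unit-sphere positions; absolute
  distances differ from any individual head, which rescales E but leaves
  its normalized geometry unchanged.
- Best-epoch checkpointing monitors test accuracy and is therefore
  optimistic; it exists for visualization workflows, not for reporting.
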