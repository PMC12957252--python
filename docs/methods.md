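# Methods

## Model

### Input representation

A sample is a window `x ∈ R^{T×C×B}`: T consecutive time steps of
per-channel, per-band differential-entropy (DE) features.  Windows are cut
from longer feature series with overlapping sliding windows
(`floor((L−T)/stride)+1` windows, stride 1 by default).  Features are
z-scored per (channel, band) position with statistics fitted on the source
subjects only; the same statistics are applied to the held-out target
subject, so the target never influences any fitted quantity.
Normalization precedes masking, so a masked channel is exactly zero in
model space.

### Dynamic channel masking

Per mini-batch one masking rate is drawn uniformly from {0.10, 0.20, 0.30}
and `round(rate·C)` channels (drawn uniformly without replacement) are
zeroed across all time steps and bands of every sample in the batch.  The
same mechanism runs at test time on the target subject; reported masked
accuracy is the mean over 5 independent seeded mask streams.  A fixed-rate
mode (single-element grid) and a high-intensity grid {0.4, 0.5, 0.6}
support the masking-strategy comparisons.

### Temporal branch

A single shared GRU encoder (hidden 64) reads the attention-weighted
flattened frames; each source subject owns a GRU decoder that unrolls T
steps from the encoder context, maps each hidden state to a (C, B) frame
with a linear head, and emits the frames in reverse time order (mirroring
the encoder's read direction).  The attention weigher scores each frame
with an additive scorer, softmax-normalizes over T and rescales the
weights to mean 1, so a constant scorer is exactly the identity; scorer
parameters start at zero (neutral) and are learned.  The reconstruction
target `r^i` is the attention-weighted unmasked window of subject i with
the same emotion label.  Training uses label-aligned tuples: a batch item
is (label k; one random sample with label k from every source subject).
Stage 2 sums the stage-1 outputs over subjects (a mixup-style cross-subject
augmentation; a sum, not a mean), re-encodes and re-decodes with the same
parameters.  The loss is the per-subject element-mean MSE of the stage-2
outputs against `r^i`, summed over subjects.  The reconstruction loss is placed
on stage-2 outputs only; stage-1 outputs are trained implicitly through
the composition (and are not detached).

The recurrent cell is a GRU; the hidden size (64) and one-layer depth match the
spatial branch, and the gated cell was chosen for stable training in this
package's numpy autodiff core.

### Spatial branch

The branch consumes a per-window spatial frame: the mean over T of the
(masked) window — the time-collapse operator is configurable
(`mean`/`last`), mean being the default.  The electrode graph uses the
clamped inverse-square distance rule `A_ij = clamp(1/(δ d_ij²), 0.1, 1)`
with δ = 8, self-loops `A_ii = 1`, and the symmetrically normalized
operator `L = D̃^{-1/2} A D̃^{-1/2}` with degrees taken from the
self-loop-augmented adjacency.  Coordinates are normalized to unit mean
radius first; on that scale the two clamp thresholds (weight 1 at
d ≈ 0.354, weight 0.1 at d ≈ 1.118) fall inside the montage's
inter-electrode distance range, which is what makes the graph informative
(raw millimetre units would push every pair to the floor).  The packaged
62-channel montage comes from the standard 10-05 template positions; the
two cerebellar leads (CB1/CB2) are mapped to the same scalp locations as
I1/I2.

The encoder stacks two graph convolutions (`L·H·W + b`, ReLU between
layers) followed by batch normalization; local features are the per-channel
rows, the global feature is their channel mean.  Decoders (one per
subject) run graph convolutions whose activated, batch-normalized outputs
are added to a zero-initialized running hidden state, so earlier layers'
aggregated features remain in every later computation; a linear head
shared across channels maps back to B bands.  Disabling the accumulator
(`hidden_state=False`) turns the decoder into a plain feed-forward GCN
stack — the "without hidden state" ablation.  Stage-2 mixing and the loss
mirror the temporal branch, with the normalized unmasked frame `S^i` as
target.

### Subject-adversarial domain generalization

Each branch has its own 2-layer-MLP subject discriminator (hidden 64) over
the N source-subject IDs, fed by the stage-1 encoder features (temporal:
final hidden state; spatial: global pooled feature) through a gradient
reversal layer — identity forward, gradients scaled by −λ backward.  The
stored adversarial losses are the plain nonnegative cross-entropies; the
minimax sign lives structurally in the GRL.  λ follows the standard
domain-adversarial ramp `λ(p) = 2/(1+e^{−10p}) − 1` over training progress
(a fixed value is available and is used in the subject-invariance
experiment).  The pre-training objective is
`L_trec + α·L_srec + β·L_tadv + γ·L_sadv`; α weights the spatial
reconstruction (0.5 in the 3-class profile, 0.1 in the 4-class profile)
and β = γ = 0.05.

### Fine-tuning

Decoders are discarded.  For each batch the masked and unmasked views are
encoded; `F = μ·E_t + (1−μ)·E_s` with a single global learnable scalar μ
initialized at 0.5 (unconstrained); a linear softmax head gives per-view
log-probabilities.  Losses: per-view NLL (the standard
nonnegative cross-entropy of the true label) plus θ times the symmetric KL between the two views'
distributions, batch-mean, probabilities floored at 1e-8 inside the KL.
Gradients flow into both views (no stop-gradient teacher).  Encoders, μ
and the classifier are updated jointly; a `freeze_encoders` switch exists.
θ defaults to 1.0; a {0.1, 0.5, 1.0} sweep is exposed through the
config.

Save-best: 10% of the source pool, stratified by subject and label and
drawn from a config-seeded stream, is held out; after each epoch the
masked-view accuracy on this validation set is computed as the average
over three fixed-seed mask streams (so checkpoint selection is not
dominated by one lucky draw), and the parameters with the maximal validation accuracy are
restored at the end.  Validation masking matches test conditions by
design.

### Protocol

Leave-one-subject-out: one fold per subject; the fold's normalizer,
batches, and discriminator labels are built from source subjects only (an
instrumented audit in the test suite hashes every training batch and
asserts no target window appears).  Optimization uses Adam, lr 1e-3,
weight decay 5e-4, for both stages.  Dataset profiles: the 3-class
profile uses T=30, batch 512, 120/200 epochs; the 4-class profile T=10,
batch 256, 200/200; the synthetic experiments use T=8 and much smaller
batches/epochs (below).  The default seed is 3.

## Synthetic data

The generator emulates the structure that matters to the method, not EEG
physics.  Each class k has a template `μ_k ∈ R^{C×B}` (i.i.d. Gaussian,
scaled so the expected pairwise template distance equals
`class_separation`).  Optionally each band of each template is drawn from
a Gaussian process over the electrode positions (squared-exponential
kernel, length scale `spatial_length_scale`, unit marginal variance):
nearby channels then carry correlated values, the redundancy that volume
conduction produces in real DE features and that a graph autoencoder can
exploit.  Subject s observes `gain_s ⊙ μ_k + offset_s` passed through a
rank-1 band-mixing matrix — an affine marginal shift that preserves class
geometry, which is exactly what domain generalization must remove.  Each
window adds a centered, moving-average-smoothed random walk along T (so
the temporal branch has sequence signal) and i.i.d. Gaussian noise; both
scale with `noise_sd`, so zero noise and zero shift reproduce the
templates exactly.  Electrode layouts default to a deterministic spherical
Fibonacci lattice on the upper hemisphere; the layout is stored with the
dataset so training builds its graph on the same geometry.

What passing tests on this generator do **not** show: robustness to real
artifact structure (EOG/EMG), non-affine subject differences, session
drift, or realistic spectra.  The generator's role is to make every
mechanism falsifiable at desk scale.

## Scaled-down study conditions (`dspmcf.experiments`)

All experiments use C=16 channels, B=5 bands, T=8 steps, and seeds 1-3;
every run is deterministic given its seed.  Problem sizes were chosen so
each mechanism is measurable in minutes on one CPU.

* **Reconstruction sanity** — 3 subjects, zero shift, noise 0.05,
  spatial length scale 0.6, 60 windows per class, batch 8, dynamic
  masking, 30 epochs.  The low noise keeps the irreducible loss floor (the
  within-class variance in z-scored units, which no encoder can remove)
  well below half of the epoch-1 loss, so the ≥50% reduction measures
  optimization, not noise.
* **Graph imputation** — same data at noise 0.3, spatial branch only,
  batch 16, 120 epochs, against a uniform control graph (all off-diagonal
  weights at the 0.1 floor).  Under the uniform operator all masked
  channels receive identical aggregated input, so channel-specific
  recovery is impossible by construction; the geometric graph's
  masked-channel MSE falls below the control's.  The moderate smoothness
  (0.6) matters: much smoother templates are recoverable from the global
  average alone and the geometric advantage disappears, much rougher ones
  make imputation impossible for both.
* **Subject invariance** — 3 subjects, shift 0.3, noise 1.5, 50 epochs,
  fixed λ = 1.  The high noise keeps linear subject probes off their
  ceiling; both probes (logistic regression, 3-fold CV) see identical
  masked views, so the representation is the only difference.
* **LOSO + consistency ablation** — 4 subjects, separation 2.0, shift
  0.4, noise 0.8, spatial length scale 0.15, 50 windows per class;
  pre-train 15 epochs, fine-tune 40.  The low channel redundancy makes
  channel loss genuinely costly, which is the regime where aligning
  masked and unmasked predictions pays; the sample size keeps per-fold
  accuracy estimates precise enough to resolve the ablation's
  single-point effect.  The θ=0 comparison is paired: one pre-training,
  two fine-tunings from identical parameters and identical batch/mask
  streams.
* **Masking-strategy ordering** — same dataset conditions at 25 windows
  per class, fine-tune 25 epochs; dynamic {10, 20, 30}% vs fixed 60%
  (fixed masking also applies at evaluation, matching that strategy's own
  test conditions).

## Numerical choices

* KL probability floor 1e-8; z-score variance floor 1e-6.
* Mask count `round(rate·C)` (banker's rounding); a grid whose rate masks
  zero channels is rejected.
* Batch normalization: batch statistics during training (both pre-training
  stages share the same statistics buffers), running estimates at
  evaluation.
* GRU/linear weights: uniform fan-in initialization from an explicit
  seeded generator; the full model is reproducible bit-for-bit from one
  seed.  Attention scorers start at zero (exact neutrality).
* Divergent training (non-finite loss) aborts with a diagnostic rather
  than continuing.

## Known limitations

* The two-stage composition trains the stage-1 decoders only through the
  stage-2 loss, which makes masked-channel imputation emerge slowly; the
  graph-imputation experiment therefore uses more epochs than the other
  experiments.
* The numpy autodiff core is single-threaded and eager; it is sized for
  the desk-scale experiments, not for 62-channel, 15-subject training
  runs at the full-scale dataset profiles.
* Accuracy differences between the full model and single ablations at
  desk scale are small relative to fold variance; the suite reports means
  over three seeds and uses paired designs where possible.
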