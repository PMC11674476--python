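# Methods

This note records the modelling choices, defaults, and numerical
conventions behind `dacb`, and what the synthetic benchmark does and does
not establish.

## Model

DACB classifies one EEG sample — by default a single instantaneous
channel vector, shaped `(n_channels, 1)` — with two parallel branches
fused by attention.

**Spatial branch.** `Conv1d(64 filters, kernel 3, stride 1, zero
same-padding) → ReLU → MaxPool(2) → SE block → flatten`. The SE block
squeezes each of the 64 feature maps to its mean, passes the 64-vector
through a bottleneck (`64 → 64/R → 64`, ELU then sigmoid, reduction ratio
R = 8) and multiplies each map by its weight. Only the filter count (64)
and the layer sequence are fixed by the architecture; kernel size 3, pool
size 2 and R = 8 are this implementation's defaults, chosen as the
smallest standard values that keep the channel axis meaningful for
14-channel inputs. All are `ModelConfig` fields.

**Temporal branch.** A Bi-LSTM with 32 units per direction runs along the
sample's sequence axis (the channel axis in the per-timepoint layout).
Both directions' full hidden sequences are kept and concatenated per step
(`bilstm_merge="concat"`, the default, giving a `seq_len × 64` map before
flattening); the alternative `"gated"` merge applies
`σ(W_h·[h→,h←]+b_h)` per step. Concat is the default because a
"Bi-LSTM → Flatten" stack implies a per-step sequence output; the gated
merge is kept as an option because it is a standard alternative reading.

**Fusion.** Each branch's flattened vector is linearly projected to a
common width d = 64 and the two results stacked into V ∈ ℝ^(2×64).
Dot-product attention with a learned query — `K = tanh(V·Wₐ)`,
`w = softmax(q·Kᵀ)` — scores the two branches. The default
(`fusion_mode="weighted_concat"`) concatenates the attention-scaled
branch vectors, `[w₁v₁, w₂v₂] ∈ ℝ^128`, before the dense head; the
alternative (`fusion_mode="pool"`) forms the convex combination
`a = w·V ∈ ℝ^64`. Weighted concatenation is the default because the
architecture integrates *both* branch feature vectors in its dense head
(a flatten-and-concatenate design), and because pooling provably caps the
full model: a convex combination of two projections of the same input
cannot carry more information than the better projection, so a pooled
full model can only track — never dominate — its stronger branch. With
weighted concatenation the full model's hypothesis class strictly
contains each single branch's. This "branch" attention mode (a 2-position
value matrix scoring *spatial vs temporal*) is the default; a "position"
mode that instead stacks all per-position features of both branches into
V (and always pools — concatenating hundreds of positions would be
enormous) is available in `ModelConfig`. With a single active branch (the
ablations) the softmax over one position is identically 1 and attention
reduces to the identity.

**Head.** Dense 64 (ReLU) → Dense 32 (ReLU) → Dense `n_classes` →
softmax. The output layer is one softmax over all classes. ReLU is used
after the conv and both hidden dense layers.

**Ablations.** `block1_spatial_only` instantiates no LSTM weights at all;
`block2_temporal_only` instantiates no conv/SE weights; `full` is DACB.
All three share the head and fusion machinery, so comparisons under
identical fold manifests are controlled.

## Training

Categorical cross-entropy minimized by Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8), learning rate 0.001, batch size 1024, master seed 42 — all
`TrainConfig` fields. Gradients are clipped to a global norm of 5 before
each update (`grad_clip`; set to `None` to disable) — the standard
stabilizer for recurrent networks, applied identically to every model
variant. Shuffling is reseeded per run, per-fold models are
re-initialized from fold-indexed seeds derived via
`SeedSequence(master, spawn_key=(fold,))` (kept below 2³¹), and the whole
stack is pure NumPy, so any run is bit-reproducible from its manifest.
The canonical epoch count for full-scale experiments is 150; the tests
and acceptance script use 3–12 epochs at reduced problem sizes (below).

Gradients come from a small tape-based reverse-mode autodiff engine. The
Bi-LSTM is a single fused operation with hand-derived backpropagation
through time; it is verified against (a) central finite differences and
(b) step-by-step composition of the public `lstm_step` cell, which is
itself oracle-tested. Parameters are initialized from
U(−1/√fan_in, +1/√fan_in) with zero biases, one spawned seed stream per
component; the attention key projection Wₐ and query q are randomly
initialized like any dense layer.

## Data pipeline

* **Middle segment**: 1000 consecutive columns from the centre of each
  trial, start index ⌊(L−n)/2⌋ (floor centering; the one-sample asymmetry
  for odd remainders is immaterial and deterministic).
* **Per-timepoint samples**: every segment column becomes one sample
  `(n_channels, 1)` inheriting its trial's label and subject — so a
  15 × 24-trial corpus yields 360 × 1000 = 360,000 samples. A
  `window_length > 1` option instead emits non-overlapping
  `(w, n_channels)` windows, for sanity experiments only.
* **Normalization**: per-channel z-score with statistics estimated on the
  training side only and applied unchanged to test data; σ is floored at
  1e−8 so constant channels map to ~0. Train-only statistics prevent the
  mild leakage that global normalization would introduce.
* **Label encoding**: SEED-IV names map to {neutral 0, sad 1, fear 2,
  happy 3} (any fixed bijection is metric-equivalent; this one is frozen
  and documented); DREAMER 1–5 ratings map to classes 0–4, one model per
  rating dimension.

## Evaluation protocols

* **Subject-wise hold-out**: a seeded choice of test subjects (3 of 15 in
  the SEED-IV shape, 5 of 23 in the DREAMER shape); all samples of a
  subject stay on one side, so the score reflects unseen identities.
* **10-fold CV**: seeded shuffle into ten near-equal folds
  (sizes differ by ≤ 1), fresh model and fresh normalization per fold,
  metric means ± sd across folds. Two modes are exposed:
  `sample_shuffled` assigns raw timepoint samples to folds — adjacent,
  highly correlated timepoints of one trial then straddle the train/test
  boundary, which inflates scores — and `trial_grouped` keeps whole
  trials together. Neither is asserted as the canonical protocol; the gap
  between them measures temporal-adjacency leakage, and the test suite
  checks its direction (shuffled ≥ grouped) on jittered data.
* **Argmax ties** resolve to the lowest class index (deterministic).

## Metrics

Accuracy is trace/total of the confusion matrix. Precision and recall are
macro-averaged one-vs-rest values; F1 is the harmonic mean *of the macro
aggregates* (not the macro average of per-class F1) — on balanced data
this keeps accuracy ≈ precision ≈ recall, which is the regime the
protocols produce. MCC defaults to the macro average of per-class
one-vs-rest binary MCCs, staying literal to the binary formula; the R_K
matrix-correlation generalization is available via `multiclass="matrix"`
and is cross-checked against scikit-learn. Any zero denominator
contributes 0, never NaN. Binary tables use the textbook formulas
exactly.

## Synthetic generator

Class c has a *signature*: a unit-norm channel-gain vector g_c and
oscillation parameters (3 sinusoids, frequencies uniform in 4–45 Hz,
amplitudes 0.5–1, random phases) on a DC baseline b_c = 1.25 Σ aₖ. A
trial is `g_c · s_c(t) + ε` with `s_c(t) = b_c + Σ aₖ(1+ηₖ) sin(2π fₖ t/fs + φₖ)`
and ε white Gaussian noise scaled so RMS(signal)/RMS(noise) equals the
requested `snr`. Gain vectors are drawn with rejection so distinct
classes stay below cosine similarity 0.9.

Two deliberate choices:

* **Positive baseline.** Because downstream sampling treats each
  timepoint as an independent example, a zero-mean oscillation would
  produce samples `s·g_c` with s of both signs — x and −x sharing a
  label — which no linear (or near-linear) decision rule can separate.
  The baseline b_c > Σ aₖ keeps the envelope strictly positive so class
  directions are linearly separable at the sample level, while the
  oscillation still differentiates classes along time for trial-level
  structure. The test suite verifies both that a logistic-regression
  probe beats chance by ≥ 20 points and that label shuffling destroys
  this.
* **Jitter.** Per-subject gain perturbation (default 0.05) and per-trial
  amplitude jitter (default 0.1) make unseen subjects and unseen trials
  genuinely harder than unseen timepoints, as in real recordings; without
  them the two CV modes would be indistinguishable.

In `vad_triple` mode three independent 5-class labels are drawn per trial
(the rating dimensions are modelled as independent; models are trained
per dimension) and the trial is the average of the three dimensions'
signatures. Labels are balanced up to rounding within each subject.

**Crossed corpus for ablation studies.** `generate_crossed_trialset`
builds a corpus whose class information is *split* between the two
signature families: 4 classes = 2 channel-gain patterns × 2 oscillation
frequencies, with a random phase per trial so no single timepoint reveals
the frequency. This corpus is only meaningful with time-spanning windowed
samples (`window_length` ≈ one period of the slower rhythm): an
instantaneous channel vector carries literally zero frequency
information, so per-timepoint sampling collapses the temporal signature
entirely. This physical fact shapes what ablations can show (below).

What the generator does **not** emulate: 1/f spectra, artifacts
(blinks, EMG), volume conduction, non-stationarity, rater disagreement.
Passing the synthetic benchmark therefore demonstrates that the
implementation learns spatial and temporal class structure under the
stated protocols — it says nothing about accuracy on real EEG corpora.

## What the ablations show — and what they cannot

Block1 (spatial-only) and Block2 (temporal-only) receive exactly the same
samples as the full model: the branches differ in inductive bias, not in
input. Measured consequence, replicated across many seeds and settings:
each single branch, given enough training, learns *both* the gain pattern
and (from windowed samples) the frequency, so at convergence all three
variants reach the same accuracy ceiling, and the full model — which has
roughly twice the head width and fuses two competing branches — converges
more slowly and occasionally drops a fold below the ceiling at small
sample sizes. The full model therefore *tracks* the best single branch
(typically within a point) rather than dominating it. A large
full-vs-branch gap would require a branch to be information-limited,
which identical inputs rule out, or the single-branch runs to fail at
training — which is not a property worth engineering. The ablation
machinery (`run_ablation`, identical fold manifests, per-variant
parameter sets with no weights from the removed branch) is exercised and
tested; the accuracy *direction* full ≥ both branches is asserted in the
acceptance suite at fixed conditions and documented as marginal: it can
fail by fractions of a point when a fold of the full model lands below
the shared ceiling.

## Channel attribution

Two complementary exports: (1) the SE block's batch-averaged excitation
scores over the 64 conv feature maps, reported both pre-sigmoid (logits,
which can be negative) and post-sigmoid; and (2) per-electrode occlusion
— the accuracy drop when one input electrode is zeroed (post-
normalization, i.e. replaced by its training mean). The SE scores live in
feature-map space, not electrode space; occlusion is the view that maps
one-to-one onto electrodes, which is why both are exported rather than
conflating them. On constructed data with a silenced electrode, occlusion
correctly ranks that electrode least important (averaged over seeds).

## Problem sizes

The default test/benchmark sizes are deliberately desk-scale: the
SEED-IV-shaped benchmark uses the full 15 × 24 trial grid but 50-sample
segments (18,000 samples) and 3 training epochs, which already drives
10-fold CV accuracy above 99% at SNR 10; the ablation study uses the
crossed corpus (240 trials, 14 channels, 4 classes, SNR 3, 960
48-timepoint windows, 3 generator seeds) with 45 epochs so every variant
reaches convergence. Full-scale runs (1000-sample segments, 150 epochs)
use identical code paths via configuration.

## Known limitations

* Pure NumPy on one core: roughly 0.5 s per 1024-sample training batch at
  the 62-channel default size; full-scale 360,000-sample, 150-epoch runs
  are feasible but slow (hours, not minutes).
* The macro one-vs-rest MCC is not identical to the matrix-correlation
  MCC for > 2 classes; both are provided and documented, with macro-OVR
  as default.
* The SE-to-electrode mapping is indirect (see attribution above).
* Real-data readers implement documented best-effort layouts for the
  access-gated corpora and are exercised on small constructed fixtures,
  not on the originals.
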