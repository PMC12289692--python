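# Methods

## Problem setting

Binary motor-imagery decoding: each 4-s cue-locked EEG epoch is labelled
−1/+1 for imagined left/right-hand movement. The physiological marker is
event-related desynchronization (ERD): mu-band (8–12 Hz) power drops on the
hemisphere contralateral to the imagined hand. Decoders must generalize to
unseen subjects (leave-one-subject-out, LOSO), which is hard because
electrode gains, mu peak frequency and noise levels vary between people.

## Synthetic data generator

The generator emulates exactly the statistics the pipeline exploits:

* **Background**: 1/f^α Gaussian noise per channel (spectral shaping of white
  noise), α = 1 by default, SD 5 µV.
* **Mu rhythm**: a narrowband Gaussian process (3 Hz band centred on a
  per-subject frequency drawn from 9–11 Hz), SD 10 µV at baseline. During a
  trial, its amplitude on the contralateral channel group is multiplied by
  √`erd_factor`, so band *power* is multiplied by `erd_factor`. Convention:
  the first half of the channel list is the left hemisphere (contralateral to
  class +1), the second half the right.
* **Blinks**: Poisson arrivals (default 2/min) of a 0.4-s raised-cosine bump,
  10× the background SD, spectrally concentrated below 4 Hz so the high-pass
  filter demonstrably suppresses them.
* **Between-subject variability**: global gain lognormal(0, 0.15), per-channel
  gains lognormal(0, 0.05), per-subject mu frequency and amplitude jitter.
  Each subject has an independent random stream derived from
  `(seed, subject_id)`, so datasets are bit-reproducible and subjects are
  mutually independent.
* **Timeline**: 2 s lead-in, trials separated by 2 s rest; labels balanced to
  within one trial per subject.

What the generator does **not** model: volume-conducted scalp topographies,
non-stationary drifts, EMG artifacts, class-dependent timing jitter. A green
test therefore establishes that the pipeline recovers lateralized band-power
differences under realistic noise — not that it reaches any particular
accuracy on real recordings.

Default scale (8 subjects × 200 trials, 22 channels, 250 Hz) mirrors the
standard benchmark recordings; tests use reduced sampling rates (64–128 Hz)
and channel counts (4–8) to fit CPU budgets. The mu band requires an
effective rate ≥ 24 Hz everywhere; configurations below that are rejected.

## Preprocessing

Fourth-order Butterworth high-pass at 4 Hz (scipy SOS). Zero-phase
forward–backward filtering is the default — cue-locked epochs must not be
delayed; a single causal pass is available (`FilterSpec(zero_phase=False)`)
and follows the analytic magnitude `|H(f)| = (f/fc)⁴/√(1+(f/fc)⁸)`, which the
tests verify at 1 and 4 Hz. No low-pass is applied. Epochs are
`[onset, onset+4 s)`, half-open, 0-based.

Artifact rejection is a single thresholding pass on the mean absolute value
(MAV): reject trials (then channels) whose MAV exceeds `mean + 3·sd`
(strict inequality, population SD). Order in the full pipeline: channel
rejection before trial rejection, so one broken electrode does not drag every
trial over the threshold. In multi-subject (LOSO) use, per-subject channel
rejection is skipped to keep the channel axis aligned across subjects.

## Backbone

Channels-as-depth CNN: input `(batch, electrodes, time)` is treated as
`(batch, depth=electrodes, 1, time)`. Each layer is a `(1, k)` convolution
(`k ∈ {8, 24, 40}`), stride `(1, 2)` with TF-style "same" zero padding so
`out_time = ceil(in_time/2)` — this exactly reproduces the reference time
sequence 180 → 90 → 45 → 23 → 12 → 6 → 3 — followed by batch normalization
and ReLU. Depth follows the algebraic progression
`chans·k0, chans·(k0+1), …` (`k0` configurable; 2 for the 64-channel
reference configuration, 1 elsewhere). A preserved-spatial baseline mode
keeps electrodes as a spatial axis (depth starts at 1) for the flattened-size
comparison. An explicit `depths` override reproduces printed schedules that
do not follow the progression (the doubling baseline 8…256).

After the last convolution the time axis becomes the sequence axis and
depth×spatial the per-step feature vector of a bidirectional LSTM
(forget-gate bias 1). Readout:

* `attention="none"`: many-to-one — final forward and backward hidden states
  concatenated;
* `"multi_head"`: softmax multi-head self-attention over the LSTM output
  sequence, token-mean pooled;
* `"softmax"` / `"svm_margin"`: the margin-attention layer below (in
  `softmax` mode the same layer runs without the hinge loss — a standard
  learned-score attention).

A two-layer fully connected head (ReLU or the experimental
`abs(x)·tanh(x)` activation, which is odd, monotone and ≈x² near zero)
produces two logits. The 4-s epoch is mapped to the CNN window
(`input_time`, default 180) by Fourier resampling (`input_map="decimate"`)
or cropping — the mapping is a config choice because nothing pins it.

## Margin-optimized attention

Given a hidden-state sequence `h_1..h_T`, features `φ_j = W_φ h_j`, scores
`s_j = A·φ_j + b`, weights `w = softmax(s)` over positions, context
`c = Σ_j w_j h_j`. `(A, b, W_φ)` are ordinary network parameters. The
soft-margin SVM objective enters as the differentiable hinge surrogate

`L_SVM = ½‖A‖² + C·mean_i max(0, 1 − y_i (A·φ̄_i + b))`,

evaluated on the attention-pooled feature `φ̄_i = Σ_j w_ij φ_ij` of each trial
`i`, and added to the cross-entropy as `L = L_CE + λ·L_SVM`. This is the
primal soft-margin SVM with slack variables eliminated
(`ξ_i = max(0, 1−margin_i)` at the optimum), so gradient descent inside the
computational graph replaces an external QP solver; the exact QP (solved via
its dual) appears only as an independent test oracle. Design choices:

* the layer uses the *mean* over trials in the batch (not the sum) so the
  auxiliary gradient scale is batch-size independent; the standalone
  `hinge_objective` keeps the sum, matching the textbook form;
* softmax-of-margin-scores is the weight normalization (clip-at-zero with
  renormalization is available); raw margins are unbounded and softmax keeps
  the weights on the simplex while preserving their order;
* labels touch only the auxiliary loss — never the scoring path — so the
  layer is usable at test time;
* subgradient 0 at the hinge kink (the `max(0,·)` autodiff convention);
* per-head `A` with optional sharing; defaults `C = 1`, `λ = 0.1`.

`fit_hinge` (used for the standalone analyses and tests) minimizes the
surrogate by smoothing continuation: a quadratically smoothed hinge with
ε descending 10⁻¹ → 10⁻¹⁰ under warm-started L-BFGS, plus two perturbed
restarts; this reaches the convex optimum to ~10⁻¹⁰ of the QP-dual value.

## Transformer variant

Epochs are cut into non-overlapping 45-sample crops (each inheriting its
trial label; remainder dropped), linearly interpolated to 72 samples — the
1-D reading of an image-resize step — patched (default patch 8 → 9 tokens),
linearly projected with learned positional embeddings, and passed through
`LN → attention → skip → LN → MLP → skip` blocks. Margin attention inside a
block is query-independent, so every token receives the same margin-weighted
value mixture. Trial predictions average crop logits. Training uses AdamW
(lr 10⁻³, weight decay 10⁻², unstated upstream) with accuracy-monitored
early stopping: best initialized to −∞, configurable patience (default 10),
best checkpoint restored. Only accuracy and loss are tracked; the third
"profit" metric slot mentioned upstream is unexplained and left pluggable.

## Evaluation

* LOSO folds in sorted subject order; within each fold a label-stratified 15%
  of training-subject trials is the validation set. Ties in predicted logits
  break toward the negative class.
* Class separation is the Fisher criterion
  `J = ‖μ₊−μ₋‖²/(tr Σ₊ + tr Σ₋)` on attention-pooled features (population
  covariances). No formula is given for the published separability numbers,
  so absolute J values are not comparable across papers or architectures —
  only orderings within one experiment are meaningful, and the ablation
  asserts exactly that.
* The ablation trains four variants (CNN+LSTM; +multi-head attention;
  +transformer encoder; +margin attention) under identical splits, budgets
  and seeds. The *directional* acceptance check compares margin attention
  against its matched softmax-scored control (identical architecture, hinge
  loss off) — the only controlled comparison of the scoring mechanism; the
  multi-head row differs additionally in head count, projections and pooling.
* One-way ANOVA across per-subject accuracies via the standard F statistic;
  an all-constant input returns NaN with a warning (0/0 F is undefined).

## Numerical and engineering choices

* All networks run on an in-package reverse-mode autodiff engine over float64
  numpy arrays; every backward rule is finite-difference tested at ~10⁻⁹
  relative error. This replaces an external deep-learning dependency.
* Determinism: every stochastic step (generation, splits, initialization,
  batch order) flows from explicit integer seeds; seeded runs are
  bit-reproducible.
* EDF export uses a built-in minimal 16-bit EDF writer/reader (integer
  sampling rates, 1-s records, events in a JSON sidecar); round-trip error is
  bounded by one quantization step per channel.
* Input standardization: a global mean/SD computed on the training split is
  applied to all inputs of a fitted model.

## Known limitations

* Binary classification only; multi-class margins are out of scope.
* The synthetic world omits real-EEG nonstationarities (see above), so
  reported accuracies say nothing about benchmark-dataset performance.
* Margin attention assumes the pooled feature space is linearly separable
  enough for a single hyperplane per head.
* The EDF reader handles only files with one uniform sampling rate.
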