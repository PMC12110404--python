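# Methods

## Model

The classifier is a residual CNN for single-channel 2-D slices.  Default
architecture (the full-scale configuration): a 3×3 conv stem to 16
channels, three residual stages with channel plan (64, 128, 256) at strides
(1, 2, 2) — so a 128-px input yields a 256×32×32 final feature map — nine
two-conv blocks per stage (total depth 56 counting stem and head), a
single-head self-attention layer over the 1024 spatial tokens of the final
map (residually added, `d_k` = channel count), global average pooling, and
a linear head to two logits.  Batch normalisation follows every
convolution; initialisation is Kaiming-style from a seeded generator, so
runs are exactly reproducible.

The agent ("generator") maps the classifier's pooled final-stage feature
vector — the RL *state* — through an MLP (state → 2·state → 2·state →
action, ReLU hidden, Tanh output) to an action in `(−1, 1)^D`.  The action
becomes multiplicative gates `w = 1 + a ∈ (0, 2)` on the final feature
map.  Two action semantics are implemented:

* **spatial** (default): `D = g²` weights form a g×g grid, bilinearly
  upsampled (align-corners) to the feature map; every channel is multiplied
  by the same spatial gate.  With the default 256-channel map this gives a
  16×16 grid over the 32×32 map.  This reading matches the goal of
  region-of-interest weighting.
* **channel** (ablation): one gain per channel.

The zero action is the exact identity in both modes, and the policy's final
linear layer is zero-initialised, so training starts from an unbiased
(identity-gated) classifier.

The critic is an MLP (state → 64 → 1, LeakyReLU) predicting expected
reward; its training signal is the mean squared error to the observed
reward, the natural choice for a one-step value baseline.

## Training

Each epoch alternates two phases over independent reshuffled passes of the
training slices:

1. **Classifier phase** — agent frozen.  Batches are forwarded with the
   agent's *deterministic* gate applied; softmax cross-entropy; momentum
   SGD (momentum 0.9, weight decay 5·10⁻⁴), initial learning rate 0.1.
2. **Agent phase** — classifier frozen and in evaluation mode (running
   batch-norm statistics, untouched).  Gates are *sampled* from the
   Tanh-squashed Gaussian policy (initial exploration sd 0.1, log-sd
   learned); the batch's accuracy under the sampled gate yields a reward of
   +1 if it strictly exceeds the 0.9 benchmark and −1 otherwise (the
   boundary counts as not exceeding); every sample of the batch becomes one
   single-step transition with that shared reward.  One PPO-Clip update per
   epoch (clip radius ε = 0.2, 4 gradient epochs against the frozen
   snapshot, Adam at initial rate 0.01); the critic takes the same number
   of Adam steps so the value baseline keeps pace with the policy —
   otherwise the ±1 plateaus early in training leave the advantage pinned
   and the policy drifts on uninformative signal.

Both learning rates decay by 0.1 every 100 epochs (`base ·
0.1^⌊epoch/100⌋`); the full-scale schedule is 600 epochs at batch size 32.
Stochastic augmentation (random rotation, crop-and-resize, horizontal and
vertical flips, brightness/contrast jitter) is applied per batch pass, not
precomputed: fresh draws every epoch keep training-batch accuracy in the
informative band around the reward benchmark instead of saturating at 1.0
once a small training set is memorised.  Class imbalance is handled by
resampling minority slices with replacement to parity before training.

Randomness is partitioned into three seeded streams (batch order +
initialisation, augmentation, RL sampling) so that an RL run and a no-RL
run with the same seed see identical phase-1 batches and augmentations —
paired comparisons then differ only in the mechanism under study.

Divergence (non-finite loss) aborts with a diagnostic rather than
continuing silently.

## Log-density of the squashed policy

Sampling draws `u ~ N(μ(s), σ²)` pre-squash and applies `a = tanh(u)`; the
log-density includes the change-of-variables term
`−Σ log(1 − a²)`, evaluated stably as `2(log 2 − u − softplus(−2u))`.  The
pre-squash draw is stored in each transition so later PPO epochs evaluate
the ratio `p_θ/p_θk` exactly rather than through `arctanh`.

## Phantom generator

Each phantom slice emulates a cropped contrast-CT tumor slice at the
statistical level (it makes no attempt at CT physics — no HU calibration,
beam hardening, or 3-D geometry):

* one elliptical lesion per patient (semi-axes drawn from a configured
  range, center jittered around the image center, orientation uniform),
  geometry drawn once per patient and shared by its slices;
* the class signal lives **only** inside the lesion: an interior mean shift
  (`roi_contrast`, positive class only) plus a class-dependent speckle
  frequency (band-limited zero-mean texture, RMS `texture_amplitude`);
* the background holds label-independent clutter: high-contrast elliptical
  distractors placed outside the lesion (rejection-sampled), plus i.i.d.
  Gaussian acquisition noise per slice;
* all randomness flows from one seed; images are clipped to [0, 1].

Because the signal is ROI-local by construction, blanking the lesion
interior provably removes all class information — the property the gating
mechanism is supposed to exploit, and one the tests verify directly with a
generic pixel-level classifier.  What passing tests on phantoms do **not**
show: robustness to scanner variation, partial-volume effects, segmentation
error, or any real-world covariate shift; the benchmark isolates the
background-distraction failure mode only.

## Desk-scale benchmark conditions

The canonical benchmark (`drlroi.benchmark`) fixes: 32-px slices, lesions
of radius 5–9 px, interior contrast 0.05, speckle frequencies (2.5, 4.0)
cycles/image, 12 distractors of contrast 0.6, noise sd 0.10; 24 patients
per class × 3 slices, 8 validation patients per class; depth-8 backbone
(one block per stage, channels 16/32/64, so the spatial gate is the full
8×8 resolution of the final map); 20 alternating epochs, classifier lr
0.05, generator lr 0.005.  These sizes give a complete paired run (RL arm
plus no-RL twin) in under a minute of single-CPU time while leaving the
baseline clearly below ceiling (its patient AUC varies roughly 0.5–1.0
across cohort draws), which is what makes the comparison informative.
Under these conditions the interesting regime is genuinely noisy: a small
validation set (16 patients) quantises the AUC coarsely, so the benchmark
is evaluated over a seed set and reported as a win fraction plus mean
improvement, not as a single number.

## Evaluation

Slice probabilities are averaged per patient; patient-level accuracy,
sensitivity, specificity (threshold 0.5 — the natural symmetric choice
with a class-balanced validation cohort), ROC and AUC are the headline
metrics, with slice-level figures reported alongside.  AUC uses the
Mann–Whitney convention (ties credit ½).  The AUC confidence interval is
the DeLong-variance normal interval truncated to [0, 1] (a patient-level
bootstrap is selectable); the paired DeLong test compares two models scored
on the same patients, with the degenerate zero-variance case handled
explicitly (identical scores → p = 1; zero variance with a nonzero
difference raises).  Class activation maps project the head weights onto
the final feature map, upsampled and min-max normalised; for the gated
model the deterministic gate is applied first, since the gated map is the
evidence the model actually pools.

## Numerical choices

* All arithmetic in float64; convolution via an offset-sliced im2col with
  BLAS matmuls; every backward pass is finite-difference-checked in the
  test suite.
* Bilinear upsampling of the gate grid uses align-corners semantics (exact
  identity when grid and map sizes agree); image resizing elsewhere uses
  scikit-image's pixel-area convention — the two are never mixed on the
  same path.
* Crop windows are half-open, 0-based, centered on the mask centroid
  rounded to the nearest pixel; out-of-frame regions pad with the image
  minimum (approximating dark air); lesions larger than the window are
  preserved whole and resized down.
* PPO ratios are computed as `exp(clip(Δlogp, ±30))` to avoid overflow;
  a non-finite ratio raises.
* Advantage standardisation is available but off by default: with shared
  batch rewards the advantage spread is often near zero and standardisation
  would amplify noise (it is skipped below spread 10⁻⁸).
* Batches of size 1 are dropped (batch statistics undefined).

## Known limitations

* Single-step episodes and a ±1 step reward are the simplest reading of
  the reward description; richer shaped rewards (e.g. margin-based) might
  give the agent a denser signal but are out of scope.
* The reward is measured on training batches; once a model overfits its
  training set the agent's signal degrades — per-batch augmentation
  mitigates but does not eliminate this at desk scale.
* The mechanism benchmark is stochastic by nature; individual seeds can
  favor the baseline, and the claim is directional (win fraction and mean
  improvement over seeds), matching how the underlying effect manifests.
* CAM *argmax* localisation inside the lesion does not emerge at desk
  scale (the corresponding check in the test suite fails and is left
  failing): the negative class's lesion has no interior mean shift by
  construction, and the strongest single activation tends to sit on a
  high-contrast background distractor even when the pooled evidence (mean
  CAM inside vs outside the lesion) favors the ROI.  On strong-signal
  phantoms (high contrast, no distractors) the CAM argmax does localise.
* The agent-learning-rate sensitivity effect is likewise weak at desk
  scale: because the gates act after batch normalisation on the final map,
  the classifier re-adapts to even saturated gates within a few batches;
  the destabilisation is measurable at the method's default initial rate
  (0.01 vs 0.1) but small.
* The NumPy core is single-threaded-friendly but slow compared to GPU
  frameworks; the full-scale configuration (128 px, depth 56, 600 epochs)
  is implemented and exercised at construction time, but training it end
  to end is impractical without acceleration.
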