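# drlroi

Reinforcement-learning-guided region-of-interest weighting for binary
classification of tumor CT slices.

## The problem

Deep classifiers trained on cropped CT tumor slices — for example, to
predict a tumor's molecular marker status (such as SOX9 immunohistochemistry
in hepatocellular carcinoma) from imaging alone — are easily distracted by
background structures that carry no information about the label.  Class
activation maps of plain residual networks frequently peak on background
clutter, and misclassified slices are exactly the ones where attention
drifted off the lesion.

`drlroi` implements a two-player remedy:

* a **classification model**: a residual CNN (depth-56 channel plan
  16 → 64 → 128 → 256 by default) with a single-head self-attention layer
  over the final feature map's spatial tokens,

  `Q = X W_Q,  K = X W_K,  V = X W_V,  A = softmax(Q Kᵀ / √d_k)`,

  trained with softmax cross-entropy `L = −log p(λ | x)`;
* a **generator (RL agent)**: an MLP (256 → 512 → 512 → 256, Tanh head)
  that reads the classifier's pooled final-stage feature vector `s` as its
  state and emits an action `a ∈ (−1, 1)^256`, realised as multiplicative
  gates `w = 1 + a ∈ (0, 2)` on the final feature map — by default a 16×16
  spatial grid bilinearly upsampled over the 32×32 map, so the agent can
  up-weight lesion regions and suppress background;
* a **critic**: an MLP (256 → 64 → 1) estimating the expected reward,
  used as the advantage baseline `A = r − V(s)`.

The agent is trained by PPO-Clip on single-step episodes: one training
batch is one episode, the reward is `+1` if batch accuracy exceeds a 0.9
benchmark and `−1` otherwise, and the surrogate

`J(θ) = E[ min(ρ A, clip(ρ, 1−ε, 1+ε) A) ]`, `ρ = p_θ(a‖s) / p_θk(a‖s)`

is maximised with a Tanh-squashed Gaussian policy.  Classifier and agent
train in alternation — each epoch first updates the classifier with the
generator frozen (its deterministic gate applied), then freezes the
classifier and updates the generator/critic from sampled gates.

Because clinical CT cohorts cannot ship with a package, `drlroi` includes a
**synthetic tumor-phantom benchmark** with known ground truth: elliptical
lesions whose interior intensity statistics carry the entire class signal,
surrounded by label-independent high-contrast distractors and noise,
grouped into multi-slice patients.  On this benchmark the claim "RL gating
helps a classifier ignore background clutter" is directly testable.

All networks run on a small pure-NumPy compute core with hand-written
backward passes (finite-difference-verified in the test suite); no deep
learning framework is required.

## Worked example

```python
import numpy as np
from drlroi.benchmark import run_paired_benchmark

result = run_paired_benchmark(seed=0)
rl, base = result["rl"], result["baseline"]
print(f"RL-gated  patient AUC: {rl['auc']:.3f}  accuracy: {rl['accuracy']:.3f}")
print(f"baseline  patient AUC: {base['auc']:.3f}  accuracy: {base['accuracy']:.3f}")
```

which prints (seed 0):

```
RL-gated  patient AUC: 0.969  accuracy: 0.938
baseline  patient AUC: 0.891  accuracy: 0.938
```

Both arms train the identical depth-8 backbone on the identical
clutter-heavy phantom cohort (24 patients per class, 3 slices each, 32 px,
20 alternating epochs); the only difference is the PPO-trained gate.
Patient scores are the mean positive-class probability over each patient's
slices; the AUC is the patient-level Mann–Whitney statistic on the 16
held-out validation patients.

The estimators follow the scikit-learn contract:

```python
from drlroi import RLGatedImageClassifier
clf = RLGatedImageClassifier(input_size=32, stage_channels=(16, 32, 64),
                             blocks_per_stage=1, epochs=20, lr_decay_every=20)
clf.fit(X_train, y_train)          # X: (n, H, W) slices in [0, 1]
proba = clf.predict_proba(X_val)
```

A `drlroi` command line binds the pieces into reproducible runs:

```bash
drlroi generate --config config.yaml --out cohort/
drlroi train    --config config.yaml --data cohort/manifest.csv --out run/
drlroi evaluate --config config.yaml --checkpoint run/checkpoint.npz \
                --data cohort/manifest.csv --report report.json
drlroi explain  --config config.yaml --checkpoint run/checkpoint.npz \
                --data cohort/manifest.csv --out cams/
```

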