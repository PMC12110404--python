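"""Desk-scale phantom benchmark: the package's canonical demonstration that
RL-learned ROI gating helps a classifier ignore background clutter.

The study conditions are fixed here in one place:

* phantom regime — weak lesion signal (small interior mean shift plus a
  speckle-frequency difference) under heavy label-independent background
  clutter and acquisition noise, 24 patients per class with 3 slices each;
* model scale — 32-px slices, a depth-8 backbone (one residual block per
  stage, channels 16/32/64, so the spatial action grid is 8x8 = 64 weights
  on an 8x8 final map), 20 alternating epochs;
* evaluation — patient-level hold-out with 8 validation patients per class.

These sizes keep a full paired run (RL-gated arm plus its no-RL twin) to
well under a minute of single-CPU time while leaving the baseline clearly
below ceiling, which is what makes the comparison informative.
"""

from __future__ import annotations

import numpy as np

from . import pipeline
from .estimators import RLGatedImageClassifier
from .evaluation import cam_roi_fractions, evaluate_scores
from .phantom import PhantomConfig, generate_cohort
from .preprocess import AugmentConfig, crop_cohort, split_cohort

# lesion signal lives only inside the ROI; clutter and noise everywhere else
BENCHMARK_PHANTOM = dict(
    n_patients_per_class=24,
    slices_per_patient=3,
    image_size=32,
    roi_radius_range=(5.0, 9.0),
    roi_contrast=0.05,
    roi_texture_freq=(2.5, 4.0),
    texture_amplitude=0.06,
    background_distractor_count=12,
    distractor_contrast=0.6,
    background_level=0.35,
    center_jitter=0.08,
    noise_sigma=0.10,
)

BENCHMARK_MODEL = dict(
    input_size=32,
    stem_channels=8,
    stage_channels=(16, 32, 64),
    blocks_per_stage=1,
    batch_size=32,
    classifier_lr=0.05,
    generator_lr=0.005,
)

BENCHMARK_EPOCHS = 20
BENCHMARK_VAL_PER_CLASS = 8

# stochastic per-batch augmentation (rotation, crop, flips, intensity
# jitter) — part of the training protocol, keeps batch accuracy informative
BENCHMARK_AUGMENT = AugmentConfig(rotation_degrees=(-10.0, 10.0),
                                  crop_fraction=0.1, flip_horizontal=0.5,
                                  flip_vertical=0.5, jitter_brightness=0.1,
                                  jitter_contrast=0.1)


def benchmark_phantom_config(seed: int) -> PhantomConfig:
    return PhantomConfig(seed=seed, **BENCHMARK_PHANTOM)


def make_estimator(seed: int, rl_enabled: bool,
                   epochs: int = BENCHMARK_EPOCHS) -> RLGatedImageClassifier:
    return RLGatedImageClassifier(rl_enabled=rl_enabled, epochs=epochs,
                                  lr_decay_every=epochs, seed=seed,
                                  augment_config=BENCHMARK_AUGMENT,
                                  **BENCHMARK_MODEL)


def run_benchmark_arm(seed: int, rl_enabled: bool,
                      epochs: int = BENCHMARK_EPOCHS) -> dict:
    """Train one arm (RL-gated or plain) and evaluate it patient-level.

    The phantom cohort, the hold-out split and the initial classifier
    weights depend only on ``seed``, so the two arms of one seed see
    identical data and start from the identical backbone.
    """
    cohort = generate_cohort(benchmark_phantom_config(1000 + seed))
    train, val = split_cohort(cohort, BENCHMARK_VAL_PER_CLASS, seed=seed)
    rng = np.random.default_rng(seed)
    window = BENCHMARK_MODEL["input_size"]
    X, y, _ = pipeline.prepare_arrays(train, window, None, True, rng)
    val_c = crop_cohort(val, window)

    est = make_estimator(seed, rl_enabled, epochs)
    est.fit(X, y)
    probs = est.predict_proba(val_c.images())[:, 1]
    report = evaluate_scores(probs, val_c.labels(), val_c.groups())
    cam = cam_roi_fractions(est.backbone_, probs, val_c, policy=est.policy_,
                            action_mode=est.action_mode)
    return {
        "seed": seed,
        "rl_enabled": rl_enabled,
        "auc": report.auc,
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "slice_probs": probs,
        "labels": val_c.labels(),
        "groups": val_c.groups(),
        "cam": cam,
        "history": est.history_,
    }


def run_paired_benchmark(seed: int, epochs: int = BENCHMARK_EPOCHS) -> dict:
    """Both arms on the identical cohort/split; returns {'rl':..., 'baseline':...}."""
    return {
        "rl": run_benchmark_arm(seed, rl_enabled=True, epochs=epochs),
        "baseline": run_benchmark_arm(seed, rl_enabled=False, epochs=epochs),
    }


# -- learning-rate sensitivity ------------------------------------------------

SENSITIVITY_PHANTOM = dict(BENCHMARK_PHANTOM, n_patients_per_class=8,
                           slices_per_patient=2)
SENSITIVITY_EPOCHS = 8


def run_sensitivity_arm(seed: int, generator_lr: float) -> dict:
    """Short RL run; reports the spread of the classifier loss across epochs
    and whether training diverged (for the agent learning-rate study)."""
    from .training import TrainingDivergedError

    cohort = generate_cohort(
        PhantomConfig(seed=2000 + seed, **SENSITIVITY_PHANTOM))
    rng = np.random.default_rng(seed)
    window = BENCHMARK_MODEL["input_size"]
    X, y, _ = pipeline.prepare_arrays(cohort, window, None, True, rng)
    params = dict(BENCHMARK_MODEL)
    params.update(generator_lr=generator_lr, batch_size=16)
    est = RLGatedImageClassifier(rl_enabled=True, epochs=SENSITIVITY_EPOCHS,
                                 lr_decay_every=SENSITIVITY_EPOCHS, seed=seed,
                                 **params)
    try:
        est.fit(X, y)
    except TrainingDivergedError:
        return {"diverged": True, "loss_spread": float("inf")}
    losses = est.history_["loss"].to_numpy()
    half = losses[len(losses) // 2:]
    return {"diverged": False, "loss_spread": float(np.std(half))}
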