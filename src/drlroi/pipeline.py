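"""End-to-end runs binding generation, preprocessing, training, evaluation
and explanation; every artifact embeds the hash of the config that made it."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import phantom, preprocess, training, evaluation
from .backbone import class_activation_map
from .config import RunConfig, config_hash, dump_resolved
from .estimators import RLGatedImageClassifier


def prepare_arrays(cohort: phantom.Cohort, window: int,
                   augment_cfg: preprocess.AugmentConfig | None,
                   balance: bool, rng: np.random.Generator):
    """Crop to the lesion, optionally balance-upsample and augment; returns
    (X, y, groups) slice arrays ready for the training engine."""
    cropped = preprocess.crop_cohort(cohort, window)
    samples = list(cropped.samples)
    if balance:
        samples = preprocess.balance_upsample(samples, rng)
    images = []
    for s in samples:
        img = s.image
        if augment_cfg is not None and not augment_cfg.is_identity():
            img = preprocess.augment(img, augment_cfg, rng)
        images.append(img)
    X = np.stack(images)
    y = np.array([s.label for s in samples], dtype=int)
    groups = np.array([s.patient_id for s in samples])
    return X, y, groups


def _write_run_manifest(out_dir: Path, config: RunConfig, artifacts: dict) -> None:
    payload = {"config_hash": config_hash(config), "artifacts": artifacts}
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def run_generate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate and write the phantom cohort; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = phantom.generate_cohort(config.phantom.build(config.seed))
    manifest = phantom.save_cohort(cohort, out)
    dump_resolved(config, out / "resolved_config.yaml")
    _write_run_manifest(out, config, {"manifest": str(manifest)})
    return manifest


def build_estimator(config: RunConfig) -> RLGatedImageClassifier:
    return RLGatedImageClassifier(
        input_size=config.preprocess.window,
        stem_channels=config.backbone.stem_channels,
        stage_channels=tuple(config.backbone.stage_channels),
        blocks_per_stage=config.backbone.blocks_per_stage,
        attention_enabled=config.backbone.attention_enabled,
        rl_enabled=config.rl.enabled,
        action_mode=config.rl.action_mode,
        epochs=config.train.epochs,
        batch_size=config.train.batch_size,
        classifier_lr=config.train.classifier_lr,
        generator_lr=config.rl.learning_rate,
        lr_decay_factor=config.train.lr_decay_factor,
        lr_decay_every=config.train.lr_decay_every,
        weight_decay=config.train.weight_decay,
        momentum=config.train.momentum,
        clip_epsilon=config.rl.epsilon,
        benchmark_accuracy=config.rl.benchmark_accuracy,
        ppo_epochs=config.rl.epochs_per_update,
        exploration_std=config.rl.exploration_std,
        advantage_standardize=config.rl.advantage_standardize,
        seed=config.seed,
    )


def run_train(config: RunConfig, data_manifest: str | Path,
              out_dir: str | Path) -> Path:
    """Train on a cohort manifest; writes checkpoint + history, returns the
    checkpoint path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = phantom.load_cohort(data_manifest)
    train_cohort, _ = preprocess.split_cohort(
        cohort, config.preprocess.n_val_per_class, config.seed)
    rng = np.random.default_rng(config.seed)
    X, y, _ = prepare_arrays(train_cohort, config.preprocess.window,
                             None, config.preprocess.balance, rng)
    est = build_estimator(config)
    if config.preprocess.augment_train:
        # stochastic per-batch augmentation inside the training loop
        est.set_params(augment_config=config.preprocess.augment.build(config.seed))
    est.fit(X, y)
    est.history_.to_csv(out / "history.csv", index=False)
    models = training.TrainedModels(
        backbone=est.backbone_, policy=est.policy_, critic=est.critic_,
        ppo_config=est._ppo_config(), train_config=est._train_config())
    ckpt = training.checkpoint(models, config.train.epochs,
                               out / "checkpoint.npz",
                               extra={"config_hash": config_hash(config)})
    dump_resolved(config, out / "resolved_config.yaml")
    _write_run_manifest(out, config, {"checkpoint": str(ckpt),
                                      "history": str(out / "history.csv")})
    return ckpt


def _validation_cohort(config: RunConfig, data_manifest: str | Path):
    cohort = phantom.load_cohort(data_manifest)
    _, val = preprocess.split_cohort(cohort, config.preprocess.n_val_per_class,
                                     config.seed)
    return preprocess.crop_cohort(val, config.preprocess.window)


def run_evaluate(config: RunConfig, checkpoint_path: str | Path,
                 data_manifest: str | Path, report_path: str | Path) -> dict:
    """Patient-level evaluation of a checkpoint on the held-out cohort."""
    models, _ = training.restore(checkpoint_path)
    val = _validation_cohort(config, data_manifest)
    probs = training.predict_proba(models.backbone, models.policy,
                                   val.images(), models.ppo_config)[:, 1]
    report = evaluation.evaluate_scores(probs, val.labels(), val.groups(),
                                        threshold=config.eval.threshold,
                                        ci_level=config.eval.ci_level)
    payload = report.to_dict()
    payload["config_hash"] = config_hash(config)
    report_path = Path(report_path)
    report_path.parent.mkdir(parents=True, exist_ok=True)
    with open(report_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def run_explain(config: RunConfig, checkpoint_path: str | Path,
                data_manifest: str | Path, out_dir: str | Path,
                n_slices: int = 8) -> list[Path]:
    """Write CAM overlays (PNG) for the first validation slices."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models, _ = training.restore(checkpoint_path)
    val = _validation_cohort(config, data_manifest)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images = val.images()[:n_slices]
    probs = training.predict_proba(models.backbone, models.policy, images,
                                   models.ppo_config)[:, 1]
    fmaps = models.backbone.features(images)
    paths = []
    for i, sample in enumerate(val.samples[:n_slices]):
        pred = int(probs[i] > config.eval.threshold)
        cam = class_activation_map(fmaps[i], models.backbone.head.W.data, pred,
                                   output_size=images.shape[1])
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.imshow(images[i], cmap="gray", vmin=0, vmax=1)
        ax.imshow(cam, cmap="jet", alpha=0.35)
        ax.contour(sample.mask, colors="w", linewidths=0.6)
        ax.set_title(f"{sample.slice_id} y={sample.label} p={probs[i]:.2f}",
                     fontsize=7)
        ax.axis("off")
        path = out / f"cam_{sample.slice_id}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    _write_run_manifest(out, config, {"cams": [str(p) for p in paths]})
    return paths
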