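"""Alternating freeze/train schedule for the classifier and the RL agent.

Each epoch has two phases over (independent, reshuffled) passes of the
training slices:

* phase 1 — generator frozen.  Every batch is forwarded with the
  generator's *deterministic* action gating the final feature map, the
  softmax cross-entropy loss is computed, and only classifier parameters
  are stepped (momentum SGD, step-decayed learning rate).
* phase 2 — classifier frozen (evaluation mode: running batch-norm
  statistics are used and left untouched).  Actions are *sampled*, batch
  accuracy against the benchmark yields the +/-1 reward shared by the
  batch's transitions, and the generator/critic are stepped by PPO-Clip and
  MSE respectively (Adam, same step decay).

Both learning rates follow the same step-decay rule: ``base * factor **
floor(epoch / every)``.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import Backbone, BackboneConfig, cross_entropy_loss
from .nn.optim import SGD
from .rl import (
    PolicyNet,
    CriticNet,
    PPOConfig,
    PPOUpdater,
    Transition,
    act,
    apply_action,
    compute_reward,
)


class TrainingDivergedError(RuntimeError):
    """Raised when a non-finite loss is encountered; carries diagnostics."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 600
    batch_size: int = 32
    classifier_lr: float = 0.1
    generator_lr: float = 0.01
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 100
    weight_decay: float = 5e-4
    momentum: float = 0.9
    seed: int = 0
    rl_enabled: bool = True

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_decay_every) <= 0:
            raise ValueError("epochs, batch_size and lr_decay_every must be positive")
        if self.lr_decay_every > self.epochs:
            raise ValueError("lr_decay_every must not exceed epochs")
        if min(self.classifier_lr, self.generator_lr, self.lr_decay_factor) <= 0:
            raise ValueError("learning rates and decay factor must be positive")


def lr_schedule(epoch: int, base_lr: float, config: TrainConfig) -> float:
    """Step decay: ``base_lr * factor ** floor(epoch / every)``."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return base_lr * config.lr_decay_factor ** (epoch // config.lr_decay_every)


@dataclass
class TrainedModels:
    backbone: Backbone
    policy: PolicyNet | None
    critic: CriticNet | None
    ppo_config: PPOConfig
    train_config: TrainConfig


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        if idx.size >= 2:        # batch-norm needs more than one sample
            yield idx


def _gates_from_actions(actions: np.ndarray, fmap_shape, mode: str) -> np.ndarray:
    """Weight maps ``w = 1 + a`` shaped to broadcast over the feature map."""
    from .nn.functional import bilinear_upsample

    B, C, H, W = fmap_shape
    w = 1.0 + np.atleast_2d(actions)
    if mode == "channel":
        return w[:, :, None, None]
    g = int(round(np.sqrt(w.shape[1])))
    if g * g != w.shape[1]:
        raise ValueError("spatial mode needs a square action length")
    grids = np.stack([bilinear_upsample(w[b].reshape(g, g), (H, W))
                      for b in range(B)])
    return grids[:, None, :, :]


def train_alternating(images: np.ndarray, labels: np.ndarray,
                      backbone: Backbone,
                      policy: PolicyNet | None,
                      critic: CriticNet | None,
                      train_config: TrainConfig,
                      ppo_config: PPOConfig,
                      on_phase_end=None,
                      augment_fn=None) -> pd.DataFrame:
    """Run the alternating schedule in place; returns the epoch history.

    ``images`` are (n, H, W) floats in [0, 1]; ``labels`` are 0/1.  With
    ``rl_enabled=False`` (or no policy) the loop reduces to plain classifier
    training: no gating, no phase 2.  ``on_phase_end(epoch, phase)`` is
    invoked after each phase ("classifier" / "agent"), e.g. to audit the
    freeze contract.  ``augment_fn(batch, rng)`` is applied to every batch
    freshly (stochastic augmentation per pass, as in standard image
    training pipelines).
    """
    cfg = train_config
    # separate streams: the classifier phase sees the same batch order and
    # augmentation draws whether or not the RL phase runs (clean paired
    # comparisons)
    rng = np.random.default_rng(cfg.seed)
    rng_aug = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    rng_rl = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    use_rl = cfg.rl_enabled and policy is not None
    clf_opt = SGD(backbone.parameters(), lr=cfg.classifier_lr,
                  momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    updater = PPOUpdater(policy, critic, ppo_config) if use_rl else None

    rows = []
    for epoch in range(cfg.epochs):
        clf_lr = lr_schedule(epoch, cfg.classifier_lr, cfg)
        gen_lr = lr_schedule(epoch, cfg.generator_lr, cfg)
        clf_opt.lr = clf_lr
        if updater is not None:
            updater.policy_opt.lr = gen_lr

        # ---- phase 1: train classifier, generator frozen ----------------
        backbone.train()
        losses, correct, seen = [], 0, 0
        for idx in _batches(len(images), cfg.batch_size, rng):
            batch, y = images[idx], labels[idx]
            if augment_fn is not None:
                batch = augment_fn(batch, rng_aug)
            if use_rl:
                fmap = backbone.features(batch)
                state = fmap.mean(axis=(2, 3))
                actions, _, _ = act(state, policy, mode="deterministic")
                out = backbone.head_forward(fmap, weights=_gates_from_actions(
                    actions, fmap.shape, ppo_config.action_mode))
            else:
                out = backbone.forward(batch)
            loss, dlogits = cross_entropy_loss(out.logits, y, return_grad=True)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite classifier loss at epoch {epoch}")
            clf_opt.zero_grad()
            backbone.backward(dlogits)
            clf_opt.step()
            losses.append(loss)
            correct += int((out.logits.argmax(axis=1) == y).sum())
            seen += len(y)
        if on_phase_end is not None:
            on_phase_end(epoch, "classifier")

        # ---- phase 2: train agent, classifier frozen ---------------------
        reward_sum, n_episodes = 0.0, 0
        ppo_objective = critic_mse = float("nan")
        if use_rl:
            backbone.eval()
            transitions: list[Transition] = []
            batch_rewards = []
            for idx in _batches(len(images), cfg.batch_size, rng_rl):
                batch, y = images[idx], labels[idx]
                if augment_fn is not None:
                    batch = augment_fn(batch, rng_rl)
                fmap = backbone.features(batch)
                states = fmap.mean(axis=(2, 3))
                if not np.all(np.isfinite(states)):
                    raise TrainingDivergedError(
                        f"non-finite feature state at epoch {epoch}")
                actions, logps, pretanh = act(states, policy, mode="sample", rng=rng_rl)
                gated = apply_action(fmap, actions, mode=ppo_config.action_mode)
                pooled = gated.mean(axis=(2, 3))
                logits = backbone.head.forward(pooled)
                accuracy = float((logits.argmax(axis=1) == y).mean())
                reward = compute_reward(accuracy, ppo_config)
                values = critic.forward(states)
                for i in range(len(y)):
                    transitions.append(Transition(
                        state=states[i], action=actions[i], pretanh=pretanh[i],
                        log_density=float(logps[i]), reward=reward,
                        value=float(values[i])))
                batch_rewards.append(reward)
            if transitions:
                stats = updater.update(transitions)
                ppo_objective = stats["ppo_objective"]
                critic_mse = stats["critic_loss"]
                reward_sum = float(np.sum(batch_rewards))
                n_episodes = len(batch_rewards)
            if on_phase_end is not None:
                on_phase_end(epoch, "agent")

        rows.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)) if losses else float("nan"),
            "train_accuracy": correct / max(seen, 1),
            "reward_rate": (np.mean([r > 0 for r in batch_rewards])
                            if use_rl and n_episodes else float("nan")),
            "mean_reward": (reward_sum / n_episodes
                            if use_rl and n_episodes else float("nan")),
            "ppo_objective": ppo_objective,
            "critic_loss": critic_mse,
            "classifier_lr": clf_lr,
            "generator_lr": gen_lr if use_rl else float("nan"),
        })
    backbone.eval()
    return pd.DataFrame(rows)


def predict_proba(backbone: Backbone, policy: PolicyNet | None,
                  images: np.ndarray, ppo_config: PPOConfig,
                  batch_size: int = 64) -> np.ndarray:
    """Positive/negative class probabilities with deterministic gating."""
    backbone.eval()
    out = []
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size]
        if policy is not None:
            fmap = backbone.features(batch)
            states = fmap.mean(axis=(2, 3))
            actions, _, _ = act(states, policy, mode="deterministic")
            gated = apply_action(fmap, actions, mode=ppo_config.action_mode)
            logits = backbone.head.forward(gated.mean(axis=(2, 3)))
        else:
            logits = backbone.forward(batch).logits
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        out.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def checkpoint(models: TrainedModels, epoch: int, path: str | Path,
               extra: dict | None = None) -> Path:
    """Serialise all model parameters, buffers and configs to an .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for name, arr in models.backbone.state_dict().items():
        arrays[f"backbone/{name}"] = arr
    if models.policy is not None:
        for name, arr in models.policy.state_dict().items():
            arrays[f"policy/{name}"] = arr
    if models.critic is not None:
        for name, arr in models.critic.state_dict().items():
            arrays[f"critic/{name}"] = arr
    meta = {
        "epoch": int(epoch),
        "backbone_config": dataclasses.asdict(models.backbone.config),
        "ppo_config": dataclasses.asdict(models.ppo_config),
        "train_config": dataclasses.asdict(models.train_config),
        "has_policy": models.policy is not None,
        "has_critic": models.critic is not None,
        "policy_hidden": (models.policy.fc1.b.data.shape[0]
                          if models.policy is not None else 0),
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    return path


def restore(path: str | Path) -> tuple[TrainedModels, int]:
    """Rebuild models from a checkpoint; forward outputs are bit-identical."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    try:
        archive = np.load(path)
        meta = json.loads(bytes(archive["meta_json"]).decode("utf-8"))
    except (ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt checkpoint: {path}") from exc
    bcfg_dict = dict(meta["backbone_config"])
    bcfg_dict["stage_channels"] = tuple(bcfg_dict["stage_channels"])
    bcfg = BackboneConfig(**bcfg_dict)
    pcfg_dict = dict(meta["ppo_config"])
    ppo_cfg = PPOConfig(**pcfg_dict)
    tcfg = TrainConfig(**meta["train_config"])

    backbone = Backbone(bcfg)
    backbone.load_state_dict({
        name[len("backbone/"):]: archive[name]
        for name in archive.files if name.startswith("backbone/")})
    policy = critic = None
    if meta["has_policy"]:
        state_dim = bcfg.state_dim
        action_dim = int(archive["policy/log_std"].shape[0])
        policy = PolicyNet(state_dim, action_dim=action_dim,
                           hidden_dim=int(meta["policy_hidden"]),
                           init_std=ppo_cfg.exploration_std)
        policy.load_state_dict({
            name[len("policy/"):]: archive[name]
            for name in archive.files if name.startswith("policy/")})
    if meta["has_critic"]:
        critic = CriticNet(bcfg.state_dim)
        critic.load_state_dict({
            name[len("critic/"):]: archive[name]
            for name in archive.files if name.startswith("critic/")})
    backbone.eval()
    models = TrainedModels(backbone=backbone, policy=policy, critic=critic,
                           ppo_config=ppo_cfg, train_config=tcfg)
    return models, int(meta["epoch"])
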