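"""Scikit-learn style estimators wrapping the alternating training engine.

:class:`RLGatedImageClassifier` is the full method — attention-augmented
residual classifier whose final feature map is gated by a PPO-trained
generator agent; setting ``rl_enabled=False`` yields the plain residual
baseline (same backbone, no agent, no gating).  The estimators follow the
scikit-learn contract (``get_params``/``set_params`` via ``BaseEstimator``,
fitted attributes with trailing underscores, ``predict``/``predict_proba``)
so they compose with pipelines and model selection; ``X`` is an
``(n, H, W)`` stack of [0, 1] grayscale slices.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .backbone import Backbone, BackboneConfig
from .rl import PolicyNet, CriticNet, PPOConfig
from .training import TrainConfig, train_alternating, predict_proba


class RLGatedImageClassifier(BaseEstimator, ClassifierMixin):
    """Binary slice classifier with RL-learned ROI gating.

    Parameters mirror the backbone / PPO / schedule configuration; defaults
    are the full-scale settings (128 px inputs, depth-56 backbone, 600
    epochs).  Desk-scale studies pass smaller values.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray of the two class labels.
    backbone_, policy_, critic_ : the trained networks (``policy_`` and
        ``critic_`` are ``None`` when ``rl_enabled=False``).
    history_ : per-epoch training history (DataFrame).
    """

    def __init__(self, input_size: int = 128, stem_channels: int = 16,
                 stage_channels: tuple[int, int, int] = (64, 128, 256),
                 blocks_per_stage: int = 9, attention_enabled: bool = True,
                 rl_enabled: bool = True, action_mode: str = "spatial",
                 epochs: int = 600, batch_size: int = 32,
                 classifier_lr: float = 0.1, generator_lr: float = 0.01,
                 lr_decay_factor: float = 0.1, lr_decay_every: int = 100,
                 weight_decay: float = 5e-4, momentum: float = 0.9,
                 clip_epsilon: float = 0.2, benchmark_accuracy: float = 0.9,
                 ppo_epochs: int = 4, exploration_std: float = 0.1,
                 advantage_standardize: bool = False,
                 augment_config=None, seed: int = 0):
        self.input_size = input_size
        self.stem_channels = stem_channels
        self.stage_channels = stage_channels
        self.blocks_per_stage = blocks_per_stage
        self.attention_enabled = attention_enabled
        self.rl_enabled = rl_enabled
        self.action_mode = action_mode
        self.epochs = epochs
        self.batch_size = batch_size
        self.classifier_lr = classifier_lr
        self.generator_lr = generator_lr
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.clip_epsilon = clip_epsilon
        self.benchmark_accuracy = benchmark_accuracy
        self.ppo_epochs = ppo_epochs
        self.exploration_std = exploration_std
        self.advantage_standardize = advantage_standardize
        self.augment_config = augment_config
        self.seed = seed

    # -- config assembly --------------------------------------------------
    def _backbone_config(self) -> BackboneConfig:
        return BackboneConfig(stem_channels=self.stem_channels,
                              stage_channels=tuple(self.stage_channels),
                              blocks_per_stage=self.blocks_per_stage,
                              attention_enabled=self.attention_enabled,
                              input_size=self.input_size)

    def _ppo_config(self) -> PPOConfig:
        return PPOConfig(epsilon=self.clip_epsilon,
                         benchmark_accuracy=self.benchmark_accuracy,
                         epochs_per_update=self.ppo_epochs,
                         learning_rate=self.generator_lr,
                         exploration_std=self.exploration_std,
                         action_mode=self.action_mode,
                         advantage_standardize=self.advantage_standardize)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           classifier_lr=self.classifier_lr,
                           generator_lr=self.generator_lr,
                           lr_decay_factor=self.lr_decay_factor,
                           lr_decay_every=self.lr_decay_every,
                           weight_decay=self.weight_decay,
                           momentum=self.momentum, seed=self.seed,
                           rl_enabled=self.rl_enabled)

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be an (n_samples, H, W) image stack")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"images must be {self.input_size}x{self.input_size}")
        return X

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, **fit_params):
        """Train on slices ``X`` with binary labels ``y``."""
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes are required")
        y01 = (y == self.classes_[1]).astype(int)

        bcfg = self._backbone_config()
        self.backbone_ = Backbone(bcfg, seed=self.seed)
        if self.rl_enabled:
            if self.action_mode == "spatial":
                g = int(round(np.sqrt(bcfg.state_dim)))
                if g * g != bcfg.state_dim:
                    raise ValueError(
                        "spatial action mode needs a square final channel count")
            self.policy_ = PolicyNet(bcfg.state_dim,
                                     init_std=self.exploration_std,
                                     seed=self.seed + 1)
            self.critic_ = CriticNet(bcfg.state_dim, seed=self.seed + 2)
        else:
            self.policy_ = None
            self.critic_ = None
        augment_fn = None
        if self.augment_config is not None and not self.augment_config.is_identity():
            from .preprocess import augment as _augment

            def augment_fn(batch, rng, _cfg=self.augment_config):
                return np.stack([_augment(img, _cfg, rng) for img in batch])

        self.history_ = train_alternating(X, y01, self.backbone_, self.policy_,
                                          self.critic_, self._train_config(),
                                          self._ppo_config(),
                                          augment_fn=augment_fn)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "backbone_")
        X = self._validate_X(X)
        return predict_proba(self.backbone_, self.policy_, X,
                             self._ppo_config())

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] > 0.5).astype(int)]

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


class ResidualAttentionClassifier(RLGatedImageClassifier):
    """The no-RL ablation: identical backbone, trained without the agent."""

    def __init__(self, input_size: int = 128, stem_channels: int = 16,
                 stage_channels: tuple[int, int, int] = (64, 128, 256),
                 blocks_per_stage: int = 9, attention_enabled: bool = True,
                 epochs: int = 600, batch_size: int = 32,
                 classifier_lr: float = 0.1, lr_decay_factor: float = 0.1,
                 lr_decay_every: int = 100, weight_decay: float = 5e-4,
                 momentum: float = 0.9, seed: int = 0):
        super().__init__(input_size=input_size, stem_channels=stem_channels,
                         stage_channels=stage_channels,
                         blocks_per_stage=blocks_per_stage,
                         attention_enabled=attention_enabled,
                         rl_enabled=False, epochs=epochs,
                         batch_size=batch_size, classifier_lr=classifier_lr,
                         lr_decay_factor=lr_decay_factor,
                         lr_decay_every=lr_decay_every,
                         weight_decay=weight_decay, momentum=momentum,
                         seed=seed)
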