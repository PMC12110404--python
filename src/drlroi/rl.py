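"""Generator (actor) and critic: weight-map actions trained by PPO-Clip.

The classifier's pooled final-stage feature vector is the agent's state.
The generator maps it through an MLP to a Tanh-squashed action ``a`` in
(-1, 1)^D, realised as multiplicative gates ``w = 1 + a`` in (0, 2) on the
classifier's final feature map — either as a spatial grid upsampled over
the map (default; "regions of interest") or as per-channel gains.  The zero
action is the exact identity.

Episodes are single-step: one batch is one episode, the reward is a step
function of batch accuracy against a fixed benchmark (default 0.9), and the
advantage is ``r - V(s)`` with the critic ``V`` regressed on the observed
reward by mean squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import Module, Parameter, Linear, ReLU, LeakyReLU
from .nn.functional import bilinear_upsample
from .nn.optim import Adam

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PPOConfig:
    epsilon: float = 0.2                  # clip radius of the surrogate ratio
    benchmark_accuracy: float = 0.9       # reward breakpoint
    epochs_per_update: int = 4            # gradient epochs per snapshot
    learning_rate: float = 0.01           # generator (Adam) initial lr
    critic_lr: float = 1e-2
    exploration_std: float = 0.1          # initial Gaussian scale
    action_mode: str = "spatial"          # "spatial" | "channel"
    advantage_standardize: bool = False
    entropy_coef: float = 0.0             # off by default

    def __post_init__(self):
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if not 0.0 < self.benchmark_accuracy < 1.0:
            raise ValueError("benchmark_accuracy must lie in (0, 1)")
        if self.action_mode not in ("spatial", "channel"):
            raise ValueError("action_mode must be 'spatial' or 'channel'")


class PolicyNet(Module):
    """Gaussian policy with a Tanh squash.

    The MLP core outputs the pre-Tanh mean; ``log_std`` is a learned
    per-dimension log-scale.  The final linear layer is zero-initialised so
    the initial deterministic action is exactly zero (identity gating).
    """

    def __init__(self, state_dim: int, action_dim: int | None = None,
                 hidden_dim: int | None = None, init_std: float = 0.1,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        action_dim = state_dim if action_dim is None else action_dim
        hidden_dim = 2 * state_dim if hidden_dim is None else hidden_dim
        self.state_dim = state_dim
        self.action_dim = action_dim
        self.fc1 = Linear(state_dim, hidden_dim, rng)
        self.act1 = ReLU()
        self.fc2 = Linear(hidden_dim, hidden_dim, rng)
        self.act2 = ReLU()
        self.fc3 = Linear(hidden_dim, action_dim, rng, zero_init=True)
        self.log_std = Parameter(np.full(action_dim, np.log(init_std)))

    def mean_pretanh(self, states: np.ndarray) -> np.ndarray:
        x = self.fc1.forward(states)
        x = self.act1.forward(x)
        x = self.fc2.forward(x)
        x = self.act2.forward(x)
        return self.fc3.forward(x)

    def backward_mean(self, dmean: np.ndarray) -> np.ndarray:
        g = self.fc3.backward(dmean)
        g = self.act2.backward(g)
        g = self.fc2.backward(g)
        g = self.act1.backward(g)
        return self.fc1.backward(g)


class CriticNet(Module):
    """State-value network ``V(s)`` (scalar output)."""

    def __init__(self, state_dim: int, hidden_dim: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = Linear(state_dim, hidden_dim, rng)
        self.act1 = LeakyReLU()
        self.fc2 = Linear(hidden_dim, 1, rng)

    def forward(self, states: np.ndarray) -> np.ndarray:
        x = self.fc1.forward(np.atleast_2d(states))
        x = self.act1.forward(x)
        return self.fc2.forward(x)[:, 0]

    def backward(self, dvalues: np.ndarray) -> None:
        g = self.fc2.backward(np.atleast_1d(dvalues)[:, None])
        g = self.act1.backward(g)
        self.fc1.backward(g)


@dataclass
class Transition:
    """One single-step episode record."""

    state: np.ndarray          # s_t, pooled feature vector
    action: np.ndarray         # a_t in (-1, 1)^D
    pretanh: np.ndarray        # Gaussian draw before the Tanh squash
    log_density: float         # log p_{theta_k}(a_t | s_t) at sampling time
    reward: float = 0.0
    value: float = 0.0

    @property
    def advantage(self) -> float:
        return self.reward - self.value


def _tanh_log_jacobian(pretanh: np.ndarray) -> np.ndarray:
    """log(1 - tanh(u)^2), evaluated stably as 2(log 2 - u - softplus(-2u))."""
    return 2.0 * (np.log(2.0) - pretanh - np.logaddexp(0.0, -2.0 * pretanh))


def gaussian_tanh_log_density(pretanh: np.ndarray, mean: np.ndarray,
                              log_std: np.ndarray) -> np.ndarray:
    """log-density of ``a = tanh(u)`` under ``u ~ N(mean, exp(log_std)^2)``.

    Inputs are (..., D); the result sums over the last axis.  The change of
    variables subtracts the log-Jacobian ``log|da/du| = log(1 - a^2)``.
    """
    std = np.exp(log_std)
    z = (pretanh - mean) / std
    log_norm = -0.5 * z ** 2 - log_std - 0.5 * _LOG_2PI
    return np.sum(log_norm - _tanh_log_jacobian(pretanh), axis=-1)


def act(state: np.ndarray, policy: PolicyNet, mode: str = "sample",
        rng: np.random.Generator | None = None):
    """Draw (or read off) an action for ``state`` (one vector or a batch).

    Returns ``(action, log_density, pretanh)``; in deterministic mode the
    log-density is evaluated at the Tanh mean itself.
    """
    state = np.asarray(state, dtype=np.float64)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    single = state.ndim == 1
    states = np.atleast_2d(state)
    mean = policy.mean_pretanh(states)
    if mode == "deterministic":
        pretanh = mean
    elif mode == "sample":
        if rng is None:
            raise ValueError("sample mode needs an rng")
        std = np.exp(policy.log_std.data)
        pretanh = mean + rng.standard_normal(mean.shape) * std
    else:
        raise ValueError(f"unknown mode {mode!r}")
    action = np.tanh(pretanh)
    logp = gaussian_tanh_log_density(pretanh, mean, policy.log_std.data)
    if single:
        return action[0], float(logp[0]), pretanh[0]
    return action, logp, pretanh


def apply_action(feature_map: np.ndarray, action: np.ndarray,
                 mode: str = "spatial") -> np.ndarray:
    """Gate a ``(C, H, W)`` or ``(B, C, H, W)`` feature map with ``w = 1 + a``.

    Spatial mode reshapes the D = g*g weights to a g x g grid, bilinearly
    upsamples it to (H, W) and multiplies every channel; channel mode scales
    channel ``c`` by ``w_c``.  The all-zero action is the exact identity.
    """
    fmap = np.asarray(feature_map, dtype=np.float64)
    batched = fmap.ndim == 4
    maps = fmap if batched else fmap[None]
    actions = np.atleast_2d(np.asarray(action, dtype=np.float64))
    if actions.shape[0] == 1 and maps.shape[0] > 1:
        actions = np.broadcast_to(actions, (maps.shape[0], actions.shape[1]))
    B, C, H, W = maps.shape
    weights = 1.0 + actions
    if mode == "channel":
        if actions.shape[1] != C:
            raise ValueError("channel mode needs one weight per channel")
        out = maps * weights[:, :, None, None]
    elif mode == "spatial":
        g = int(round(np.sqrt(actions.shape[1])))
        if g * g != actions.shape[1]:
            raise ValueError("spatial mode needs a square action length")
        out = np.empty_like(maps)
        for b in range(B):
            grid = bilinear_upsample(weights[b].reshape(g, g), (H, W))
            out[b] = maps[b] * grid
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if batched else out[0]


def action_weight_map(action: np.ndarray, shape: tuple[int, int],
                      mode: str = "spatial") -> np.ndarray:
    """The (H, W) gate produced by one action (spatial mode visualisation)."""
    if mode != "spatial":
        raise ValueError("weight maps are only defined for spatial mode")
    g = int(round(np.sqrt(action.size)))
    if g * g != action.size:
        raise ValueError("spatial mode needs a square action length")
    return bilinear_upsample((1.0 + np.asarray(action)).reshape(g, g), shape)


def compute_reward(batch_accuracy: float, config: PPOConfig) -> float:
    """+1 when accuracy strictly exceeds the benchmark, else -1 (the
    boundary counts as not exceeding)."""
    if not 0.0 <= batch_accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    return 1.0 if batch_accuracy > config.benchmark_accuracy else -1.0


def advantages(transitions: list[Transition],
               standardize: bool = False) -> np.ndarray:
    """One-step advantages ``r - V(s)``; optionally standardised to mean 0,
    sd 1 across the batch (skipped when the spread is degenerate)."""
    adv = np.array([t.advantage for t in transitions], dtype=np.float64)
    if standardize:
        sd = adv.std()
        if sd > 1e-8:
            adv = (adv - adv.mean()) / sd
    return adv


def ppo_clip_objective(transitions: list[Transition], policy: PolicyNet,
                       config: PPOConfig) -> float:
    """The clipped surrogate: mean over transitions of
    ``min(rho * A, clip(rho, 1 - eps, 1 + eps) * A)`` where
    ``rho = p_theta(a|s) / p_theta_k(a|s)``.  Equals ``mean(A)`` when the
    policy coincides with the snapshot."""
    states = np.stack([t.state for t in transitions])
    pretanh = np.stack([t.pretanh for t in transitions])
    logp_old = np.array([t.log_density for t in transitions])
    adv = advantages(transitions, config.advantage_standardize)
    mean = policy.mean_pretanh(states)
    logp = gaussian_tanh_log_density(pretanh, mean, policy.log_std.data)
    rho = np.exp(logp - logp_old)
    if not np.all(np.isfinite(rho)):
        raise FloatingPointError("non-finite importance ratio")
    clipped = np.clip(rho, 1.0 - config.epsilon, 1.0 + config.epsilon)
    return float(np.mean(np.minimum(rho * adv, clipped * adv)))


def critic_loss(transitions: list[Transition], critic: CriticNet) -> float:
    """Mean squared error between V(s_t) and the observed reward."""
    states = np.stack([t.state for t in transitions])
    rewards = np.array([t.reward for t in transitions])
    values = critic.forward(states)
    return float(np.mean((values - rewards) ** 2))


class PPOUpdater:
    """Owns the generator/critic optimisers and performs one PPO update
    (several gradient epochs against a fixed snapshot) per call."""

    def __init__(self, policy: PolicyNet, critic: CriticNet, config: PPOConfig):
        self.policy = policy
        self.critic = critic
        self.config = config
        self.policy_opt = Adam(policy.parameters(), lr=config.learning_rate)
        self.critic_opt = Adam(critic.parameters(), lr=config.critic_lr)

    def update(self, transitions: list[Transition]) -> dict[str, float]:
        cfg = self.config
        states = np.stack([t.state for t in transitions])
        pretanh = np.stack([t.pretanh for t in transitions])
        logp_old = np.array([t.log_density for t in transitions])
        rewards = np.array([t.reward for t in transitions])
        adv = advantages(transitions, cfg.advantage_standardize)
        T = len(transitions)

        objective = float("nan")
        for _ in range(cfg.epochs_per_update):
            mean = self.policy.mean_pretanh(states)
            log_std = self.policy.log_std.data
            logp = gaussian_tanh_log_density(pretanh, mean, log_std)
            rho = np.exp(np.clip(logp - logp_old, -30.0, 30.0))
            if not np.all(np.isfinite(rho)):
                raise FloatingPointError("non-finite importance ratio in PPO update")
            clipped = np.clip(rho, 1.0 - cfg.epsilon, 1.0 + cfg.epsilon)
            unclipped_term = rho * adv
            clipped_term = clipped * adv
            objective = float(np.mean(np.minimum(unclipped_term, clipped_term)))

            # d objective / d logp: gradient flows through rho only where the
            # unclipped branch is active or the clip is not saturated
            active = (unclipped_term <= clipped_term) | (
                (rho >= 1.0 - cfg.epsilon) & (rho <= 1.0 + cfg.epsilon))
            dlogp = np.where(active, rho * adv, 0.0) / T        # ascent direction
            std2 = np.exp(2.0 * log_std)
            z = pretanh - mean
            dmean = -(dlogp[:, None] * z / std2)                # descent on -J
            dlog_std = -(dlogp[:, None] * (z ** 2 / std2 - 1.0))
            if cfg.entropy_coef > 0.0:
                dlog_std -= cfg.entropy_coef / T                # entropy bonus

            self.policy_opt.zero_grad()
            self.policy.backward_mean(dmean)
            self.policy.log_std.grad += dlog_std.sum(axis=0)
            self.policy_opt.step()

        # critic regression on the observed rewards, stepped as many times
        # as the policy so the value baseline keeps pace
        v_loss = float("nan")
        for _ in range(cfg.epochs_per_update):
            values = self.critic.forward(states)
            v_loss = float(np.mean((values - rewards) ** 2))
            self.critic_opt.zero_grad()
            self.critic.backward(2.0 * (values - rewards) / T)
            self.critic_opt.step()
        return {"ppo_objective": objective, "critic_loss": v_loss,
                "mean_reward": float(rewards.mean())}
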