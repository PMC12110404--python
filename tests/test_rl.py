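"""Policy sampling, gating semantics, reward, advantage and PPO-Clip."""

import numpy as np
import pytest

from drlroi.nn.functional import bilinear_upsample
from drlroi.rl import (
    CriticNet,
    PPOConfig,
    PPOUpdater,
    PolicyNet,
    Transition,
    act,
    advantages,
    apply_action,
    compute_reward,
    critic_loss,
    gaussian_tanh_log_density,
    ppo_clip_objective,
)

RNG = np.random.default_rng(1)


def _make_transitions(policy, n, state_dim, rng, reward=1.0, value=0.25):
    out = []
    for _ in range(n):
        s = rng.normal(size=state_dim)
        a, logp, u = act(s, policy, mode="sample", rng=rng)
        out.append(Transition(state=s, action=a, pretanh=u, log_density=logp,
                              reward=reward, value=value))
    return out


class TestAct:
    def test_zero_final_layer_gives_zero_deterministic_action(self):
        policy = PolicyNet(8, seed=0)
        a, _, _ = act(np.ones(8), policy, mode="deterministic")
        np.testing.assert_array_equal(a, np.zeros(8))

    def test_vanishing_std_collapses_sample_to_mean(self):
        policy = PolicyNet(4, seed=0)
        policy.log_std.data[...] = -20.0
        det, _, _ = act(np.ones(4), policy, mode="deterministic")
        samp, _, _ = act(np.ones(4), policy, mode="sample",
                         rng=np.random.default_rng(0))
        np.testing.assert_allclose(samp, det, atol=1e-8)

    def test_log_density_matches_change_of_variables_oracle(self):
        """Hand evaluation of the Gaussian + Tanh density for a 2-D policy."""
        policy = PolicyNet(2, hidden_dim=4, seed=3)
        policy.fc3.W.data[...] = np.random.default_rng(5).normal(size=(4, 2))
        state = np.array([0.3, -0.7])
        a, logp, u = act(state, policy, mode="sample",
                         rng=np.random.default_rng(7))
        mean = policy.mean_pretanh(state[None])[0]
        std = np.exp(policy.log_std.data)
        gauss = -0.5 * ((u - mean) / std) ** 2 - np.log(std) \
            - 0.5 * np.log(2 * np.pi)
        jac = np.log(1.0 - np.tanh(u) ** 2)
        expected = float(np.sum(gauss - jac))
        assert logp == pytest.approx(expected, rel=1e-9)
        np.testing.assert_allclose(a, np.tanh(u))

    def test_non_finite_state_raises(self):
        policy = PolicyNet(2, seed=0)
        with pytest.raises(ValueError):
            act(np.array([np.nan, 0.0]), policy)

    def test_action_mean_bounded(self):
        policy = PolicyNet(4, seed=0)
        policy.fc3.W.data[...] = np.random.default_rng(0).normal(size=policy.fc3.W.shape) * 0.5
        a, _, _ = act(np.ones(4) * 3, policy, mode="deterministic")
        assert np.all(np.abs(a) < 1.0)
        assert np.any(np.abs(a) > 0.0)


class TestApplyAction:
    def test_zero_action_is_exact_identity(self):
        fmap = RNG.uniform(size=(4, 8, 8))
        out = apply_action(fmap, np.zeros(4), mode="channel")
        np.testing.assert_array_equal(out, fmap)
        out_s = apply_action(fmap, np.zeros(64), mode="spatial")
        np.testing.assert_array_equal(out_s, fmap)

    def test_near_minus_one_action_suppresses_map(self):
        fmap = RNG.uniform(size=(4, 8, 8)) + 1.0
        out = apply_action(fmap, np.full(64, -1.0 + 1e-9), mode="spatial")
        assert np.max(np.abs(out)) < 1e-8

    def test_channel_mode_scales_each_channel(self):
        fmap = np.ones((3, 4, 4))
        action = np.array([-0.5, 0.0, 0.5])
        out = apply_action(fmap, action, mode="channel")
        np.testing.assert_allclose(out[0], 0.5)
        np.testing.assert_allclose(out[1], 1.0)
        np.testing.assert_allclose(out[2], 1.5)

    def test_spatial_mode_matches_bilinear_oracle(self):
        """A single hot grid entry scales the corresponding upsampled patch
        by exactly the bilinear kernel."""
        fmap = np.ones((2, 8, 8))
        action = np.zeros(16)
        action[5] = 0.8                       # grid position (1, 1) of 4x4
        out = apply_action(fmap, action, mode="spatial")
        grid = (1.0 + action).reshape(4, 4)
        expected = bilinear_upsample(grid, (8, 8))
        for c in range(2):
            np.testing.assert_allclose(out[c], expected)

    def test_non_square_action_in_spatial_mode_raises(self):
        with pytest.raises(ValueError):
            apply_action(np.ones((2, 4, 4)), np.zeros(5), mode="spatial")


class TestRewardAndAdvantage:
    @pytest.mark.parametrize("acc,expected", [
        (0.95, 1.0),    # exceeds the benchmark -> positive
        (0.85, -1.0),   # below -> negative
        (0.90, -1.0),   # boundary counts as not exceeding
        (1.0, 1.0),
        (0.0, -1.0),
    ])
    def test_step_function(self, acc, expected):
        assert compute_reward(acc, PPOConfig()) == expected

    def test_reward_has_single_breakpoint_at_benchmark(self):
        cfg = PPOConfig()
        grid = np.linspace(0, 1, 201)
        rewards = np.array([compute_reward(a, cfg) for a in grid])
        flips = np.nonzero(np.diff(rewards))[0]
        assert len(flips) == 1
        assert grid[flips[0]] == pytest.approx(0.9, abs=0.005)

    def test_one_step_advantage(self):
        t = Transition(state=np.zeros(2), action=np.zeros(2),
                       pretanh=np.zeros(2), log_density=0.0,
                       reward=1.0, value=0.3)
        assert t.advantage == pytest.approx(0.7)
        t2 = Transition(state=np.zeros(2), action=np.zeros(2),
                        pretanh=np.zeros(2), log_density=0.0,
                        reward=-1.0, value=-1.0)
        assert t2.advantage == 0.0

    def test_advantage_standardization(self):
        rng = np.random.default_rng(0)
        ts = [Transition(state=np.zeros(2), action=np.zeros(2),
                         pretanh=np.zeros(2), log_density=0.0,
                         reward=float(rng.choice([-1, 1])),
                         value=float(rng.normal())) for _ in range(50)]
        adv = advantages(ts, standardize=True)
        assert adv.mean() == pytest.approx(0.0, abs=1e-12)
        assert adv.std() == pytest.approx(1.0, abs=1e-12)


class TestPPOObjective:
    def _single_transition_objective(self, rho, eps, adv):
        """Hand-evaluated clipped surrogate for a scalar ratio."""
        return min(rho * adv, float(np.clip(rho, 1 - eps, 1 + eps)) * adv)

    @pytest.mark.parametrize("rho,adv,expected", [
        (1.0, 2.0, 2.0),
        (1.5, 1.0, 1.2),
        (0.5, -1.0, -0.8),
    ])
    def test_hand_evaluated_clipped_values(self, rho, adv, expected):
        assert self._single_transition_objective(rho, 0.2, adv) == \
            pytest.approx(expected)

    def test_objective_equals_mean_advantage_at_snapshot(self):
        policy = PolicyNet(4, seed=0)
        rng = np.random.default_rng(2)
        ts = _make_transitions(policy, 10, 4, rng, reward=1.0, value=0.4)
        cfg = PPOConfig()
        obj = ppo_clip_objective(ts, policy, cfg)
        assert obj == pytest.approx(np.mean([t.advantage for t in ts]), rel=1e-9)

    def test_objective_never_exceeds_unclipped_surrogate(self):
        policy = PolicyNet(4, seed=0)
        rng = np.random.default_rng(3)
        ts = _make_transitions(policy, 20, 4, rng)
        # perturb the policy so ratios deviate from 1
        policy.fc3.W.data += rng.normal(scale=0.3, size=policy.fc3.W.shape)
        cfg = PPOConfig()
        states = np.stack([t.state for t in ts])
        pretanh = np.stack([t.pretanh for t in ts])
        logp_old = np.array([t.log_density for t in ts])
        mean = policy.mean_pretanh(states)
        logp = gaussian_tanh_log_density(pretanh, mean, policy.log_std.data)
        rho = np.exp(logp - logp_old)
        adv = np.array([t.advantage for t in ts])
        assert ppo_clip_objective(ts, policy, cfg) <= np.mean(rho * adv) + 1e-12

    def test_ppo_gradient_matches_policy_gradient_at_snapshot(self):
        """At rho = 1 the clip is inactive, so the surrogate gradient equals
        the vanilla likelihood-ratio gradient (finite-difference check on a
        single weight)."""
        policy = PolicyNet(2, hidden_dim=4, seed=1)
        policy.fc3.W.data[...] = np.random.default_rng(4).normal(size=(4, 2)) * 0.1
        rng = np.random.default_rng(5)
        ts = _make_transitions(policy, 6, 2, rng, reward=1.0, value=0.2)
        cfg = PPOConfig()
        adv = np.array([t.advantage for t in ts])
        states = np.stack([t.state for t in ts])
        pretanh = np.stack([t.pretanh for t in ts])

        eps = 1e-6
        w = policy.fc3.W.data

        def surrogate():
            return ppo_clip_objective(ts, policy, cfg)

        def vanilla():
            mean = policy.mean_pretanh(states)
            logp = gaussian_tanh_log_density(pretanh, mean, policy.log_std.data)
            return float(np.mean(logp * adv))

        orig = w[0, 0]
        w[0, 0] = orig + eps
        s_hi, v_hi = surrogate(), vanilla()
        w[0, 0] = orig - eps
        s_lo, v_lo = surrogate(), vanilla()
        w[0, 0] = orig
        ds = (s_hi - s_lo) / (2 * eps)
        dv = (v_hi - v_lo) / (2 * eps)
        assert ds == pytest.approx(dv, rel=1e-4, abs=1e-8)


class TestCritic:
    def test_zero_loss_when_values_match_rewards(self):
        critic = CriticNet(2, seed=0)
        ts = [Transition(state=np.ones(2), action=np.zeros(2),
                         pretanh=np.zeros(2), log_density=0.0, reward=0.0)]
        v = critic.forward(np.ones((1, 2)))[0]
        ts[0].reward = float(v)
        assert critic_loss(ts, critic) == pytest.approx(0.0, abs=1e-18)

    def test_unit_loss_for_unit_errors(self):
        critic = CriticNet(2, seed=0)
        critic.fc2.W.data[...] = 0.0
        critic.fc2.b.data[...] = 0.0
        ts = [Transition(state=np.ones(2), action=np.zeros(2),
                         pretanh=np.zeros(2), log_density=0.0, reward=r)
              for r in (1.0, -1.0)]
        assert critic_loss(ts, critic) == pytest.approx(1.0)

    def test_update_reduces_critic_loss(self):
        policy = PolicyNet(4, seed=0)
        critic = CriticNet(4, seed=0)
        cfg = PPOConfig(learning_rate=1e-3)
        updater = PPOUpdater(policy, critic, cfg)
        rng = np.random.default_rng(6)
        ts = _make_transitions(policy, 32, 4, rng, reward=1.0)
        before = critic_loss(ts, critic)
        for _ in range(20):
            updater.update(ts)
        assert critic_loss(ts, critic) < before
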