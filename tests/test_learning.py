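"""Replay, targets, loss, schedule, and the compiled training loop."""

import numpy as np
import pytest

from collabhunt import _fastloop, env, learning
from collabhunt.agents import PolicyParams, build_state_vector, forward
from collabhunt.env import ConditionConfig
from collabhunt.learning import (
    Adam,
    LearnerConfig,
    ReplayMemory,
    Transition,
    add_transition,
    ddqn_target,
    epsilon,
    huber,
    loss_and_grads,
    sample_batch,
    sampling_probabilities,
    train,
    update_priorities,
)


def fill_memory(mem, dim, n, rng, terminal_every=None):
    for k in range(n):
        term = terminal_every is not None and k % terminal_every == 0
        mem.add(
            Transition(rng.normal(0, 1, dim), int(rng.integers(1, 14)),
                       float(rng.choice([-1.0, 0.0, 1.0])), rng.normal(0, 1, dim), term)
        )
    return mem


class TestLearnerConfig:
    def test_full_scale_defaults(self):
        cfg = LearnerConfig()
        assert cfg.gamma == 0.9
        assert cfg.alpha == 0.6
        assert cfg.lr == 1e-6
        assert cfg.batch == 32
        assert cfg.memory_size == 10_000
        assert cfg.target_sync_every == 2000
        assert cfg.total_episodes == 10**6
        assert (cfg.eps_start, cfg.eps_final, cfg.eps_anneal_episodes) == (1.0, 0.1, 10_000)

    @pytest.mark.parametrize("kw", [{"gamma": 1.5}, {"alpha": -0.1}, {"beta": 2.0},
                                    {"priority_floor": 0.0}])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            LearnerConfig(**kw)


class TestReplayMemory:
    def test_first_insert_has_priority_one(self, rng):
        mem = ReplayMemory(10, 4)
        add_transition(mem, Transition(np.zeros(4), 1, 0.0, np.zeros(4), False))
        assert len(mem) == 1
        assert mem.priorities[0] == 1.0

    def test_ring_buffer_evicts_oldest(self, rng):
        mem = ReplayMemory(5, 4)
        for k in range(6):
            mem.add(Transition(np.full(4, float(k)), 1, 0.0, np.zeros(4), False))
        assert len(mem) == 5
        stored = {mem.s[i][0] for i in range(5)}
        assert 0.0 not in stored and 5.0 in stored

    def test_new_items_inherit_running_max_priority(self, rng):
        mem = fill_memory(ReplayMemory(10, 4), 4, 5, rng)
        update_priorities(mem, [2], [5.0], LearnerConfig())
        mem.add(Transition(np.zeros(4), 1, 0.0, np.zeros(4), False))
        assert mem.priorities[5] == pytest.approx(5.0 + 1e-6)


class TestSampling:
    def test_two_equal_priorities_sample_evenly(self, rng):
        mem = fill_memory(ReplayMemory(4, 4), 4, 2, rng)
        cfg = LearnerConfig(batch=2)
        counts = np.zeros(2)
        for _ in range(2000):
            _, idx, _ = sample_batch(mem, cfg, rng)
            counts += np.bincount(idx, minlength=2)
        assert counts[0] / counts.sum() == pytest.approx(0.5, abs=0.03)

    def test_alpha_one_probabilities_follow_priorities(self, rng):
        mem = fill_memory(ReplayMemory(4, 4), 4, 2, rng)
        mem.priorities[:2] = [1.0, 3.0]
        probs = sampling_probabilities(mem, alpha=1.0)
        np.testing.assert_allclose(probs, [0.25, 0.75])

    def test_alpha_zero_is_uniform_sampling(self, rng):
        mem = fill_memory(ReplayMemory(10, 4), 4, 10, rng)
        mem.priorities[:10] = np.arange(1.0, 11.0)
        probs = sampling_probabilities(mem, alpha=0.0)
        np.testing.assert_allclose(probs, np.full(10, 0.1))

    def test_beta_zero_makes_weights_unity(self, rng):
        mem = fill_memory(ReplayMemory(64, 4), 4, 64, rng)
        mem.priorities[:64] = rng.uniform(0.1, 5.0, 64)
        _, _, w = sample_batch(mem, LearnerConfig(beta=0.0), rng)
        np.testing.assert_allclose(w, 1.0)

    def test_undersized_memory_rejected(self, rng):
        mem = fill_memory(ReplayMemory(64, 4), 4, 8, rng)
        with pytest.raises(ValueError):
            sample_batch(mem, LearnerConfig(), rng)


class TestPriorities:
    def test_zero_error_keeps_floor(self, rng):
        mem = fill_memory(ReplayMemory(8, 4), 4, 4, rng)
        update_priorities(mem, [0], [0.0], LearnerConfig())
        assert mem.priorities[0] == pytest.approx(1e-6)
        assert mem.priorities[0] > 0

    def test_negative_error_uses_absolute_value(self, rng):
        mem = fill_memory(ReplayMemory(8, 4), 4, 4, rng)
        update_priorities(mem, [1], [-2.0], LearnerConfig())
        assert mem.priorities[1] == pytest.approx(2.0 + 1e-6)

    def test_priority_monotone_in_error(self, rng):
        mem = fill_memory(ReplayMemory(8, 4), 4, 8, rng)
        update_priorities(mem, np.arange(4), [0.1, 0.5, 2.0, 7.0], LearnerConfig())
        assert np.all(np.diff(mem.priorities[:4]) > 0)

    def test_bad_index_rejected(self, rng):
        mem = fill_memory(ReplayMemory(8, 4), 4, 4, rng)
        with pytest.raises(IndexError):
            update_priorities(mem, [9], [1.0], LearnerConfig())


class TestDdqnTarget:
    def batch_of(self, rng, n=16, dim=8, terminal=False):
        return {
            "s": rng.normal(0, 1, (n, dim)),
            "a": rng.integers(1, 14, n),
            "r": rng.choice([-1.0, 0.0, 1.0], n),
            "s2": rng.normal(0, 1, (n, dim)),
            "terminal": np.full(n, terminal),
        }

    def test_terminal_transitions_have_no_bootstrap(self, rng):
        batch = self.batch_of(rng, terminal=True)
        online = PolicyParams.initialize(8, rng)
        target = PolicyParams.initialize(8, rng)
        np.testing.assert_allclose(ddqn_target(batch, online, target, 0.9), batch["r"])

    def test_zero_discount_reduces_to_reward(self, rng):
        batch = self.batch_of(rng)
        online = PolicyParams.initialize(8, rng)
        np.testing.assert_allclose(ddqn_target(batch, online, online, 0.0), batch["r"])

    def test_identical_networks_reduce_to_plain_dqn_max(self, rng):
        batch = self.batch_of(rng)
        online = PolicyParams.initialize(8, rng)
        ys = ddqn_target(batch, online, online, 0.9)
        # brute-force max oracle, one item at a time
        for i in range(len(ys)):
            q = [forward(online, batch["s2"][i]).Q[a] for a in range(13)]
            assert ys[i] == pytest.approx(batch["r"][i] + 0.9 * max(q))

    def test_matches_brute_force_enumeration(self, rng):
        batch = self.batch_of(rng, n=32)
        online = PolicyParams.initialize(8, rng)
        target = PolicyParams.initialize(8, rng)
        ys = ddqn_target(batch, online, target, 0.9)
        for i in range(32):
            qo = forward(online, batch["s2"][i]).Q
            qt = forward(target, batch["s2"][i]).Q
            astar = max(range(13), key=lambda a: qo[a])
            assert ys[i] == pytest.approx(batch["r"][i] + 0.9 * qt[astar])


class TestLoss:
    def test_exact_targets_give_zero_loss_and_grads(self, rng):
        online = PolicyParams.initialize(8, rng)
        batch = {"s": rng.normal(0, 1, (8, 8)), "a": rng.integers(1, 14, 8)}
        q = forward(online, batch["s"]).Q
        targets = q[np.arange(8), batch["a"] - 1]
        loss, grads, td = loss_and_grads(batch, targets, np.ones(8), online)
        assert loss == 0.0
        np.testing.assert_allclose(td, 0.0, atol=1e-12)
        for g in grads.values():
            np.testing.assert_allclose(g, 0.0, atol=1e-12)

    @pytest.mark.parametrize("residual,expected", [(0.5, 0.125), (10.0, 9.5)])
    def test_huber_piecewise_values(self, residual, expected):
        assert huber(np.array([residual]))[0] == pytest.approx(expected)

    @pytest.mark.parametrize("residual,expected", [(0.5, 0.125), (10.0, 9.5)])
    def test_per_item_loss_through_network(self, rng, residual, expected):
        online = PolicyParams.initialize(8, rng)
        batch = {"s": rng.normal(0, 1, (4, 8)), "a": rng.integers(1, 14, 4)}
        q = forward(online, batch["s"]).Q
        targets = q[np.arange(4), batch["a"] - 1] + residual
        loss, _, _ = loss_and_grads(batch, targets, np.ones(4), online)
        assert loss == pytest.approx(expected)

    def test_loss_invariant_under_batch_permutation(self, rng):
        online = PolicyParams.initialize(8, rng)
        batch = {"s": rng.normal(0, 1, (16, 8)), "a": rng.integers(1, 14, 16)}
        targets = rng.normal(0, 1, 16)
        weights = rng.uniform(0.2, 1.0, 16)
        loss1, _, _ = loss_and_grads(batch, targets, weights, online)
        perm = rng.permutation(16)
        loss2, _, _ = loss_and_grads(
            {"s": batch["s"][perm], "a": batch["a"][perm]}, targets[perm], weights[perm],
            online,
        )
        assert loss2 == pytest.approx(loss1)

    def test_gradients_match_finite_differences(self, rng):
        online = PolicyParams.initialize(4, rng)
        batch = {"s": rng.normal(0, 1, (6, 4)), "a": rng.integers(1, 14, 6)}
        targets = rng.normal(0, 1, 6)
        weights = rng.uniform(0.2, 1.0, 6)
        _, grads, _ = loss_and_grads(batch, targets, weights, online)
        eps = 1e-6
        for name in ("w1", "ba2", "wv2", "b2"):
            arr = getattr(online, name)
            flat = arr.reshape(-1)
            g = grads[name].reshape(-1)
            for j in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _, _ = loss_and_grads(batch, targets, weights, online)
                flat[j] = orig - eps
                lm, _, _ = loss_and_grads(batch, targets, weights, online)
                flat[j] = orig
                assert g[j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)


class TestEpsilonSchedule:
    @pytest.mark.parametrize(
        "episode,expected",
        [(0, 1.0), (5000, 0.55), (10_000, 0.1), (500_000, 0.1)],
    )
    def test_linear_anneal_then_constant(self, episode, expected):
        assert epsilon(episode, LearnerConfig()) == pytest.approx(expected)

    def test_negative_episode_rejected(self):
        with pytest.raises(ValueError):
            epsilon(-1, LearnerConfig())


class TestCompiledPathEquivalence:
    """The numba fast path must agree with the numpy reference ops."""

    def random_world(self, cfg, rng):
        w = env.reset(cfg, rng)
        w.vel[:] = rng.normal(0, 0.5, w.vel.shape)
        return w

    def test_featurize_matches_reference(self, two_slow_shared, rng):
        for _ in range(20):
            w = self.random_world(two_slow_shared, rng)
            for agent in range(3):
                out = np.empty(12)
                _fastloop.featurize(w.pos, w.vel, agent, 2, out)
                ref = build_state_vector(w, agent, two_slow_shared)
                np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_q_forward_matches_reference(self, rng):
        params = PolicyParams.initialize(8, rng)
        p32 = tuple(np.ascontiguousarray(a, dtype=np.float32) for a in params.arrays())
        for _ in range(10):
            s = rng.normal(0, 1, 8)
            q_fast = _fastloop.q_forward_one(*p32, s.astype(np.float32))
            q_ref = forward(params, s).Q
            np.testing.assert_allclose(q_fast, q_ref, rtol=1e-4, atol=1e-5)

    def test_env_step_matches_reference(self, two_slow_shared, rng):
        cfg = two_slow_shared
        for trial in range(25):
            w = self.random_world(cfg, rng)
            actions = rng.integers(1, 14, 3)
            new_pos = np.empty((3, 2))
            new_vel = np.empty((3, 2))
            rewards = np.empty(3)
            code, _ = _fastloop.env_step(
                w.pos, w.vel, actions, 2, cfg.mobility, cfg.prey_accel, cfg.damping,
                cfg.dt, cfg.agent_diameter, cfg.arena_half_width, w.step + 1,
                cfg.max_steps, cfg.sharing == "shared", new_pos, new_vel, rewards,
            )
            ref = env.step(w, actions, cfg)
            np.testing.assert_allclose(new_pos, ref.state.pos, atol=1e-12)
            np.testing.assert_allclose(new_vel, ref.state.vel, atol=1e-12)
            np.testing.assert_array_equal(rewards, ref.rewards)
            assert learning.EVENT_CODES[int(code)] == ref.event

    def test_train_step_matches_numpy_pipeline(self, rng):
        dim, B = 8, 32
        params = PolicyParams.initialize(dim, rng)
        target = PolicyParams.initialize(dim, rng, )
        online32 = tuple(np.ascontiguousarray(a, np.float32) for a in params.arrays())
        target32 = tuple(np.ascontiguousarray(a, np.float32) for a in target.arrays())
        m32 = tuple(np.zeros_like(a) for a in online32)
        v32 = tuple(np.zeros_like(a) for a in online32)
        batch = {
            "s": rng.normal(0, 1, (B, dim)),
            "a": rng.integers(1, 14, B),
            "r": rng.choice([-1.0, 0.0, 1.0], B),
            "s2": rng.normal(0, 1, (B, dim)),
            "terminal": rng.random(B) < 0.2,
        }
        weights = rng.uniform(0.2, 1.0, B).astype(np.float32)
        td_fast = np.zeros(B, dtype=np.float32)
        loss_fast = _fastloop.train_step(
            online32, target32, m32, v32, 1,
            batch["s"].astype(np.float32), batch["a"].astype(np.int64),
            batch["r"].astype(np.float32), batch["s2"].astype(np.float32),
            batch["terminal"].astype(np.float32), weights,
            np.float32(0.9), np.float32(1e-3), td_fast,
        )
        # reference: float64 ops composed from the public numpy pieces
        start32 = PolicyParams(*(a.astype(np.float64) for a in
                                 tuple(np.ascontiguousarray(x, np.float32)
                                       for x in params.arrays())))
        ys = ddqn_target(batch, start32, target, 0.9)
        loss_ref, grads, td_ref = loss_and_grads(batch, ys, weights.astype(float), start32)
        opt = Adam(start32, lr=1e-3)
        opt.step(start32, grads)
        assert loss_fast == pytest.approx(loss_ref, rel=1e-3, abs=1e-5)
        np.testing.assert_allclose(td_fast, td_ref, rtol=1e-3, atol=1e-3)
        for fast, ref in zip(online32, start32.arrays()):
            np.testing.assert_allclose(fast, ref, rtol=5e-3, atol=5e-4)


class TestTrain:
    def test_zero_episodes_returns_untouched_initialization(self, solo_fast):
        res = train(solo_fast, LearnerConfig.desk(total_episodes=0), seed=3)
        rng = np.random.default_rng(3)
        expected = [PolicyParams.initialize(8, rng) for _ in range(2)]
        for got, want in zip(res.params, expected):
            assert got == want

    def test_same_seed_reproduces_checkpoints(self, solo_fast):
        cfg = LearnerConfig.desk(total_episodes=60)
        a = train(solo_fast, cfg, seed=9)
        b = train(solo_fast, cfg, seed=9)
        assert a.log["length"].equals(b.log["length"])
        for (ea, pa), (eb, pb) in zip(a.checkpoints, b.checkpoints):
            assert ea == eb
            for x, y in zip(pa, pb):
                assert x == y

    def test_weights_move_and_log_is_complete(self, solo_fast):
        cfg = LearnerConfig.desk(total_episodes=60)
        res = train(solo_fast, cfg, seed=5)
        rng = np.random.default_rng(5)
        init = [PolicyParams.initialize(8, rng) for _ in range(2)]
        assert not np.allclose(res.params[0].w1, init[0].w1)
        assert len(res.log) == 60
        assert set(res.log["event"]).issubset(
            {"capture", "prey_out", "predator_out", "timeout"}
        )
        assert res.log["epsilon"].iloc[0] == pytest.approx(1.0)
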