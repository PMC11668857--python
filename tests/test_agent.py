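import numpy as np
import pytest
from scipy import stats

import rlfocus as rf
from conftest import tabular_q_learning


class TestSelectAction:
    def test_greedy_argmax(self):
        rng = np.random.default_rng(0)
        assert rf.select_action([1.0, 3.0, 2.0], 0.0, rng) == 1

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert rf.select_action([2.0, 2.0, 1.0], 0.0, rng) == 0

    def test_fully_random_is_uniform(self):
        rng = np.random.default_rng(1)
        counts = np.zeros(7)
        n = 10_000
        for _ in range(n):
            counts[rf.select_action(np.zeros(7) + np.arange(7), 1.0, rng)] += 1
        chi2 = ((counts - n / 7) ** 2 / (n / 7)).sum()
        assert stats.chi2.sf(chi2, df=6) > 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rf.select_action([], 0.0, np.random.default_rng(0))


class TestBellmanTarget:
    @pytest.mark.parametrize(
        ("r", "gamma", "maxq", "done", "expected"),
        [
            (5.0, 0.9, 2.0, True, 5.0),
            (1.0, 0.9, 2.0, False, 2.8),
            (1.0, 0.0, 7.0, False, 1.0),
        ],
    )
    def test_hand_values(self, r, gamma, maxq, done, expected):
        assert rf.bellman_target(r, gamma, maxq, done) == pytest.approx(expected)


class TestQNetwork:
    @pytest.mark.parametrize("res", [8, 32, 64, 84])
    def test_forward_shapes_across_resolutions(self, res):
        net = rf.QNetwork(res, 5, np.random.default_rng(0))
        q = net.forward(np.zeros((3, res, res), dtype=np.float32))
        assert q.shape == (3, 5)

    def test_gradients_match_finite_differences(self):
        """Backprop against a central-difference oracle on a tiny network."""
        rng = np.random.default_rng(3)
        net = rf.QNetwork(8, 3, rng, conv_channels=(2, 3), fc_units=4)
        x = rng.random((2, 8, 8)).astype(np.float32)
        tgt = rng.random((2, 3)).astype(np.float32)

        def loss():
            q = net.forward(x)
            return float(np.mean((q - tgt) ** 2))

        q, cache = net.forward(x, want_cache=True)
        dq = (2.0 / q.size) * (q - tgt)
        grads = net.backward(dq, cache)
        for name in ("W1", "W2", "W3", "W4", "Wv", "b2", "bv"):
            w = net.params[name]
            flat = w.ravel()
            for k in [0, flat.size // 2, flat.size - 1]:
                eps = 1e-3
                old = flat[k]
                flat[k] = old + eps
                up = loss()
                flat[k] = old - eps
                down = loss()
                flat[k] = old
                num = (up - down) / (2 * eps)
                assert grads[name].ravel()[k] == pytest.approx(num, abs=2e-3), name

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rf.AgentConfig(replay_capacity=0)
        with pytest.raises(ValueError):
            rf.AgentConfig(gamma=1.5)
        with pytest.raises(ValueError):
            rf.AgentConfig(n_step=0)


@pytest.fixture(scope="module")
def toy_training():
    lst = rf.build_dataset_list(
        2, ["regular_grid"], n_frames=16, seed=3, size=8,
        psf_sigma0=0.3, psf_slope=0.25, noise_sd=0.01, astigmatism=0.4,
    )
    aset = rf.build_action_set(2, 3)
    # the package's documented training configuration (printed-form reward)
    env = rf.AutofocusEnv(lst, aset, obs_resolution=8, max_steps=50,
                          reward_params=rf.RewardParams(literal_sign=True))
    cfg = rf.AgentConfig(
        input_resolution=8, n_actions=3, train_steps=5000, eval_every=2500,
        eval_episodes=30, learning_rate=1e-3, replay_capacity=4000,
        target_update_period=250, seed=0,
    )
    agent, log = rf.train(env, cfg)
    return lst, env, cfg, agent, log


class TestTraining:
    def test_same_seed_reproduces_training_log(self, toy_training):
        lst, env, cfg, agent, log = toy_training
        env2 = rf.AutofocusEnv(
            lst, env.action_set, obs_resolution=8, max_steps=50,
            reward_params=rf.RewardParams(literal_sign=True),
        )
        agent2, log2 = rf.train(env2, cfg)
        assert log.equals(log2)
        for k, v in agent.network.params.items():
            assert np.array_equal(v, agent2.network.params[k])

    def test_toy_convergence_and_tabular_policy_agreement(self, toy_training):
        """The function-approximation agent should solve the toy MDP about as
        well as a long-run tabular Q-learner on the same environment."""
        lst, env, cfg, agent, log = toy_training
        rep = rf.evaluate(agent, lst, n_episodes=300, seed=99)
        q_tab = tabular_q_learning(
            rf.AutofocusEnv(lst, env.action_set, obs_resolution=8, max_steps=50,
                            reward_params=rf.RewardParams(literal_sign=True)),
            n_steps=60_000, gamma=cfg.gamma,
        )
        # tabular greedy rollout as reference
        tab_env = rf.AutofocusEnv(lst, env.action_set, obs_resolution=8, max_steps=50,
                                  reward_params=rf.RewardParams(literal_sign=True))

        def tab_policy(e, obs, rng):
            return int(np.argmax(q_tab[e.current_stack_index, e.current_frame_index]))

        tab_rep = rf.run_policy(tab_env, tab_policy, 300, np.random.default_rng(5))
        assert rep.success_rate >= 0.9 * tab_rep.success_rate - 0.05
        # greedy policies agree on most states
        agree = 0
        total = 0
        for s in range(len(lst)):
            for i in range(lst[0].n_frames):
                obs = env.observation(s, i, 1)
                a_net = int(np.argmax(agent.q_values(obs)))
                a_tab = int(np.argmax(q_tab[s, i]))
                agree += a_net == a_tab
                total += 1
        assert agree / total >= 0.6

    def test_agent_checkpoint_roundtrip(self, toy_training, tmp_path):
        lst, env, cfg, agent, log = toy_training
        agent.save(tmp_path / "ckpt")
        back = rf.DQNAgent.load(tmp_path / "ckpt")
        obs = env.observation(0, 5, 1)
        assert np.allclose(agent.q_values(obs), back.q_values(obs))
        assert back.action_set.control_factors == agent.action_set.control_factors


class TestEvaluate:
    def test_oracle_policy_scores_perfectly(self, toy_dataset_list, basic_action_set):
        env = rf.AutofocusEnv(toy_dataset_list, basic_action_set, obs_resolution=8)

        def oracle(e, obs, rng):
            d = e.current_stack.focus_index - e.current_frame_index
            if d == 0:
                return e.action_set.stop_index
            step = 1 if d > 0 else -1
            return e.action_set.control_factors.index(step)

        rep = rf.run_policy(env, oracle, 200, np.random.default_rng(0))
        assert rep.success_rate == 1.0
        assert rep.accuracy_rate == 1.0

    def test_always_stop_success_equals_tolerance_fraction(self, basic_action_set):
        """Uniform starts on a 100-frame stack: only starts within +-2 frames
        of focus succeed, i.e. exactly 5/100 by enumeration."""
        lst = rf.build_dataset_list(
            1, ["speckle"], n_frames=100, seed=8, size=8, noise_sd=0.0
        )
        env = rf.AutofocusEnv(lst, basic_action_set, obs_resolution=8)
        focus = lst[0].focus_index
        hits = sum(1 for start in range(100) if abs(start - focus) <= 2)
        assert hits == 5

        def always_stop(e, obs, rng):
            return e.action_set.stop_index

        rep = rf.run_policy(env, always_stop, 4000, np.random.default_rng(1))
        assert rep.success_rate == pytest.approx(5 / 100, abs=0.02)

    def test_greedy_evaluation_deterministic(self, toy_training):
        lst, env, cfg, agent, log = toy_training
        a = rf.evaluate(agent, lst, n_episodes=50, seed=3)
        b = rf.evaluate(agent, lst, n_episodes=50, seed=3)
        assert a == b

    def test_bad_episode_count_rejected(self, toy_training):
        lst, env, cfg, agent, log = toy_training
        with pytest.raises(ValueError):
            rf.evaluate(agent, lst, n_episodes=0)
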