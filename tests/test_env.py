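import numpy as np
import pytest

import rlfocus as rf
from rlfocus.reward import RewardParams


@pytest.fixture()
def env(toy_dataset_list, basic_action_set):
    return rf.AutofocusEnv(
        toy_dataset_list, basic_action_set, obs_resolution=8, max_steps=50
    )


class TestEpisodeMetrics:
    @pytest.mark.parametrize(
        ("final", "focus", "dev", "success", "accurate"),
        [
            (52, 50, 0.2, True, False),  # inclusive threshold boundary
            (50, 50, 0.0, True, True),
            (57, 50, 0.7, False, False),
        ],
    )
    def test_deviation_and_flags(self, final, focus, dev, success, accurate):
        d, s, a = rf.episode_metrics(final, focus, 0.1)
        assert d == pytest.approx(dev)
        assert (s, a) == (success, accurate)

    def test_negative_indices_rejected(self):
        with pytest.raises(ValueError):
            rf.episode_metrics(-1, 5, 0.1)


class TestReset:
    def test_empty_list_rejected(self, basic_action_set):
        with pytest.raises(ValueError):
            rf.AutofocusEnv(rf.StateDatasetList(stacks=[]), basic_action_set)

    def test_single_stack_always_selected(self, toy_dataset_list, basic_action_set):
        single = rf.StateDatasetList(stacks=[toy_dataset_list[0]])
        env = rf.AutofocusEnv(single, basic_action_set, obs_resolution=8)
        rng = np.random.default_rng(0)
        for _ in range(10):
            env.reset(rng)
            assert env.current_stack_index == 0

    def test_fixed_seed_reproduces_initialization(self, env):
        a = env.reset(np.random.default_rng(7))
        sa, ia = env.current_stack_index, env.current_frame_index
        b = env.reset(np.random.default_rng(7))
        assert (env.current_stack_index, env.current_frame_index) == (sa, ia)
        assert np.array_equal(a.frame, b.frame)

    def test_stack_selection_uniform_over_resets(self, basic_action_set):
        lst = rf.build_dataset_list(
            10, ["speckle"], n_frames=8, seed=5, size=8, noise_sd=0.0
        )
        env = rf.AutofocusEnv(lst, basic_action_set, obs_resolution=8)
        rng = np.random.default_rng(123)
        counts = np.zeros(10)
        n = 10_000
        for _ in range(n):
            env.reset(rng)
            counts[env.current_stack_index] += 1
        expected = n / 10
        sd = np.sqrt(n * 0.1 * 0.9)
        assert np.all(np.abs(counts - expected) <= 3 * sd)


class TestStep:
    def _reset_at(self, env, stack_idx, frame_idx):
        rng = np.random.default_rng(0)
        env.reset(rng)
        env._stack_idx = stack_idx
        env._index = frame_idx
        env._start_index = frame_idx
        return env

    def test_stop_at_focus_is_accurate_success(self, env):
        focus = env.dataset_list[0].focus_index
        self._reset_at(env, 0, focus)
        _, _, done, info = env.step(env.action_set.stop_index)
        rec = info["record"]
        assert done and rec.success and rec.accurate and rec.steps == 1

    def test_stop_three_frames_out_fails(self, env):
        focus = env.dataset_list[0].focus_index
        self._reset_at(env, 0, focus - 3)
        _, _, done, info = env.step(env.action_set.stop_index)
        rec = info["record"]
        assert done and not rec.success
        assert rec.deviation_volts == pytest.approx(0.3)

    def test_stop_at_tolerance_boundary_succeeds(self, env):
        focus = env.dataset_list[0].focus_index
        self._reset_at(env, 0, focus - 2)
        _, _, _, info = env.step(env.action_set.stop_index)
        assert info["record"].success and not info["record"].accurate

    def test_truncation_at_step_budget(self, env):
        env.reset(np.random.default_rng(1))
        move = env.action_set.control_factors.index(1)
        for k in range(50):
            _, _, done, info = env.step(move)
        assert done and info["truncated"]
        assert info["record"].steps == 50
        assert not info["record"].success

    def test_step_after_done_rejected(self, env):
        env.reset(np.random.default_rng(1))
        env.step(env.action_set.stop_index)
        with pytest.raises(RuntimeError):
            env.step(0)

    def test_action_index_out_of_range_rejected(self, env):
        env.reset(np.random.default_rng(1))
        with pytest.raises(ValueError):
            env.step(3)

    def test_moves_clip_at_sweep_edges(self, env):
        self._reset_at(env, 0, 0)
        down = env.action_set.control_factors.index(-1)
        env.step(down)
        assert env.current_frame_index == 0


class TestBookkeeping:
    def test_return_equals_sum_of_rewards(self, env):
        rng = np.random.default_rng(3)
        for _ in range(20):
            env.reset(rng)
            total = 0.0
            done = False
            while not done:
                a = int(rng.integers(len(env.action_set)))
                _, r, done, info = env.step(a)
                total += r
            assert info["record"].episode_return == pytest.approx(total)

    def test_accurate_implies_success(self, env):
        rng = np.random.default_rng(4)
        for _ in range(200):
            env.reset(rng)
            done = False
            while not done:
                _, _, done, info = env.step(int(rng.integers(len(env.action_set))))
            rec = info["record"]
            assert (not rec.accurate) or rec.success
            assert rec.steps <= env.max_steps

    def test_observations_stay_in_unit_range(self, env):
        rng = np.random.default_rng(5)
        obs = env.reset(rng)
        assert obs.frame.min() >= 0.0 and obs.frame.max() <= 1.0
        obs, _, _, _ = env.step(0)
        assert obs.frame.min() >= 0.0 and obs.frame.max() <= 1.0

    def test_rewards_follow_eq_components(self, toy_dataset_list, basic_action_set):
        # with only the stop gate on, a correct stop pays exactly mu
        params = RewardParams(gates=rf.RewardGates(False, False, True, False))
        env = rf.AutofocusEnv(
            toy_dataset_list, basic_action_set, reward_params=params, obs_resolution=8
        )
        env.reset(np.random.default_rng(0))
        env._stack_idx, env._index = 0, toy_dataset_list[0].focus_index
        _, r, _, _ = env.step(env.action_set.stop_index)
        assert r == pytest.approx(params.mu)


class TestEvalReport:
    def test_histogram_mass_conserved(self, env):
        rng = np.random.default_rng(6)
        records = []
        for _ in range(50):
            env.reset(rng)
            done = False
            while not done:
                _, _, done, info = env.step(int(rng.integers(len(env.action_set))))
            records.append(info["record"])
        rep = rf.EvalReport.from_records(records)
        assert sum(rep.deviation_histogram.values()) == rep.n_episodes
        assert rep.rmse_volts >= rep.mae_volts >= 0.0
        assert rep.success_rate >= rep.accuracy_rate
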