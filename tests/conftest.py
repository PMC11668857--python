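import numpy as np
import pytest

import rlfocus as rf


@pytest.fixture(scope="session")
def small_noiseless_stack() -> rf.FocalStack:
    """64x64, 40-frame noiseless stack with an interior focus."""
    tex = rf.make_texture("regular_grid", 64, 0.9, seed=11)
    return rf.render_stack(
        tex, n_frames=40, focus_index=17, psf_sigma0=0.15, psf_slope=0.09,
        noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def toy_dataset_list() -> rf.StateDatasetList:
    """Two tiny 16-frame stacks of 8x8 frames (fast env/agent fixtures)."""
    return rf.build_dataset_list(
        2, ["regular_grid"], n_frames=16, seed=3, size=8,
        psf_sigma0=0.3, psf_slope=0.25, noise_sd=0.01, astigmatism=0.4,
    )


@pytest.fixture(scope="session")
def basic_action_set() -> rf.ActionSet:
    return rf.build_action_set(2, 3)


def tabular_q_learning(
    env: rf.AutofocusEnv,
    n_steps: int,
    seed: int = 0,
    alpha: float = 0.2,
    gamma: float = 0.7,
    epsilon: float = 0.3,
) -> np.ndarray:
    """Independent tabular Q-learning oracle on the same MDP.

    States are (stack, frame) pairs — the information a perfect perceiver
    could extract from the observation; used as a reference policy for the
    function-approximation agent.
    """
    rng = np.random.default_rng(seed)
    n_stacks = len(env.dataset_list)
    n_actions = len(env.action_set)
    q = np.zeros((n_stacks, env.n_frames, n_actions))
    env.reset(rng)
    for _ in range(n_steps):
        s, i = env.current_stack_index, env.current_frame_index
        if rng.random() < epsilon:
            a = int(rng.integers(n_actions))
        else:
            a = int(np.argmax(q[s, i]))
        _, r, done, info = env.step(a)
        target = r
        if not done:
            target += gamma * q[s, env.current_frame_index].max()
        elif info["truncated"]:
            target = r + gamma * q[s, env.current_frame_index].max()
        q[s, i, a] += alpha * (target - q[s, i, a])
        if done:
            env.reset(rng)
    return q
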