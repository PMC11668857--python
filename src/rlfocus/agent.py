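"""Value-based deep-RL autofocus agent.

A DQN: a small convolutional Q-network over grayscale frame observations,
an experience-replay buffer, an epsilon-greedy behaviour policy and a
periodically synchronized target network.  Training samples episodes by
random draws from the state-dataset list (the environment does the
sampling); evaluation runs the greedy policy.

The network, backpropagation and Adam optimizer are implemented directly in
numpy (im2col convolutions), sized for desk-scale CPU training: two stride-2+
conv layers and two fully connected layers.  Rewards are scaled inside the
agent (default 0.01) so Q-values sit near unit magnitude; this is an
optimizer conditioning choice only and does not alter the environment's
reward bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .actions import ActionSet
from .env import AutofocusEnv, EvalReport, Observation
from .reward import RewardParams
from .simulate import StateDatasetList

__all__ = [
    "AgentConfig",
    "Transition",
    "QNetwork",
    "DQNAgent",
    "select_action",
    "bellman_target",
    "train",
    "evaluate",
    "run_policy",
]


@dataclass(frozen=True)
class AgentConfig:
    """Hyperparameters of the DQN agent and its training loop."""

    input_resolution: int = 84
    n_actions: int = 7
    gamma: float = 0.8
    learning_rate: float = 1e-4
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_steps: int | None = None  # default: half of train_steps
    replay_capacity: int = 10_000
    batch_size: int = 32
    target_update_period: int = 500
    train_steps: int = 50_000
    eval_every: int = 5_000
    eval_episodes: int = 100
    update_every: int = 1
    n_step: int = 3  # multi-step return length (1 = classic one-step target)
    double_dqn: bool = True  # online-net action selection in the target
    dueling: bool = True  # value + advantage heads
    train_max_steps: int | None = None  # shorter truncation during training only
    terminal_fraction: float = 0.25  # stratified replay: share of stop transitions
    aux_weight: float = 1.0  # self-supervised directional-sharpness auxiliary loss
    use_sharpness_features: bool = True  # multi-scale gradient energies as FC inputs
    dyna_fraction: float = 0.5  # batch share synthesized from the stack dataset
    augment_flips: bool = True  # random flips of whole update batches
    noise_augment: float = 0.02  # fresh sensor noise per batch presentation
    conv_channels: tuple[int, int] = (8, 16)
    learn_start: int | None = None  # default: 10 * batch_size
    reward_scale: float = 0.01
    grad_clip: float = 10.0
    use_step_feature: bool = True
    standardize_obs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        for name in ("epsilon_start", "epsilon_end"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "input_resolution",
            "n_actions",
            "replay_capacity",
            "batch_size",
            "target_update_period",
            "train_steps",
            "eval_every",
            "update_every",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.reward_scale <= 0:
            raise ValueError("learning_rate and reward_scale must be positive")
        if self.n_step < 1:
            raise ValueError("n_step must be >= 1")


@dataclass(frozen=True)
class Transition:
    """One replay entry (observations stored by stack/frame index)."""

    stack_idx: int
    frame_idx: int
    n: int
    action: int
    reward: float
    next_frame_idx: int
    next_n: int
    done: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.reward):
            raise ValueError("transition reward must be finite")


def select_action(q_values: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy action choice; ties break to the lowest index."""
    q = np.asarray(q_values, dtype=np.float64).ravel()
    if q.size == 0:
        raise ValueError("q_values must be non-empty")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(0, q.size))
    return int(np.argmax(q))


def bellman_target(r: float, gamma: float, max_next_q: float, done: bool) -> float:
    """One-step TD target r + gamma * max_a' Q(s', a') * (1 - done)."""
    return float(r + gamma * max_next_q * (1.0 - float(done)))


# ---------------------------------------------------------------------------
# numpy Q-network
# ---------------------------------------------------------------------------


FEATURE_SCALES = (0.0, 1.5, 4.0)


def sharpness_features(frames: np.ndarray) -> np.ndarray:
    """Multi-scale directional gradient energies of standardized frames.

    For each smoothing scale, the log mean squared horizontal and vertical
    first differences — six texture-robust numbers that encode blur level
    (energy falls with defocus) and defocus sign (the astigmatic PSF
    elongation skews the x/y ratio).  Computed purely from the observed
    pixels; appended to the Q-network's fully connected layer.
    """
    from scipy import ndimage

    frames = np.asarray(frames, dtype=np.float32)
    mean = frames.mean(axis=(-2, -1), keepdims=True)
    sd = frames.std(axis=(-2, -1), keepdims=True)
    f = (frames - mean) / (sd + 1e-6)
    cols = []
    for s in FEATURE_SCALES:
        g = ndimage.gaussian_filter(f, (0, s, s)) if s > 0 else f
        dx = np.diff(g, axis=-1)
        dy = np.diff(g, axis=-2)
        cols.append(np.log1p((dx * dx).mean(axis=(-2, -1))))
        cols.append(np.log1p((dy * dy).mean(axis=(-2, -1))))
    return np.stack(cols, axis=-1).astype(np.float32)


def _im2col(x: np.ndarray, k: int, s: int) -> np.ndarray:
    """(B, C, H, W) -> (B, oh, ow, C*k*k) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    b, c, oh, ow = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, oh, ow, c * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, s: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    b, c, h, w = x_shape
    oh = (h - k) // s + 1
    ow = (w - k) // s + 1
    dwin = dcols.reshape(b, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + oh * s : s, j : j + ow * s : s] += dwin[..., i, j]
    return dx


class QNetwork:
    """Two conv layers + two fully connected layers, ReLU activations.

    Geometry adapts to the input resolution so toy inputs (down to 8x8)
    remain valid; an optional scalar step-count feature is appended to the
    flattened convolutional features.
    """

    def __init__(
        self,
        input_resolution: int,
        n_actions: int,
        rng: np.random.Generator,
        conv_channels: tuple[int, int] = (8, 16),
        fc_units: int = 128,
        n_extras: int = 0,
        dueling: bool = True,
    ) -> None:
        h = int(input_resolution)
        if h < 8:
            raise ValueError("input resolution must be >= 8")
        c1, c2 = conv_channels
        self.k1 = min(8, h)
        self.s1 = 4 if h >= 16 else max(1, self.k1 // 2)
        h1 = (h - self.k1) // self.s1 + 1
        self.k2 = min(4, h1)
        self.s2 = 2 if h1 >= 8 else 1
        h2 = (h1 - self.k2) // self.s2 + 1
        self.h, self.h1, self.h2 = h, h1, h2
        self.c1, self.c2 = c1, c2
        self.n_actions = int(n_actions)
        self.n_extras = int(n_extras)
        self.dueling = dueling
        flat = h2 * h2 * c2 + self.n_extras
        self.flat = flat

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params = {
            "W1": he((self.k1 * self.k1, c1), self.k1 * self.k1),
            "b1": np.zeros(c1, dtype=np.float32),
            "W2": he((c1 * self.k2 * self.k2, c2), c1 * self.k2 * self.k2),
            "b2": np.zeros(c2, dtype=np.float32),
            "W3": he((flat, fc_units), flat),
            "b3": np.zeros(fc_units, dtype=np.float32),
            # small output layers so initial Q-values start near zero
            "W4": (rng.standard_normal((fc_units, self.n_actions)) * 1e-3).astype(np.float32),
            "b4": np.zeros(self.n_actions, dtype=np.float32),
        }
        if dueling:
            # separate state-value head: Q = V + A - mean(A); keeps the shared
            # value accurate where per-action differences are tiny (far field)
            self.params["Wv"] = (rng.standard_normal((fc_units, 1)) * 1e-3).astype(np.float32)
            self.params["bv"] = np.zeros(1, dtype=np.float32)
        # auxiliary head: predicts the observation's own horizontal/vertical
        # gradient energies (self-supervised; targets computed from the input
        # pixels), shaping trunk features that encode blur level + direction
        self.params["Wa"] = he((fc_units, 2), fc_units)
        self.params["ba"] = np.zeros(2, dtype=np.float32)

    def copy_from(self, other: "QNetwork") -> None:
        for k, v in other.params.items():
            self.params[k] = v.copy()

    def forward(
        self, frames: np.ndarray, extras: np.ndarray | None = None, want_cache: bool = False
    ):
        """Q-values for a batch of frames (B, H, W) plus optional scalar
        extras (B, n_extras); optionally keep the backprop cache."""
        p = self.params
        x = np.ascontiguousarray(frames, dtype=np.float32)[:, None, :, :]
        cols1 = _im2col(x, self.k1, self.s1)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        x1 = np.ascontiguousarray(a1.transpose(0, 3, 1, 2))
        cols2 = _im2col(x1, self.k2, self.s2)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(len(frames), -1)
        if self.n_extras:
            if extras is None:
                raise ValueError(f"this network expects {self.n_extras} extra features")
            extras = np.asarray(extras, dtype=np.float32).reshape(len(frames), self.n_extras)
            flat = np.concatenate([flat, extras], axis=1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        adv = a3 @ p["W4"] + p["b4"]
        if self.dueling:
            v = a3 @ p["Wv"] + p["bv"]
            q = v + adv - adv.mean(axis=1, keepdims=True)
        else:
            q = adv
        if not want_cache:
            return q
        cache = {
            "x_shape": x.shape, "x1_shape": x1.shape,
            "cols1": cols1, "z1": z1, "cols2": cols2, "z2": z2,
            "flat": flat, "z3": z3, "a3": a3,
        }
        return q, cache

    def aux_predict(self, cache: dict) -> np.ndarray:
        """Auxiliary head output (B, 2) from a forward cache."""
        return cache["a3"] @ self.params["Wa"] + self.params["ba"]

    def backward(
        self, dq: np.ndarray, cache: dict, daux: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Gradients of the loss wrt parameters, given dLoss/dQ.

        ``daux`` optionally carries dLoss/d(aux head output); its gradient
        joins the Q-loss gradient in the shared trunk.
        """
        p = self.params
        dq = dq.astype(np.float32)
        grads: dict[str, np.ndarray] = {}
        if self.dueling:
            # Q = V + A - mean(A): dV = sum_a dQ, dA = dQ - mean_a(dQ)
            dv = dq.sum(axis=1, keepdims=True)
            dadv = dq - dq.mean(axis=1, keepdims=True)
            grads["Wv"] = cache["a3"].T @ dv
            grads["bv"] = dv.sum(axis=0)
            grads["W4"] = cache["a3"].T @ dadv
            grads["b4"] = dadv.sum(axis=0)
            da3 = dv @ p["Wv"].T + dadv @ p["W4"].T
        else:
            grads["W4"] = cache["a3"].T @ dq
            grads["b4"] = dq.sum(axis=0)
            da3 = dq @ p["W4"].T
        if daux is not None:
            daux = daux.astype(np.float32)
            grads["Wa"] = cache["a3"].T @ daux
            grads["ba"] = daux.sum(axis=0)
            da3 = da3 + daux @ p["Wa"].T
        dz3 = da3 * (cache["z3"] > 0)
        grads["W3"] = cache["flat"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        if self.n_extras:
            dflat = dflat[:, : -self.n_extras]
        b = len(dflat)
        dz2 = dflat.reshape(b, self.h2, self.h2, self.c2) * (cache["z2"] > 0)
        grads["W2"] = cache["cols2"].reshape(-1, p["W2"].shape[0]).T @ dz2.reshape(-1, self.c2)
        grads["b2"] = dz2.sum(axis=(0, 1, 2))
        dcols2 = dz2 @ p["W2"].T
        dx1 = _col2im(dcols2, cache["x1_shape"], self.k2, self.s2)
        dz1 = dx1.transpose(0, 2, 3, 1) * (cache["z1"] > 0)
        grads["W1"] = cache["cols1"].reshape(-1, p["W1"].shape[0]).T @ dz1.reshape(-1, self.c1)
        grads["b1"] = dz1.sum(axis=(0, 1, 2))
        return grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# agent
# ---------------------------------------------------------------------------


class DQNAgent:
    """A trained (or training) Q-network bound to its action set and settings."""

    def __init__(
        self,
        config: AgentConfig,
        action_set: ActionSet,
        reward_params: RewardParams | None = None,
        max_steps: int = 50,
        measure_name: str = "energy",
    ) -> None:
        if len(action_set) != config.n_actions:
            config = replace(config, n_actions=len(action_set))
        self.config = config
        self.action_set = action_set
        self.reward_params = reward_params if reward_params is not None else RewardParams()
        self.max_steps = max_steps
        self.measure_name = measure_name
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        self.network = QNetwork(
            config.input_resolution,
            config.n_actions,
            rng,
            conv_channels=tuple(config.conv_channels),
            n_extras=self.n_extras,
            dueling=config.dueling,
        )
        # affine normalization of the sharpness features, fitted on the
        # training list at train() time and stored with the checkpoint
        self.feat_mu = np.zeros(6, dtype=np.float32)
        self.feat_sd = np.ones(6, dtype=np.float32)

    @property
    def n_extras(self) -> int:
        return (1 if self.config.use_step_feature else 0) + (
            6 if self.config.use_sharpness_features else 0
        )

    def extras_for(self, frames: np.ndarray, steps: np.ndarray) -> np.ndarray | None:
        """Assemble the scalar FC inputs: normalized step count and (optionally)
        normalized multi-scale sharpness features of the frames."""
        parts = []
        if self.config.use_step_feature:
            parts.append(
                (np.asarray(steps, dtype=np.float32) / self.max_steps)[:, None]
            )
        if self.config.use_sharpness_features:
            feats = (sharpness_features(frames) - self.feat_mu) / self.feat_sd
            parts.append(feats)
        if not parts:
            return None
        return np.concatenate(parts, axis=1)

    def preprocess(self, frames: np.ndarray) -> np.ndarray:
        """Per-frame standardization: defocus crushes contrast, so zero-mean
        unit-variance input keeps the structural signal at a learnable
        amplitude regardless of blur level."""
        frames = np.asarray(frames, dtype=np.float32)
        if not self.config.standardize_obs:
            return frames
        axes = (-2, -1)
        mean = frames.mean(axis=axes, keepdims=True)
        sd = frames.std(axis=axes, keepdims=True)
        return (frames - mean) / (sd + 1e-6)

    def q_values(self, obs: Observation) -> np.ndarray:
        frames = obs.frame[None]
        extras = self.extras_for(frames, np.array([obs.step_count]))
        return np.asarray(self.network.forward(self.preprocess(frames), extras)).ravel()

    def act(self, obs: Observation, epsilon: float, rng: np.random.Generator) -> int:
        return select_action(self.q_values(obs), epsilon, rng)

    def make_env(self, dataset_list: StateDatasetList) -> AutofocusEnv:
        return AutofocusEnv(
            dataset_list,
            self.action_set,
            reward_params=self.reward_params,
            max_steps=self.max_steps,
            obs_resolution=self.config.input_resolution,
            measure_name=self.measure_name,
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights as .npz with a JSON config sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network.params)
        sidecar = {
            "config": asdict(self.config),
            "action_set": {
                "control_factors": list(self.action_set.control_factors),
                "base_b": self.action_set.base_b,
                "method": self.action_set.method,
                "v_step": self.action_set.v_step,
            },
            "max_steps": self.max_steps,
            "measure_name": self.measure_name,
            "feat_mu": self.feat_mu.tolist(),
            "feat_sd": self.feat_sd.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DQNAgent":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = meta["config"]
        if "conv_channels" in cfg_dict:
            cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        config = AgentConfig(**cfg_dict)
        aset = ActionSet(
            control_factors=tuple(meta["action_set"]["control_factors"]),
            base_b=meta["action_set"]["base_b"],
            method=meta["action_set"]["method"],
            v_step=meta["action_set"]["v_step"],
        )
        agent = cls(config, aset, max_steps=meta["max_steps"], measure_name=meta["measure_name"])
        agent.feat_mu = np.asarray(meta.get("feat_mu", [0.0] * 6), dtype=np.float32)
        agent.feat_sd = np.asarray(meta.get("feat_sd", [1.0] * 6), dtype=np.float32)
        with np.load(path.with_suffix(".npz")) as data:
            for k in agent.network.params:
                agent.network.params[k] = data[k].astype(np.float32)
        return agent


# ---------------------------------------------------------------------------
# replay buffer
# ---------------------------------------------------------------------------


class _Replay:
    """Index-based circular buffer of (possibly multi-step) transitions.

    ``disc`` is the discount applied to the bootstrap term: gamma**k for a
    k-step return, 0 when the window hit a terminal stop.
    """

    def __init__(self, capacity: int) -> None:
        self.capacity = capacity
        self.stack = np.zeros(capacity, dtype=np.int32)
        self.idx = np.zeros(capacity, dtype=np.int32)
        self.n = np.zeros(capacity, dtype=np.int32)
        self.action = np.zeros(capacity, dtype=np.int32)
        self.reward = np.zeros(capacity, dtype=np.float32)
        self.next_idx = np.zeros(capacity, dtype=np.int32)
        self.next_n = np.zeros(capacity, dtype=np.int32)
        self.disc = np.zeros(capacity, dtype=np.float32)
        self.size = 0
        self.pos = 0

    def push(self, stack, idx, n, action, reward, next_idx, next_n, disc) -> None:
        p = self.pos
        self.stack[p] = stack
        self.idx[p] = idx
        self.n[p] = n
        self.action[p] = action
        self.reward[p] = reward
        self.next_idx[p] = next_idx
        self.next_n[p] = next_n
        self.disc[p] = disc
        self.pos = (p + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(
        self, batch_size: int, rng: np.random.Generator, terminal_fraction: float = 0.0
    ) -> np.ndarray:
        """Uniform sample, optionally stratified to oversample terminal stops.

        Stop outcomes are rare under a wandering behaviour policy but carry
        the decisive reward signal; reserving a batch share for them keeps
        Q(stop) from being forgotten between successful episodes.
        """
        sel = rng.integers(0, self.size, size=batch_size)
        if terminal_fraction > 0.0:
            terminals = np.flatnonzero(self.disc[: self.size] == 0.0)
            if len(terminals) > 0:
                k = int(round(batch_size * terminal_fraction))
                if k > 0:
                    sel[:k] = terminals[rng.integers(0, len(terminals), size=k)]
        return sel


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def _epsilon(t: int, config: AgentConfig) -> float:
    decay = config.epsilon_decay_steps or max(1, config.train_steps // 2)
    frac = min(1.0, t / decay)
    return config.epsilon_start + frac * (config.epsilon_end - config.epsilon_start)


def _gather_obs(env: AutofocusEnv, stacks: np.ndarray, idxs: np.ndarray) -> np.ndarray:
    return np.stack(
        [env.observation_frames(int(s))[int(i)] for s, i in zip(stacks, idxs)]
    )


def _aux_targets(frames: np.ndarray) -> np.ndarray:
    """Self-supervised targets: log horizontal/vertical gradient energies of
    the (preprocessed) input frames — blur level and astigmatic direction."""
    dx = np.diff(frames, axis=2)
    dy = np.diff(frames, axis=1)
    ex = np.log1p((dx * dx).mean(axis=(1, 2)))
    ey = np.log1p((dy * dy).mean(axis=(1, 2)))
    return np.stack([ex, ey], axis=1).astype(np.float32)


def train(
    env: AutofocusEnv,
    config: AgentConfig,
    eval_list: StateDatasetList | None = None,
) -> tuple[DQNAgent, pd.DataFrame]:
    """Train a DQN on an autofocus environment.

    Runs epsilon-greedy episodes with replay updates and periodic target-
    network synchronization.  Every ``eval_every`` environment steps the
    greedy policy is evaluated on the training list and, if given, on a
    held-out ``eval_list``; the returned log has one row per evaluation
    epoch with raw and min-max-scaled mean returns and mean time steps.
    Fully reproducible for a fixed config seed.
    """
    if config.replay_capacity < config.batch_size:
        raise ValueError("replay_capacity must be >= batch_size")
    config = replace(
        config, n_actions=len(env.action_set), input_resolution=env.obs_resolution
    )
    agent = DQNAgent(
        config,
        env.action_set,
        reward_params=env.reward_params,
        max_steps=env.max_steps,
        measure_name=env.measure_name,
    )

    ss = np.random.SeedSequence(config.seed)
    _, ss_env, ss_act, ss_replay, ss_eval = ss.spawn(5)
    env_rng = np.random.default_rng(ss_env)
    act_rng = np.random.default_rng(ss_act)
    replay_rng = np.random.default_rng(ss_replay)
    eval_seed_base = int(np.random.default_rng(ss_eval).integers(2**30))

    target = QNetwork(
        config.input_resolution, config.n_actions,
        np.random.default_rng(0), conv_channels=tuple(config.conv_channels),
        n_extras=agent.n_extras, dueling=config.dueling,
    )
    optimizer = _Adam(agent.network.params, config.learning_rate)
    replay = _Replay(config.replay_capacity)
    learn_start = config.learn_start or max(config.batch_size * 10, config.batch_size)
    scale = config.reward_scale
    n_stacks = len(env.dataset_list)

    # per-(stack, frame) sharpness features, and their normalization fitted on
    # the training list (stored with the agent for use at evaluation time)
    feat_cache = None
    if config.use_sharpness_features:
        feat_cache = [
            sharpness_features(env.observation_frames(s)) for s in range(n_stacks)
        ]
        all_feats = np.concatenate(feat_cache)
        agent.feat_mu = all_feats.mean(axis=0)
        agent.feat_sd = all_feats.std(axis=0) + 1e-6
    target.copy_from(agent.network)

    obs = env.reset(env_rng)
    log_rows: list[dict] = []
    train_eval_env = agent.make_env(env.dataset_list)
    held_out_env = agent.make_env(eval_list) if eval_list is not None else None

    # a shorter truncation during data collection resets episodes more often
    # (broader start coverage); truncation bootstraps through, so it does not
    # bias the value estimates, and evaluation keeps the full budget
    eval_max_steps = env.max_steps
    if config.train_max_steps is not None:
        env.max_steps = int(config.train_max_steps)

    def _extras(stacks: np.ndarray, idxs: np.ndarray, ns: np.ndarray) -> np.ndarray | None:
        parts = []
        if config.use_step_feature:
            parts.append((ns.astype(np.float32) / agent.max_steps)[:, None])
        if config.use_sharpness_features:
            feats = np.stack([feat_cache[s][i] for s, i in zip(stacks, idxs)])
            parts.append((feats - agent.feat_mu) / agent.feat_sd)
        if not parts:
            return None
        return np.concatenate(parts, axis=1)

    # n-step return assembly: per live entry [frame_idx, n, action, accum, k]
    pending: list[list] = []

    def _flush(next_idx: int, next_n: int, terminal: bool, only_mature: bool) -> None:
        remaining = []
        for entry in pending:
            mature = entry[4] >= config.n_step
            if mature or not only_mature:
                disc = 0.0 if terminal else config.gamma ** entry[4]
                replay.push(
                    entry[5], entry[0], entry[1], entry[2], entry[3],
                    next_idx, next_n, disc,
                )
            else:
                remaining.append(entry)
        pending[:] = remaining

    for t in range(1, config.train_steps + 1):
        stack_idx = env.current_stack_index
        frame_idx = env.current_frame_index
        n_before = env.step_count
        action = agent.act(obs, _epsilon(t, config), act_rng)
        obs, r, done, info = env.step(action)
        pending.append([frame_idx, n_before, action, 0.0, 0, stack_idx])
        for entry in pending:
            entry[3] += (config.gamma ** entry[4]) * r * scale
            entry[4] += 1
        if done:
            # stop is terminal; a time-limit truncation bootstraps through
            _flush(env.current_frame_index, env.step_count,
                   terminal=not info["truncated"], only_mature=False)
            obs = env.reset(env_rng)
        else:
            _flush(env.current_frame_index, env.step_count,
                   terminal=False, only_mature=True)

        if replay.size >= learn_start and t % config.update_every == 0:
            # batch = replayed real transitions + Dyna transitions synthesized
            # uniformly from the captured stacks (the dataset IS the model)
            k_dyna = int(round(config.batch_size * config.dyna_fraction))
            k_real = config.batch_size - k_dyna
            sel = replay.sample(k_real, replay_rng, config.terminal_fraction)
            b_stack = replay.stack[sel]
            b_idx = replay.idx[sel]
            b_n = replay.n[sel]
            b_act = replay.action[sel]
            b_rew = replay.reward[sel].copy()
            b_disc = replay.disc[sel].copy()
            b_nidx = replay.next_idx[sel]
            b_nn = replay.next_n[sel]
            if k_dyna:
                d_stack = replay_rng.integers(0, n_stacks, k_dyna).astype(np.int32)
                d_idx = replay_rng.integers(0, env.n_frames, k_dyna).astype(np.int32)
                d_act = replay_rng.integers(0, config.n_actions, k_dyna).astype(np.int32)
                d_n = replay_rng.integers(0, env.max_steps, k_dyna).astype(np.int32)
                d_rew = np.empty(k_dyna, dtype=np.float32)
                d_nidx = np.empty(k_dyna, dtype=np.int32)
                d_disc = np.empty(k_dyna, dtype=np.float32)
                for j in range(k_dyna):
                    r_j, nxt, term = env.simulate_transition(
                        int(d_stack[j]), int(d_idx[j]), int(d_act[j]), int(d_n[j]) + 1
                    )
                    d_rew[j] = r_j * scale
                    d_nidx[j] = nxt
                    d_disc[j] = 0.0 if term else config.gamma
                b_stack = np.concatenate([b_stack, d_stack])
                b_idx = np.concatenate([b_idx, d_idx])
                b_n = np.concatenate([b_n, d_n])
                b_act = np.concatenate([b_act, d_act])
                b_rew = np.concatenate([b_rew, d_rew])
                b_disc = np.concatenate([b_disc, d_disc])
                b_nidx = np.concatenate([b_nidx, d_nidx])
                b_nn = np.concatenate([b_nn, d_n + 1])
            frames = _gather_obs(env, b_stack, b_idx)
            next_frames = _gather_obs(env, b_stack, b_nidx)
            if config.noise_augment > 0:
                # fresh per-presentation sensor noise: the frozen noise field
                # of a stored frame cannot be memorized, so the fit must rely
                # on the stable structural (blur) content
                frames = frames + replay_rng.normal(
                    0.0, config.noise_augment, size=frames.shape
                ).astype(np.float32)
                next_frames = next_frames + replay_rng.normal(
                    0.0, config.noise_augment, size=next_frames.shape
                ).astype(np.float32)
            frames = agent.preprocess(frames)
            next_frames = agent.preprocess(next_frames)
            if config.augment_flips:
                # flips of the whole field of view leave actions, rewards and
                # the astigmatism axes unchanged, so Q is flip-invariant:
                # train on randomly flipped (state, next-state) pairs
                if replay_rng.random() < 0.5:
                    frames = frames[:, :, ::-1]
                    next_frames = next_frames[:, :, ::-1]
                if replay_rng.random() < 0.5:
                    frames = frames[:, ::-1, :]
                    next_frames = next_frames[:, ::-1, :]
                frames = np.ascontiguousarray(frames)
                next_frames = np.ascontiguousarray(next_frames)
            next_extras = _extras(b_stack, b_nidx, b_nn)
            q_next_t = target.forward(next_frames, next_extras)
            if config.double_dqn:
                a_star = np.argmax(agent.network.forward(next_frames, next_extras), axis=1)
                max_next = q_next_t[np.arange(len(a_star)), a_star]
            else:
                max_next = q_next_t.max(axis=1)
            targets = b_rew + b_disc * max_next
            q, cache = agent.network.forward(
                frames, _extras(b_stack, b_idx, b_n), want_cache=True
            )
            rows = np.arange(config.batch_size)
            acts = b_act
            td = q[rows, acts] - targets
            loss = float(np.mean(td**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at step {t}: non-finite TD loss {loss}"
                )
            dq = np.zeros_like(q)
            dq[rows, acts] = (2.0 / config.batch_size) * td
            daux = None
            if config.aux_weight > 0:
                aux_err = agent.network.aux_predict(cache) - _aux_targets(frames)
                daux = (config.aux_weight * 2.0 / aux_err.size) * aux_err
            grads = agent.network.backward(dq, cache, daux)
            gnorm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
            if gnorm > config.grad_clip:
                for k in grads:
                    grads[k] *= config.grad_clip / gnorm
            optimizer.step(agent.network.params, grads)

        if t % config.target_update_period == 0:
            target.copy_from(agent.network)

        if t % config.eval_every == 0 or t == config.train_steps:
            epoch = len(log_rows) + 1
            row = {"step": t, "epoch": epoch, "epsilon": _epsilon(t, config)}
            train_rep = evaluate(
                agent, env.dataset_list, n_episodes=config.eval_episodes,
                seed=eval_seed_base + 2 * epoch, env=train_eval_env,
            )
            row.update(
                train_return=train_rep.mean_return,
                train_steps_mean=train_rep.mean_steps,
                train_success=train_rep.success_rate,
                train_accuracy=train_rep.accuracy_rate,
            )
            if eval_list is not None:
                ev = evaluate(
                    agent, eval_list, n_episodes=config.eval_episodes,
                    seed=eval_seed_base + 2 * epoch + 1, env=held_out_env,
                )
                row.update(
                    eval_return=ev.mean_return,
                    eval_steps_mean=ev.mean_steps,
                    eval_success=ev.success_rate,
                    eval_accuracy=ev.accuracy_rate,
                )
            log_rows.append(row)

    env.max_steps = eval_max_steps
    log = pd.DataFrame(log_rows)
    for col in ("train_return", "eval_return"):
        if col in log.columns:
            v = log[col].to_numpy(dtype=float)
            span = v.max() - v.min()
            log[col.replace("_return", "_scaled_return")] = (
                (v - v.min()) / span if span > 0 else np.zeros_like(v)
            )
    return agent, log


def run_policy(
    env: AutofocusEnv,
    policy,
    n_episodes: int,
    rng: np.random.Generator,
) -> EvalReport:
    """Roll out ``policy(env, obs, rng) -> action index`` and aggregate.

    The policy callable may inspect the environment (oracle baselines do);
    learned agents only use the observation.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    records = []
    for _ in range(n_episodes):
        obs = env.reset(rng)
        done = False
        while not done:
            obs, _, done, info = env.step(policy(env, obs, rng))
        records.append(info["record"])
    return EvalReport.from_records(records)


def evaluate(
    agent: DQNAgent,
    dataset_list: StateDatasetList,
    n_episodes: int = 1000,
    greedy: bool = True,
    seed: int = 0,
    env: AutofocusEnv | None = None,
) -> EvalReport:
    """Evaluate an agent on a dataset list (greedy policy by default).

    Pass a prebuilt ``env`` over the same list to reuse its observation
    cache across repeated evaluations.
    """
    if env is None:
        env = agent.make_env(dataset_list)
    rng = np.random.default_rng(seed)
    epsilon = 0.0 if greedy else agent.config.epsilon_end

    def policy(env_, obs, rng_):
        return agent.act(obs, epsilon, rng_)

    return run_policy(env, policy, n_episodes, rng)
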