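"""Episodic autofocus environment.

Each episode: a focal stack (state dataset) is drawn uniformly from the list
L, the lens starts at a uniformly random voltage, and the agent moves along
the voltage grid in discrete control-factor steps until it issues the stop
action (factor 0) or the step budget runs out.  Observations are the current
frame (resized to the configured input resolution) plus the step count; the
reward is the hybrid clarity/time/stop/bonus reward evaluated on the frame
reached by each action.

Success bookkeeping follows the voltage-deviation convention: an episode is
*successful* if the final voltage is within 0.2 V of true focus and
*accurate* if the deviation is exactly 0 V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .actions import ActionSet, apply_action
from .measures import normalize_curve, sharpness_curve
from .reward import RewardInputs, RewardParams, compute_reward
from .simulate import StateDatasetList

__all__ = [
    "Observation",
    "EpisodeRecord",
    "EvalReport",
    "AutofocusEnv",
    "episode_metrics",
]

SUCCESS_TOLERANCE_VOLTS = 0.2
_EPS = 1e-12


@dataclass
class Observation:
    """What the agent sees: the current frame and the step count."""

    frame: np.ndarray  # (res, res) float32 in [0, 1]
    step_count: int


@dataclass
class EpisodeRecord:
    """Outcome of one autofocus episode."""

    stack_id: str
    start_index: int
    final_index: int
    steps: int
    deviation_volts: float
    success: bool
    accurate: bool
    episode_return: float
    truncated: bool = False  # hit the step budget without stopping


def episode_metrics(
    final_index: int, focus_index: int, v_step: float
) -> tuple[float, bool, bool]:
    """(deviation in volts, success, accurate) for a final lens position."""
    if final_index < 0 or focus_index < 0:
        raise ValueError("frame indices must be non-negative")
    deviation = abs(final_index - focus_index) * v_step
    success = deviation <= SUCCESS_TOLERANCE_VOLTS + _EPS
    accurate = final_index == focus_index
    return deviation, success, accurate


@dataclass
class EvalReport:
    """Aggregated evaluation metrics over a batch of episodes."""

    success_rate: float
    accuracy_rate: float
    mean_steps: float
    mae_volts: float
    rmse_volts: float
    mean_return: float
    n_episodes: int
    non_termination_rate: float
    deviation_histogram: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: list[EpisodeRecord]) -> "EvalReport":
        if not records:
            raise ValueError("cannot aggregate an empty episode batch")
        dev = np.array([r.deviation_volts for r in records])
        # per-0.1 V bins keyed by the nearest bin center
        hist: dict[str, int] = {}
        for d in dev:
            key = f"{round(float(d), 1):.1f}"
            hist[key] = hist.get(key, 0) + 1
        return cls(
            success_rate=float(np.mean([r.success for r in records])),
            accuracy_rate=float(np.mean([r.accurate for r in records])),
            mean_steps=float(np.mean([r.steps for r in records])),
            mae_volts=float(np.mean(dev)),
            rmse_volts=float(np.sqrt(np.mean(dev**2))),
            mean_return=float(np.mean([r.episode_return for r in records])),
            n_episodes=len(records),
            non_termination_rate=float(np.mean([r.truncated for r in records])),
            deviation_histogram=hist,
        )


class AutofocusEnv:
    """Gym-style environment over a :class:`StateDatasetList`.

    Parameters
    ----------
    dataset_list:
        Non-empty list L of focal stacks sharing frame count and resolution.
    action_set:
        Signed control factors; factor 0 is the stop action.
    reward_params:
        Hybrid reward coefficients and component gates.
    max_steps:
        Episode step budget; exceeding it truncates the episode (recorded
        distinctly from an autonomous stop).
    obs_resolution:
        Side length the observed frame is resized to.
    measure_name:
        Clarity measure used for the reward's normalized sharpness.
    """

    def __init__(
        self,
        dataset_list: StateDatasetList,
        action_set: ActionSet,
        reward_params: RewardParams | None = None,
        max_steps: int = 50,
        obs_resolution: int = 84,
        tolerance_volts: float = SUCCESS_TOLERANCE_VOLTS,
        measure_name: str = "energy",
    ) -> None:
        if len(dataset_list) == 0:
            raise ValueError("dataset list must be non-empty")
        self.dataset_list = dataset_list
        self.action_set = action_set
        self.reward_params = reward_params if reward_params is not None else RewardParams()
        self.max_steps = int(max_steps)
        self.obs_resolution = int(obs_resolution)
        self.tolerance_volts = float(tolerance_volts)
        self.measure_name = measure_name
        self.n_frames = dataset_list[0].n_frames

        # normalized clarity curve per stack (per-stack min-max, reward input);
        # the "least clear image" of each stack is the curve argmin
        self._norm_curves = [
            normalize_curve(sharpness_curve(s, measure_name)).values for s in dataset_list.stacks
        ]
        self._least_sharp = [int(np.argmin(c)) for c in self._norm_curves]
        self._obs_cache: dict[int, np.ndarray] = {}

        # episode state
        self._stack_idx: int | None = None
        self._index = 0
        self._n = 0
        self._return = 0.0
        self._start_index = 0
        self._done = True

    # -- observation cache ---------------------------------------------------

    def observation_frames(self, stack_idx: int) -> np.ndarray:
        """All frames of one stack at observation resolution (cached)."""
        if stack_idx not in self._obs_cache:
            stack = self.dataset_list[stack_idx]
            res = self.obs_resolution
            if stack.frames.shape[1:] == (res, res):
                obs = stack.frames.astype(np.float32)
            else:
                down = stack.frames.shape[1] > res
                obs = resize(
                    stack.frames, (stack.n_frames, res, res), order=1, anti_aliasing=down
                ).astype(np.float32)
            self._obs_cache[stack_idx] = np.clip(obs, 0.0, 1.0)
        return self._obs_cache[stack_idx]

    def observation(self, stack_idx: int, frame_idx: int, n: int) -> Observation:
        return Observation(
            frame=self.observation_frames(stack_idx)[frame_idx], step_count=n
        )

    # -- episode API ---------------------------------------------------------

    @property
    def current_stack_index(self) -> int:
        if self._stack_idx is None:
            raise RuntimeError("reset the environment first")
        return self._stack_idx

    @property
    def current_frame_index(self) -> int:
        return self._index

    @property
    def step_count(self) -> int:
        return self._n

    @property
    def done(self) -> bool:
        return self._done

    @property
    def current_stack(self):
        return self.dataset_list[self.current_stack_index]

    def reset(self, rng: np.random.Generator) -> Observation:
        """Start a new episode: uniform stack from L, uniform start voltage."""
        self._stack_idx = int(rng.integers(0, len(self.dataset_list)))
        self._index = int(rng.integers(0, self.n_frames))
        self._start_index = self._index
        self._n = 0
        self._return = 0.0
        self._done = False
        return self.observation(self._stack_idx, self._index, 0)

    def simulate_transition(
        self, stack_idx: int, frame_idx: int, action_index: int, n: int
    ) -> tuple[float, int, bool]:
        """Dataset-model transition: the (reward, next frame index, terminal)
        outcome of taking one action from an arbitrary state, without touching
        the live episode.  Valid because training runs on pre-captured stacks:
        every counterfactual outcome is already in the data.

        ``n`` is the step count the action would carry (>= 1).
        """
        if not 0 <= action_index < len(self.action_set):
            raise ValueError("action index out of range")
        stack = self.dataset_list[stack_idx]
        factor = self.action_set.control_factors[action_index]
        if factor == 0:
            deviation = abs(frame_idx - stack.focus_index) * stack.v_step
            stop_correct = deviation <= self.tolerance_volts + _EPS
            next_idx = frame_idx
            terminal = True
        else:
            stop_correct = False
            next_idx = apply_action(frame_idx, factor, self.n_frames)
            terminal = False
        curve = self._norm_curves[stack_idx]
        if next_idx == stack.focus_index:
            extreme = "sharpest"
        elif next_idx == self._least_sharp[stack_idx]:
            extreme = "least_sharp"
        else:
            extreme = "neither"
        reward = compute_reward(
            RewardInputs(
                fc_norm=float(curve[next_idx]),
                n=max(int(n), 1),
                stop_correct=stop_correct,
                extreme=extreme,
            ),
            self.reward_params,
        )
        return reward, next_idx, terminal

    def _extreme(self, index: int) -> str:
        """The extra-reward flags mark the stack's two extreme images: the
        ground-truth sharpest frame and the least clear frame (curve argmin)."""
        stack = self.current_stack
        if index == stack.focus_index:
            return "sharpest"
        if index == self._least_sharp[self._stack_idx]:
            return "least_sharp"
        return "neither"

    def step(self, action_index: int) -> tuple[Observation, float, bool, dict]:
        """Apply one action; returns (observation, reward, done, info).

        A nonzero control factor moves the lens (clipped at the sweep ends);
        factor 0 stops the episode, with the Done flag set iff the final
        deviation is within the success tolerance.  ``info`` carries the
        :class:`EpisodeRecord` under ``"record"`` once the episode ends.
        """
        if self._done:
            raise RuntimeError("step() called on a finished episode; call reset()")
        if not 0 <= action_index < len(self.action_set):
            raise ValueError(
                f"action index {action_index} out of range for {len(self.action_set)} actions"
            )
        factor = self.action_set.control_factors[action_index]
        stack = self.current_stack
        self._n += 1

        stop_correct = False
        truncated = False
        if factor == 0:
            deviation = abs(self._index - stack.focus_index) * stack.v_step
            stop_correct = deviation <= self.tolerance_volts + _EPS
            self._done = True
        else:
            self._index = apply_action(self._index, factor, self.n_frames)
            if self._n >= self.max_steps:
                self._done = True
                truncated = True

        reward = compute_reward(
            RewardInputs(
                fc_norm=float(self._norm_curves[self._stack_idx][self._index]),
                n=self._n,
                stop_correct=stop_correct,
                extreme=self._extreme(self._index),
            ),
            self.reward_params,
        )
        self._return += reward

        obs = self.observation(self._stack_idx, self._index, self._n)
        info: dict = {"stop_correct": stop_correct, "truncated": truncated}
        if self._done:
            deviation, near_focus, exact = episode_metrics(
                self._index, stack.focus_index, stack.v_step
            )
            # an episode only counts as successful/accurate if the agent
            # stopped autonomously; running out of budget is the
            # "non-terminating" outcome however close the lens ended up
            stopped = not truncated
            info["record"] = EpisodeRecord(
                stack_id=stack.sample_id or str(self._stack_idx),
                start_index=self._start_index,
                final_index=self._index,
                steps=self._n,
                deviation_volts=deviation,
                success=stopped and near_focus,
                accurate=stopped and exact,
                episode_return=self._return,
                truncated=truncated,
            )
        return obs, reward, self._done, info
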