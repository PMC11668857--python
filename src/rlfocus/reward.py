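"""Hybrid autofocus reward.

Per step the agent receives

    r = -alpha * (1 - Fc_norm)          (sharpness term, in [-alpha, 0])
        - beta * ln(n / beta)           (time-step term, positive for n < beta)
        + mu * Done                     (stop bonus, only on a correct stop)
        +/- delta                       (extreme-image bonus/penalty)

where ``Fc_norm`` is the min-max-normalized clarity of the current frame, n
is the number of actions taken so far, and Done flags a stop within the
success tolerance of true focus.  The sharpness term is oriented so the
sharpest frame incurs zero penalty (a ``literal_sign`` flag preserves the
opposite orientation for comparison).  Each of the four components can be
gated off independently; the five standard ablation variants enable
sharpness alone, +stop, +time, +extra, and all four.

Defaults: alpha=100, beta=30, mu=200, delta=100 — chosen so the maximum
magnitudes of the terms share one order of magnitude and no single objective
dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "RewardGates",
    "RewardParams",
    "RewardInputs",
    "compute_reward",
    "variant_gates",
]

EXTREMES = ("sharpest", "least_sharp", "neither")


@dataclass(frozen=True)
class RewardGates:
    sharpness_on: bool = True
    time_on: bool = True
    stop_on: bool = True
    extra_on: bool = True


@dataclass(frozen=True)
class RewardParams:
    alpha: float = 100.0
    beta: float = 30.0
    mu: float = 200.0
    delta: float = 100.0
    gates: RewardGates = field(default_factory=RewardGates)
    literal_sign: bool = False  # penalize high sharpness (printed-form orientation)

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.mu, self.delta) <= 0:
            raise ValueError("alpha, beta, mu, delta must all be positive")


@dataclass(frozen=True)
class RewardInputs:
    fc_norm: float  # normalized sharpness of the current frame, in [0, 1]
    n: int  # actions taken so far this episode (1 for the first)
    stop_correct: bool = False  # the Done flag
    extreme: str = "neither"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fc_norm <= 1.0:
            raise ValueError(f"fc_norm must lie in [0, 1], got {self.fc_norm}")
        if self.n < 1:
            raise ValueError(f"step count n must be >= 1, got {self.n}")
        if self.extreme not in EXTREMES:
            raise ValueError(f"extreme must be one of {EXTREMES}, got {self.extreme!r}")


def compute_reward(inputs: RewardInputs, params: RewardParams) -> float:
    """Evaluate the hybrid reward for one step."""
    g = params.gates
    r = 0.0
    if g.sharpness_on:
        if params.literal_sign:
            r -= params.alpha * inputs.fc_norm
        else:
            r -= params.alpha * (1.0 - inputs.fc_norm)
    if g.time_on:
        r -= params.beta * math.log(inputs.n / params.beta)
    if g.stop_on and inputs.stop_correct:
        r += params.mu
    if g.extra_on:
        if inputs.extreme == "sharpest":
            r += params.delta
        elif inputs.extreme == "least_sharp":
            r -= params.delta
    return r


def variant_gates(variant: int) -> RewardGates:
    """Gate settings of the five ablation variants.

    1 sharpness only; 2 +stop; 3 +time; 4 +extra; 5 all components.
    """
    table = {
        1: RewardGates(sharpness_on=True, time_on=False, stop_on=False, extra_on=False),
        2: RewardGates(sharpness_on=True, time_on=False, stop_on=True, extra_on=False),
        3: RewardGates(sharpness_on=True, time_on=True, stop_on=False, extra_on=False),
        4: RewardGates(sharpness_on=True, time_on=False, stop_on=False, extra_on=True),
        5: RewardGates(sharpness_on=True, time_on=True, stop_on=True, extra_on=True),
    }
    try:
        return table[variant]
    except KeyError:
        raise ValueError(f"reward variant must be in 1..5, got {variant}") from None
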