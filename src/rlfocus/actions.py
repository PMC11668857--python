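"""Discrete voltage-adjustment action sets.

Each action multiplies the voltage resolution ``v`` (0.1 V per unit) by a
signed integer control factor tau; factor 0 is the stop action.  Two
constructions grow the non-unit factors from a base b:

* ``logarithmic`` — powers of the base: {0, +-1, +-b, +-b^2, ...}
* ``multiple``    — integer multiples:  {0, +-1, +-b, +-2b, ...}

For b = 2 the two coincide for 7 actions: (-4, -2, -1, 0, 1, 2, 4).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ActionSet", "build_action_set", "check_action_space", "apply_action"]

METHODS = ("logarithmic", "multiple")


@dataclass(frozen=True)
class ActionSet:
    """Sorted signed control factors including 0 (stop) and +-1."""

    control_factors: tuple[int, ...]
    base_b: int
    method: str
    v_step: float = 0.1

    def __post_init__(self) -> None:
        f = self.control_factors
        if len(f) < 3 or len(f) % 2 == 0:
            raise ValueError("action set must have odd cardinality >= 3")
        if tuple(sorted(f)) != f:
            raise ValueError("control factors must be sorted")
        if 0 not in f or 1 not in f or -1 not in f:
            raise ValueError("action set must contain 0 (stop) and +-1")
        if any(-t not in f for t in f):
            raise ValueError("action set must be symmetric about 0")

    def __len__(self) -> int:
        return len(self.control_factors)

    @property
    def stop_index(self) -> int:
        return self.control_factors.index(0)

    def voltage_steps(self) -> tuple[float, ...]:
        """Actions in volts: a = tau * v."""
        return tuple(t * self.v_step for t in self.control_factors)


def build_action_set(
    b: int, n_A: int, method: str = "logarithmic", v_step: float = 0.1
) -> ActionSet:
    """Construct the n_A-action set for base b under one construction method."""
    if n_A < 3 or n_A % 2 == 0:
        raise ValueError(f"n_A must be an odd integer >= 3, got {n_A}")
    if b < 2:
        raise ValueError(f"base b must be >= 2, got {b}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

    n_extra = (n_A - 3) // 2  # non-unit magnitudes per direction
    if method == "logarithmic":
        magnitudes = [b**j for j in range(1, n_extra + 1)]
    else:
        magnitudes = [k * b for k in range(1, n_extra + 1)]
    positives = [1] + magnitudes
    factors = sorted([-m for m in positives] + [0] + positives)
    return ActionSet(
        control_factors=tuple(factors), base_b=b, method=method, v_step=v_step
    )


def check_action_space(b: int, n_A: int, n_S: int) -> bool:
    """True iff the largest logarithmic factor fits half the state range.

    The base-growth constraint ties the action-space size to the number of
    states: the biggest jump b^((n_A-3)/2) must not exceed n_S / 2.
    """
    if n_A < 3 or n_A % 2 == 0 or b < 2 or n_S < 1:
        raise ValueError("invalid action-space parameters")
    return b ** ((n_A - 3) // 2) <= n_S / 2


def apply_action(index: int, factor: int, n_frames: int) -> int:
    """Move a frame index by a control factor, clipping at the sweep ends.

    Clipping (not erroring) mirrors the physical lens saturating at its
    voltage limits.
    """
    if not 0 <= index < n_frames:
        raise ValueError(f"index {index} out of range for {n_frames} frames")
    return min(max(index + factor, 0), n_frames - 1)
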