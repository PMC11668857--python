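"""Image sharpness (clarity) measures and per-stack curve normalization.

The Energy measure — the squared-gradient sum used as the clarity index in
the reward and the classical searches — plus the standard comparison set
(Tenengrad, Laplacian energy, intensity variance, Brenner).  All measures are
non-negative, peak at best focus on unimodal stacks, and are invariant to
image flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simulate import FocalStack

__all__ = [
    "MEASURES",
    "SharpnessCurve",
    "energy_gradient",
    "measure",
    "sharpness_curve",
    "normalize_curve",
]


def _as_image(img: np.ndarray) -> np.ndarray:
    """Measures accept any finite 2-D intensity array (no size floor)."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite intensities")
    return arr


def energy_gradient(img: np.ndarray) -> float:
    """Energy clarity value: sum of squared first differences in x and y.

    ``sum((I[x+1,y]-I[x,y])^2 + (I[x,y+1]-I[x,y])^2)`` with out-of-range
    neighbours omitted.
    """
    arr = _as_image(img)
    dy = np.diff(arr, axis=0)
    dx = np.diff(arr, axis=1)
    return float(np.sum(dy * dy) + np.sum(dx * dx))


def _tenengrad(arr: np.ndarray) -> float:
    gy = ndimage.sobel(arr, axis=0, mode="reflect")
    gx = ndimage.sobel(arr, axis=1, mode="reflect")
    return float(np.sum(gx * gx + gy * gy))


def _laplacian(arr: np.ndarray) -> float:
    lap = ndimage.laplace(arr, mode="reflect")
    return float(np.sum(lap * lap))


def _variance(arr: np.ndarray) -> float:
    return float(np.var(arr))


def _brenner(arr: np.ndarray) -> float:
    d2y = arr[2:, :] - arr[:-2, :]
    d2x = arr[:, 2:] - arr[:, :-2]
    return float(np.sum(d2y * d2y) + np.sum(d2x * d2x))


MEASURES = {
    "energy": lambda img: energy_gradient(img),
    "tenengrad": lambda img: _tenengrad(_as_image(img)),
    "laplacian": lambda img: _laplacian(_as_image(img)),
    "variance": lambda img: _variance(_as_image(img)),
    "brenner": lambda img: _brenner(_as_image(img)),
}


def measure(img: np.ndarray, name: str = "energy") -> float:
    """Evaluate one named sharpness measure on an image."""
    try:
        fn = MEASURES[name]
    except KeyError:
        raise ValueError(
            f"unknown sharpness measure {name!r}; expected one of {sorted(MEASURES)}"
        ) from None
    return fn(img)


@dataclass
class SharpnessCurve:
    """Per-frame sharpness values of one stack under one measure."""

    values: np.ndarray
    measure_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("curve must be a non-empty 1-D array")
        if not np.isfinite(self.values).all():
            raise ValueError("curve contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.values))


def sharpness_curve(stack: FocalStack, name: str = "energy") -> SharpnessCurve:
    """Evaluate a measure on every frame of a stack."""
    vals = np.array([measure(f, name) for f in stack.frames])
    return SharpnessCurve(values=vals, measure_name=name)


def normalize_curve(curve: SharpnessCurve) -> SharpnessCurve:
    """Min-max normalize a curve to [0, 1] (per stack, argmax preserved)."""
    v = curve.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ValueError("cannot normalize a constant sharpness curve (max == min)")
    return SharpnessCurve(values=(v - vmin) / (vmax - vmin), measure_name=curve.measure_name)
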