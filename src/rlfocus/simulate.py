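"""Synthetic through-focus stack simulator.

Emulates the acquisition of a voltage-driven liquid-lens microscope: a sweep
of the drive voltage in fixed increments produces an ordered
defocused-focused-defocused stack of grayscale frames of one field of view.
Defocus is modelled as a Gaussian PSF whose width grows linearly with the
frame distance from best focus; an optional astigmatism term elongates the
PSF along an axis that flips through focus, which is the physical cue that
makes the *sign* of defocus observable in a single frame.

Three texture families stand in for the sample types used in training:
high-contrast regular micro-structured patterns (``regular_grid``),
medium-contrast resolution-target bars (``bar_target``) and medium-contrast
irregular laser-processed surfaces (``speckle``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "FormatError",
    "FocalStack",
    "StateDatasetList",
    "TEXTURE_FAMILIES",
    "make_texture",
    "render_stack",
    "augment_stack",
    "build_dataset_list",
    "build_dataset_split",
    "write_stack",
    "read_stack",
    "validate_gray_image",
]

TEXTURE_FAMILIES = ("regular_grid", "bar_target", "speckle")

#: default per-family Michelson contrast, mirroring the sample descriptions
#: (high-contrast regular patterns; medium-contrast targets and substrates)
FAMILY_CONTRAST = {"regular_grid": 0.9, "bar_target": 0.5, "speckle": 0.5}

MIN_IMAGE_SIZE = 8


class FormatError(ValueError):
    """A stack directory or its sidecar is malformed."""


def validate_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Check the grayscale-image contract: 2-D, >=8 px per side, values in [0,1]."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if min(arr.shape) < MIN_IMAGE_SIZE:
        raise ValueError(
            f"image sides must be >= {MIN_IMAGE_SIZE} px, got shape {arr.shape}"
        )
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite intensities")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    return arr


@dataclass
class FocalStack:
    """An ordered through-focus sweep of one field of view.

    ``frames[i]`` was captured at ``voltage_grid[i]``; ``focus_index`` is the
    ground-truth sharpest frame.  The voltage grid is uniform (the lens is
    stepped in fixed increments).
    """

    frames: np.ndarray  # (n_frames, h, w) float in [0, 1]
    voltage_grid: np.ndarray  # (n_frames,) volts, uniform spacing
    focus_index: int
    texture_family: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.voltage_grid = np.asarray(self.voltage_grid, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if len(self.frames) != len(self.voltage_grid):
            raise ValueError("frames and voltage_grid length mismatch")
        if len(self.voltage_grid) >= 2:
            steps = np.diff(self.voltage_grid)
            if steps.min() <= 0 or np.ptp(steps) > 1e-9:
                raise ValueError("voltage grid must be uniformly increasing")
        if not 0 <= self.focus_index < len(self.frames):
            raise ValueError(
                f"focus_index {self.focus_index} out of range "
                f"for {len(self.frames)} frames"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def v_step(self) -> float:
        if len(self.voltage_grid) < 2:
            return 0.0
        return float(self.voltage_grid[1] - self.voltage_grid[0])

    @property
    def focus_voltage(self) -> float:
        return float(self.voltage_grid[self.focus_index])


@dataclass
class StateDatasetList:
    """The parallel list L of focal stacks sampled randomly during training."""

    stacks: list[FocalStack] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stacks:
            shapes = {s.frames.shape for s in self.stacks}
            if len(shapes) > 1:
                raise ValueError(f"stacks must share frame count and resolution: {shapes}")

    def __len__(self) -> int:
        return len(self.stacks)

    def __getitem__(self, i: int) -> FocalStack:
        return self.stacks[i]

    @property
    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.stacks:
            counts[s.texture_family] = counts.get(s.texture_family, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# texture synthesis
# ---------------------------------------------------------------------------


def _two_levels(contrast: float) -> tuple[float, float]:
    # mean-0.5 two-level pattern with exact Michelson contrast
    return 0.5 * (1.0 - contrast), 0.5 * (1.0 + contrast)


def make_texture(family: str, size: int, contrast: float = 0.9, seed: int = 0) -> np.ndarray:
    """Render a deterministic in-focus texture of one family.

    Parameters
    ----------
    family:
        One of ``regular_grid`` (periodic two-level mesh), ``bar_target``
        (groups of parallel bars of varying pitch) or ``speckle``
        (band-limited random granularity).
    size:
        Side length in pixels (square output), at least 8.
    contrast:
        Requested Michelson contrast ``(max-min)/(max+min)`` in (0, 1].
    seed:
        Seeds the per-texture randomness (phases, bar layout, speckle field).
    """
    if family not in TEXTURE_FAMILIES:
        raise ValueError(f"unknown texture family {family!r}; expected one of {TEXTURE_FAMILIES}")
    if size < MIN_IMAGE_SIZE:
        raise ValueError(f"texture size must be >= {MIN_IMAGE_SIZE}, got {size}")
    if not (0.0 < contrast <= 1.0):
        raise ValueError(f"contrast must lie in (0, 1], got {contrast}")

    rng = np.random.default_rng(seed)
    lo, hi = _two_levels(contrast)
    y, x = np.mgrid[0:size, 0:size]

    # every family mixes fine detail with coarse structure: real samples have
    # features across scales, which keeps the sharpness curve informative
    # (non-flat) even under heavy defocus — the regime classical searches and
    # the learned policy both rely on
    if family == "regular_grid":
        # two-level periodic mesh: union of a fine and a coarse stripe grid
        # with random pitches and phases
        fine = int(rng.integers(max(4, size // 16), max(5, size // 8)))
        coarse = int(rng.integers(max(6, size // 4), max(7, size // 2)))
        mask = np.zeros((size, size), dtype=bool)
        for pitch in (fine, coarse):
            duty = pitch // 2
            py = int(rng.integers(0, pitch))
            px = int(rng.integers(0, pitch))
            mask |= (((y + py) % pitch) < duty) & (((x + px) % pitch) < duty)
        img = np.where(mask, hi, lo)
    elif family == "bar_target":
        # grouped parallel bars, pitch halving between groups (resolution-
        # target style), alternating orientation
        img = np.full((size, size), lo)
        n_groups = 4
        band = size // n_groups
        for g in range(n_groups):
            pitch = max(2, band >> g)
            duty = max(1, pitch // 2)
            phase = int(rng.integers(0, pitch))
            g0, g1 = g * band, min((g + 1) * band, size)
            if g % 2 == 0:
                bars = ((x[g0:g1] + phase) % pitch) < duty
            else:
                bars = ((y[g0:g1] + phase) % pitch) < duty
            img[g0:g1] = np.where(bars, hi, lo)
    else:  # speckle
        # two-scale band-limited granularity: filtered white noise, min-max
        # rescaled so the requested Michelson contrast is met exactly
        grain = max(1.5, size / 32.0)
        base = rng.standard_normal((size, size))
        fine = ndimage.gaussian_filter(base, grain, mode="wrap") - ndimage.gaussian_filter(
            base, 3.0 * grain, mode="wrap"
        )
        coarse_field = ndimage.gaussian_filter(
            rng.standard_normal((size, size)), 4.0 * grain, mode="wrap"
        )
        blend = fine / max(fine.std(), 1e-12) + coarse_field / max(coarse_field.std(), 1e-12)
        span = blend.max() - blend.min()
        img = lo + (hi - lo) * (blend - blend.min()) / span

    return validate_gray_image(img)


# ---------------------------------------------------------------------------
# through-focus rendering
# ---------------------------------------------------------------------------


def _psf_sigma(
    i: int,
    focus_index: int,
    psf_sigma0: float,
    psf_slope: float,
    astigmatism: float,
) -> tuple[float, float]:
    """(sigma_y, sigma_x) of the defocus PSF at frame ``i``.

    The isotropic width grows linearly with the frame distance from focus.
    ``astigmatism`` in [0, 1) elongates the PSF along y on one side of focus
    and along x on the other — the directional cue a real (aberrated) lens
    provides; 0 recovers the symmetric isotropic model.
    """
    d = abs(i - focus_index)
    sigma = psf_sigma0 + psf_slope * d
    side = np.sign(i - focus_index)
    return sigma * (1.0 + astigmatism * side), sigma * (1.0 - astigmatism * side)


def render_stack(
    texture: np.ndarray,
    n_frames: int = 100,
    focus_index: int = 50,
    v_start: float = 35.0,
    v_step: float = 0.1,
    psf_sigma0: float = 0.5,
    psf_slope: float = 0.3,
    noise_sd: float = 0.01,
    seed: int = 0,
    astigmatism: float = 0.0,
    texture_family: str = "regular_grid",
    sample_id: str = "",
) -> FocalStack:
    """Simulate a voltage sweep over one field of view.

    Frame ``i`` is the texture blurred by a Gaussian PSF of width
    ``psf_sigma0 + psf_slope * |i - focus_index|`` pixels plus additive
    Gaussian sensor noise of standard deviation ``noise_sd``, clipped to
    [0, 1].  ``voltage_grid[i] = v_start + i * v_step``.
    """
    texture = validate_gray_image(texture)
    if n_frames < 3:
        raise ValueError(f"a through-focus stack needs >= 3 frames, got {n_frames}")
    if not 0 <= focus_index < n_frames:
        raise ValueError(f"focus_index {focus_index} out of range for {n_frames} frames")
    if v_step <= 0:
        raise ValueError("v_step must be positive")
    if psf_slope <= 0:
        raise ValueError("psf_slope must be positive")
    if not 0.0 <= astigmatism < 1.0:
        raise ValueError("astigmatism must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames,) + texture.shape, dtype=np.float64)
    for i in range(n_frames):
        sig = _psf_sigma(i, focus_index, psf_sigma0, psf_slope, astigmatism)
        frame = ndimage.gaussian_filter(texture, sig, mode="reflect")
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)

    voltages = v_start + v_step * np.arange(n_frames)
    return FocalStack(
        frames=frames,
        voltage_grid=voltages,
        focus_index=focus_index,
        texture_family=texture_family,
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_AUG_OPS = ("hflip", "vflip", "crop", "gamma")


def augment_stack(
    stack: FocalStack,
    ops: Sequence[str | tuple[str, float]],
    seed: int = 0,
) -> FocalStack:
    """Apply augmentation ops stack-wide (identically to every frame).

    ``ops`` entries are names from {hflip, vflip, crop, gamma}, optionally as
    ``(name, parameter)`` pairs: crop takes the retained fraction per side
    (>= 0.5, cropped window resized back), gamma takes the exponent.  Frame
    count, voltage grid and focus index are always preserved.
    """
    rng = np.random.default_rng(seed)
    frames = stack.frames.copy()
    h, w = frames.shape[1:]
    for op in ops:
        name, param = op if isinstance(op, tuple) else (op, None)
        if name == "hflip":
            frames = frames[:, :, ::-1]
        elif name == "vflip":
            frames = frames[:, ::-1, :]
        elif name == "gamma":
            exponent = float(rng.uniform(0.7, 1.4)) if param is None else float(param)
            if exponent <= 0:
                raise ValueError("gamma exponent must be positive")
            frames = frames**exponent
        elif name == "crop":
            frac = float(rng.uniform(0.5, 0.95)) if param is None else float(param)
            if not 0.5 <= frac <= 1.0:
                raise ValueError("crop must retain >= 50% of each dimension")
            ch, cw = max(MIN_IMAGE_SIZE, round(h * frac)), max(MIN_IMAGE_SIZE, round(w * frac))
            y0 = int(rng.integers(0, h - ch + 1))
            x0 = int(rng.integers(0, w - cw + 1))
            window = frames[:, y0 : y0 + ch, x0 : x0 + cw]
            frames = np.clip(
                resize(window, frames.shape, order=1, anti_aliasing=False), 0.0, 1.0
            )
        else:
            raise ValueError(f"unknown augmentation op {name!r}; expected one of {_AUG_OPS}")
    return FocalStack(
        frames=frames,
        voltage_grid=stack.voltage_grid.copy(),
        focus_index=stack.focus_index,
        texture_family=stack.texture_family,
        sample_id=stack.sample_id,
    )


# ---------------------------------------------------------------------------
# dataset-list assembly
# ---------------------------------------------------------------------------


def build_dataset_list(
    n_stacks: int,
    families: Sequence[str],
    n_frames: int = 100,
    seed: int = 0,
    size: int = 224,
    v_start: float = 35.0,
    v_step: float = 0.1,
    psf_sigma0: float = 0.5,
    psf_slope: float = 0.3,
    noise_sd: float = 0.01,
    astigmatism: float = 0.0,
) -> StateDatasetList:
    """Assemble the training/evaluation list L of focal stacks.

    Stacks are distributed round-robin across ``families``; each stack gets a
    disjoint child seed, a fresh texture and a ground-truth focus index drawn
    uniformly from the central 80% of the frame range (so every stack has both
    defocus flanks).
    """
    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    if not families:
        raise ValueError("families must be non-empty")
    for fam in families:
        if fam not in TEXTURE_FAMILIES:
            raise ValueError(f"unknown texture family {fam!r}")

    children = np.random.SeedSequence(seed).spawn(n_stacks)
    lo = int(round(0.1 * n_frames))
    hi = max(lo + 1, int(round(0.9 * n_frames)))  # exclusive
    stacks = []
    for k in range(n_stacks):
        family = families[k % len(families)]
        rng = np.random.default_rng(children[k])
        tex_seed = int(rng.integers(0, 2**31 - 1))
        noise_seed = int(rng.integers(0, 2**31 - 1))
        focus = int(rng.integers(lo, hi))
        texture = make_texture(family, size, FAMILY_CONTRAST[family], seed=tex_seed)
        stacks.append(
            render_stack(
                texture,
                n_frames=n_frames,
                focus_index=focus,
                v_start=v_start,
                v_step=v_step,
                psf_sigma0=psf_sigma0,
                psf_slope=psf_slope,
                noise_sd=noise_sd,
                seed=noise_seed,
                astigmatism=astigmatism,
                texture_family=family,
                sample_id=f"{family}-{k:03d}",
            )
        )
    return StateDatasetList(stacks=stacks)


def build_dataset_split(
    n_train: int,
    n_test: int,
    families: Sequence[str],
    n_frames: int = 100,
    seed: int = 0,
    size: int = 224,
    v_start: float = 35.0,
    v_step: float = 0.1,
    psf_sigma0: float = 0.5,
    psf_slope: float = 0.3,
    noise_sd: float = 0.01,
    astigmatism: float = 0.0,
) -> tuple[StateDatasetList, StateDatasetList]:
    """Train/test lists as fields of view of shared samples.

    Mirrors the acquisition protocol: one physical *sample* per texture
    family, imaged at many fields of view; each stack is a random window of
    that sample's texture (optionally flipped) with its own focus voltage and
    sensor noise.  The train and test lists never share a stack, but they do
    share samples — evaluating on the test list measures generalization
    across fields of view, not across unknown samples (that is the separate
    generalization study).
    """
    if n_train < 1 or n_test < 0:
        raise ValueError("need n_train >= 1 and n_test >= 0")
    if not families:
        raise ValueError("families must be non-empty")

    root = np.random.SeedSequence(seed)
    sample_seeds, stack_seeds = root.spawn(2)
    big = size * 2
    sample_rngs = {
        fam: np.random.default_rng(s)
        for fam, s in zip(families, sample_seeds.spawn(len(families)))
    }
    textures = {
        fam: make_texture(fam, big, FAMILY_CONTRAST[fam], seed=int(rng.integers(2**31 - 1)))
        for fam, rng in sample_rngs.items()
    }

    lo = int(round(0.1 * n_frames))
    hi = max(lo + 1, int(round(0.9 * n_frames)))
    children = stack_seeds.spawn(n_train + n_test)

    def one_stack(k: int, split: str) -> FocalStack:
        family = families[k % len(families)]
        rng = np.random.default_rng(children[k])
        y0 = int(rng.integers(0, big - size + 1))
        x0 = int(rng.integers(0, big - size + 1))
        window = textures[family][y0 : y0 + size, x0 : x0 + size]
        if rng.random() < 0.5:
            window = window[:, ::-1]
        if rng.random() < 0.5:
            window = window[::-1, :]
        focus = int(rng.integers(lo, hi))
        return render_stack(
            np.ascontiguousarray(window),
            n_frames=n_frames,
            focus_index=focus,
            v_start=v_start,
            v_step=v_step,
            psf_sigma0=psf_sigma0,
            psf_slope=psf_slope,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
            astigmatism=astigmatism,
            texture_family=family,
            sample_id=f"{family}-{split}-{k:03d}",
        )

    train = StateDatasetList(stacks=[one_stack(k, "train") for k in range(n_train)])
    test = StateDatasetList(
        stacks=[one_stack(n_train + k, "test") for k in range(n_test)]
    )
    return train, test


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

_SIDECAR = "stack.json"


def write_stack(stack: FocalStack, dir_path: str | Path) -> None:
    """Write a stack as 8-bit grayscale PNGs plus a JSON sidecar."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (frame, volts) in enumerate(zip(stack.frames, stack.voltage_grid)):
        name = f"frame_{i:03d}_v{volts:.2f}.png"
        iio.imwrite(out / name, np.round(frame * 255).astype(np.uint8))
        names.append(name)
    sidecar = {
        "frames": names,
        "voltage_grid": [float(v) for v in stack.voltage_grid],
        "focus_index": int(stack.focus_index),
        "texture_family": stack.texture_family,
        "sample_id": stack.sample_id,
    }
    (out / _SIDECAR).write_text(json.dumps(sidecar, indent=1))


def read_stack(dir_path: str | Path) -> FocalStack:
    """Read a stack directory written by :func:`write_stack`.

    Frames are returned in voltage order as recorded in the sidecar, whatever
    the on-disk listing order.
    """
    src = Path(dir_path)
    sidecar_path = src / _SIDECAR
    if not sidecar_path.is_file():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
        names = list(meta["frames"])
        voltages = np.asarray(meta["voltage_grid"], dtype=np.float64)
        focus_index = int(meta["focus_index"])
        family = str(meta.get("texture_family", "regular_grid"))
        sample_id = str(meta.get("sample_id", ""))
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    if len(names) != len(voltages):
        raise FormatError("sidecar frame list and voltage grid length mismatch")

    frames = []
    for i, name in enumerate(names):
        path = src / name
        if not path.is_file():
            raise FormatError(f"missing frame file for index {i}: {path.name}")
        frames.append(np.asarray(iio.imread(path), dtype=np.float64) / 255.0)
    try:
        return FocalStack(
            frames=np.stack(frames),
            voltage_grid=voltages,
            focus_index=focus_index,
            texture_family=family,
            sample_id=sample_id,
        )
    except ValueError as exc:
        raise FormatError(f"inconsistent stack in {src}: {exc}") from exc
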