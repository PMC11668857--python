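"""Structured run configuration, seed fan-out and run manifests.

A run is described by one YAML file with nested blocks (simulation, action,
reward, agent, experiment, output) plus a single global seed.  Dotted-path
overrides (``agent.train_steps=2000``) are applied on top.  The global seed
fans out to per-component seeds keyed by component *name* (a stable CRC of
the name, mixed with the global seed), so adding a component never perturbs
the random streams of the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, fields, is_dataclass, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .agent import AgentConfig
from .reward import RewardGates, RewardParams
from .simulate import TEXTURE_FAMILIES

__all__ = [
    "SimulationBlock",
    "ActionBlock",
    "RewardBlock",
    "ExperimentBlock",
    "RunConfig",
    "component_seed",
    "load_config",
    "apply_overrides",
    "write_manifest",
]


def component_seed(global_seed: int, component: str) -> int:
    """Deterministic per-component seed derived from the global seed."""
    mix = np.random.SeedSequence([int(global_seed), zlib.crc32(component.encode())])
    return int(mix.generate_state(1)[0] % (2**31))


@dataclass
class SimulationBlock:
    n_stacks: int = 10
    families: tuple[str, ...] = TEXTURE_FAMILIES
    frame_size: int = 224
    n_frames: int = 100
    v_start: float = 35.0
    v_step: float = 0.1
    psf_sigma0: float = 0.5
    psf_slope: float = 0.3
    noise_sd: float = 0.01
    astigmatism: float = 0.0

    def validate(self) -> None:
        if self.n_stacks < 1:
            raise ValueError("simulation.n_stacks must be >= 1")
        bad = [f for f in self.families if f not in TEXTURE_FAMILIES]
        if bad:
            raise ValueError(f"simulation.families contains unknown families {bad}")


@dataclass
class ActionBlock:
    base: int = 5
    n_actions: int = 7
    method: str = "logarithmic"

    def validate(self) -> None:
        if self.method not in ("logarithmic", "multiple"):
            raise ValueError(f"action.method must be 'logarithmic' or 'multiple', got {self.method!r}")
        if self.n_actions < 3 or self.n_actions % 2 == 0:
            raise ValueError("action.n_actions must be an odd integer >= 3")


_GATE_NAMES = ("sharpness_on", "time_on", "stop_on", "extra_on")


@dataclass
class RewardBlock:
    alpha: float = 100.0
    beta: float = 30.0
    mu: float = 200.0
    delta: float = 100.0
    gates: dict = field(
        default_factory=lambda: {name: True for name in _GATE_NAMES}
    )
    literal_sign: bool = False

    def validate(self) -> None:
        unknown = set(self.gates) - set(_GATE_NAMES)
        if unknown:
            raise ValueError(
                f"reward.gates has unknown gate name(s) {sorted(unknown)}; "
                f"valid gates: {list(_GATE_NAMES)}"
            )

    def to_params(self) -> RewardParams:
        self.validate()
        merged = {name: True for name in _GATE_NAMES}
        merged.update(self.gates)
        return RewardParams(
            alpha=self.alpha,
            beta=self.beta,
            mu=self.mu,
            delta=self.delta,
            gates=RewardGates(**merged),
            literal_sign=self.literal_sign,
        )


@dataclass
class ExperimentBlock:
    eval_episodes: int = 1000
    max_steps: int = 50
    obs_resolution: int = 84

    def validate(self) -> None:
        if self.eval_episodes < 1:
            raise ValueError("experiment.eval_episodes must be >= 1")


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs"
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    action: ActionBlock = field(default_factory=ActionBlock)
    reward: RewardBlock = field(default_factory=RewardBlock)
    agent: AgentConfig = field(default_factory=AgentConfig)
    experiment: ExperimentBlock = field(default_factory=ExperimentBlock)

    def validate(self) -> "RunConfig":
        self.simulation.validate()
        self.action.validate()
        self.reward.validate()
        self.experiment.validate()
        return self

    def seed_for(self, component: str) -> int:
        return component_seed(self.seed, component)


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config field(s) {sorted(unknown)} in block '{path}'")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        target = known[key].type
        if isinstance(value, dict) and is_dataclass(_resolve(cls, key)):
            kwargs[key] = _build(_resolve(cls, key), value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
        del target
    return cls(**kwargs)


def _resolve(cls, key):
    # nested dataclass types of RunConfig blocks
    nested = {
        "simulation": SimulationBlock,
        "action": ActionBlock,
        "reward": RewardBlock,
        "agent": AgentConfig,
        "experiment": ExperimentBlock,
    }
    return nested.get(key, type(None))


def load_config(path: str | Path | None = None, overrides: Sequence[str] = ()) -> RunConfig:
    """Load a YAML run config (defaults if no path) and apply overrides."""
    data = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = loaded
    cfg = _build(RunConfig, data, "run")
    cfg = apply_overrides(cfg, overrides)
    return cfg.validate()


def _parse_scalar(text: str):
    return yaml.safe_load(text)


def apply_overrides(cfg: RunConfig, overrides: Sequence[str]) -> RunConfig:
    """Apply ``block.field=value`` overrides (YAML-parsed values)."""
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} must look like path.to.field=value")
        dotted, raw = item.split("=", 1)
        parts = dotted.strip().split(".")
        value = _parse_scalar(raw)
        target = cfg
        for part in parts[:-1]:
            if not hasattr(target, part):
                raise ValueError(f"unknown config path {dotted!r} (no block {part!r})")
            target = getattr(target, part)
        leaf = parts[-1]
        if is_dataclass(target) and not isinstance(target, type):
            if leaf not in {f.name for f in fields(target)}:
                raise ValueError(f"unknown config field {dotted!r}")
            if isinstance(target, AgentConfig):
                # frozen dataclass: rebuild and reattach
                new = replace(target, **{leaf: value})
                cfg.agent = new
            else:
                setattr(target, leaf, value if not isinstance(value, list) else tuple(value))
        elif isinstance(target, dict):
            target[leaf] = value
        else:
            raise ValueError(f"cannot apply override to {dotted!r}")
    return cfg


def write_manifest(cfg: RunConfig, path: str | Path, extra: dict | None = None) -> None:
    """Record the exact config, seed and package version beside the outputs."""
    from . import __version__

    manifest = {"version": __version__, "config": asdict(cfg)}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
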