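"""Scripted studies: action-space size/construction, random-sampling list
size, reward ablation, cross-sample generalization, and the classical-search
baseline comparison.

Every study emits a machine-readable pandas table whose rows carry the seed
and a hash of the configuration that produced them, so identical
config+seeds reproduce identical rows.  The full protocol evaluates each
trained policy over 1000 episodes; all problem sizes (frame resolution,
stack count, training steps) are set through :class:`StudySettings` so the
studies scale from quick desk-scale checks to the full 224x224 protocol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .actions import build_action_set
from .agent import AgentConfig, DQNAgent, evaluate, train
from .env import AutofocusEnv, EvalReport
from .reward import RewardParams, variant_gates
from .search import (
    fibonacci_search,
    golden_section_search,
    sweep_search,
)
from .simulate import TEXTURE_FAMILIES, StateDatasetList, build_dataset_list

__all__ = [
    "StudySettings",
    "run_action_space_study",
    "run_sampling_study",
    "run_ablation",
    "run_generalization",
    "run_baseline_comparison",
    "export_report",
    "import_report",
]

#: baseline step-counting convention, stated in every baseline report
PROBE_CONVENTION = (
    "agent steps = actions taken including the stop action; "
    "search steps = distinct lens settings probed (image captures)"
)


@dataclass(frozen=True)
class StudySettings:
    """Problem sizes and training settings shared by the studies.

    Defaults follow the acquisition protocol (224x224 frames, 100-frame
    stacks at 0.1 V, 1000-episode evaluation); reduce ``frame_size``,
    ``train_steps`` and ``eval_episodes`` for desk-scale runs.  The defocus
    PSF parameters are referenced to 224-px frames and scaled with
    ``frame_size`` so smaller renders keep the same scene geometry.
    ``astigmatism`` models the through-focus PSF anisotropy of a real lens —
    the single-frame cue for the sign of defocus.
    """

    frame_size: int = 224
    n_frames: int = 100
    obs_resolution: int = 84
    v_start: float = 35.0
    v_step: float = 0.1
    psf_sigma0_ref: float = 0.5
    # study optics: defocus must grow fast enough that a 2-3 frame (0.2-0.3 V)
    # move is discriminable at the observation resolution — the premise of
    # single-frame defocus readout; 0.6 px/frame at 224 px reference sits in
    # the realistic high-NA range while keeping the far field informative
    psf_slope_ref: float = 0.6
    noise_sd: float = 0.01
    astigmatism: float = 0.4
    max_steps: int = 50
    eval_episodes: int = 1000
    agent: AgentConfig = field(
        default_factory=lambda: AgentConfig(
            learning_rate=5e-4, batch_size=64, epsilon_end=0.15,
            replay_capacity=50_000,
        )
    )

    def scaled_psf(self) -> tuple[float, float]:
        s = self.frame_size / 224.0
        return self.psf_sigma0_ref * s, self.psf_slope_ref * s

    def build_list(self, n_stacks: int, families: Sequence[str], seed: int) -> StateDatasetList:
        sigma0, slope = self.scaled_psf()
        return build_dataset_list(
            n_stacks,
            families,
            n_frames=self.n_frames,
            seed=seed,
            size=self.frame_size,
            v_start=self.v_start,
            v_step=self.v_step,
            psf_sigma0=sigma0,
            psf_slope=slope,
            noise_sd=self.noise_sd,
            astigmatism=self.astigmatism,
        )

    def agent_config(self, n_actions: int, seed: int) -> AgentConfig:
        return replace(
            self.agent,
            n_actions=n_actions,
            input_resolution=self.obs_resolution,
            seed=seed,
        )


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _report_fields(rep: EvalReport, prefix: str) -> dict:
    return {
        f"{prefix}_success_rate": rep.success_rate,
        f"{prefix}_accuracy_rate": rep.accuracy_rate,
        f"{prefix}_mean_steps": rep.mean_steps,
        f"{prefix}_mae_volts": rep.mae_volts,
        f"{prefix}_rmse_volts": rep.rmse_volts,
        f"{prefix}_mean_return": rep.mean_return,
        f"{prefix}_non_termination_rate": rep.non_termination_rate,
        f"{prefix}_deviation_histogram": json.dumps(rep.deviation_histogram),
    }


def _train_and_eval(
    train_list: StateDatasetList,
    test_list: StateDatasetList | None,
    action_set,
    reward_params: RewardParams,
    settings: StudySettings,
    seed: int,
):
    cfg = settings.agent_config(len(action_set), seed)
    env = AutofocusEnv(
        train_list,
        action_set,
        reward_params=reward_params,
        max_steps=settings.max_steps,
        obs_resolution=settings.obs_resolution,
    )
    agent, log = train(env, cfg, eval_list=test_list)
    train_rep = evaluate(
        agent, train_list, n_episodes=settings.eval_episodes, seed=seed + 10_000
    )
    test_rep = (
        evaluate(agent, test_list, n_episodes=settings.eval_episodes, seed=seed + 20_000)
        if test_list is not None
        else None
    )
    return agent, log, train_rep, test_rep


def run_action_space_study(
    sizes: Sequence[int],
    bases: Sequence[int],
    methods: Sequence[str],
    train_list: StateDatasetList,
    test_list: StateDatasetList,
    seeds: Sequence[int] = (0, 1, 2),
    settings: StudySettings | None = None,
) -> pd.DataFrame:
    """Train and evaluate one agent per (action-space size, base, method).

    Rows average the evaluation metrics over the seeds; n_A = 3 degenerates
    to the basic forward/backward/stop set for every base and method, so it
    is reported once per method.
    """
    if not sizes or not bases or not methods:
        raise ValueError("empty study grid")
    settings = settings or StudySettings()
    rows = []
    for method in methods:
        for b in bases:
            for n_A in sizes:
                aset = build_action_set(b, n_A, method, settings.v_step)
                per_seed = []
                for seed in seeds:
                    _, _, tr, te = _train_and_eval(
                        train_list, test_list, aset, RewardParams(), settings, seed
                    )
                    per_seed.append({**_report_fields(tr, "train"), **_report_fields(te, "test")})
                row = {
                    "n_actions": n_A,
                    "base": b,
                    "method": method,
                    "action_set": str(list(aset.control_factors)),
                    "seeds": str(list(seeds)),
                    "config_hash": _config_hash(
                        {"study": "action_space", "b": b, "n_A": n_A, "method": method,
                         "seeds": list(seeds), "settings": asdict(settings)}
                    ),
                }
                for key in per_seed[0]:
                    if key.endswith("histogram"):
                        row[key] = per_seed[0][key]
                    else:
                        row[key] = float(np.mean([p[key] for p in per_seed]))
                rows.append(row)
    return pd.DataFrame(rows)


def run_sampling_study(
    list_sizes: Sequence[int] = (1, 5, 10, 50),
    families: Sequence[str] = TEXTURE_FAMILIES,
    seeds: Sequence[int] = (0, 1, 2),
    settings: StudySettings | None = None,
    base: int = 5,
    n_actions: int = 7,
) -> pd.DataFrame:
    """Effect of the state-dataset list size on autofocus performance.

    For each list size a fresh training list and an equal-sized held-out
    test list are generated; one agent is trained per seed.
    """
    if any(s < 1 for s in list_sizes):
        raise ValueError("list sizes must be positive")
    settings = settings or StudySettings()
    aset = build_action_set(base, n_actions, "logarithmic", settings.v_step)
    rows = []
    for size in list_sizes:
        per_seed = []
        for seed in seeds:
            train_list = settings.build_list(size, families, seed=1_000_000 + 7 * seed)
            test_list = settings.build_list(size, families, seed=2_000_000 + 7 * seed)
            _, _, tr, te = _train_and_eval(
                train_list, test_list, aset, RewardParams(), settings, seed
            )
            per_seed.append({**_report_fields(tr, "train"), **_report_fields(te, "test")})
        row = {
            "list_size": size,
            "seeds": str(list(seeds)),
            "config_hash": _config_hash(
                {"study": "sampling", "size": size, "seeds": list(seeds),
                 "settings": asdict(settings)}
            ),
        }
        for key in per_seed[0]:
            if key.endswith("histogram"):
                row[key] = per_seed[0][key]
            else:
                row[key] = float(np.mean([p[key] for p in per_seed]))
        rows.append(row)
    return pd.DataFrame(rows)


def run_ablation(
    train_list: StateDatasetList,
    test_list: StateDatasetList,
    variants: Sequence[int] = (1, 2, 3, 4, 5),
    seeds: Sequence[int] = (0, 1, 2),
    settings: StudySettings | None = None,
    base: int = 5,
    n_actions: int = 7,
) -> tuple[pd.DataFrame, dict[tuple[int, int], pd.DataFrame]]:
    """Reward-component ablation over the five gate variants.

    Returns the metric table (one row per variant, seed-averaged) and the
    per-(variant, seed) training logs carrying the per-epoch return and
    time-step curves.  Mean steps are reported over all episodes with
    truncated (non-terminating) episodes at the step budget, alongside the
    non-termination fraction; the mean return is reported both raw and
    min-max scaled across variants.
    """
    if not set(variants) <= {1, 2, 3, 4, 5}:
        raise ValueError("variants must be a subset of 1..5")
    settings = settings or StudySettings()
    aset = build_action_set(base, n_actions, "logarithmic", settings.v_step)
    rows = []
    logs: dict[tuple[int, int], pd.DataFrame] = {}
    for variant in variants:
        params = RewardParams(gates=variant_gates(variant))
        per_seed = []
        for seed in seeds:
            _, log, tr, te = _train_and_eval(
                train_list, test_list, aset, params, settings, seed
            )
            logs[(variant, seed)] = log
            per_seed.append({**_report_fields(tr, "train"), **_report_fields(te, "test")})
        row = {
            "variant": variant,
            "seeds": str(list(seeds)),
            "config_hash": _config_hash(
                {"study": "ablation", "variant": variant, "seeds": list(seeds),
                 "settings": asdict(settings)}
            ),
        }
        for key in per_seed[0]:
            if key.endswith("histogram"):
                row[key] = per_seed[0][key]
            else:
                row[key] = float(np.mean([p[key] for p in per_seed]))
        rows.append(row)
    table = pd.DataFrame(rows)
    ret = table["test_mean_return"].to_numpy(dtype=float)
    span = ret.max() - ret.min()
    table["test_scaled_return"] = (ret - ret.min()) / span if span > 0 else 0.0
    return table, logs


def run_generalization(
    single_sample_list: StateDatasetList,
    two_family_list: StateDatasetList,
    unseen_family: str,
    seeds: Sequence[int] = (0, 1, 2),
    settings: StudySettings | None = None,
    base: int = 5,
    n_actions: int = 7,
) -> pd.DataFrame:
    """Cross-sample generalization: single- vs two-family training.

    Both training regimes are evaluated on a freshly generated list of the
    ``unseen_family`` (absent from both training lists, enforced).  One row
    per (method, seed).
    """
    for name, lst in (("single-family", single_sample_list), ("two-family", two_family_list)):
        if unseen_family in lst.family_counts:
            raise ValueError(f"unseen family {unseen_family!r} overlaps the {name} training list")
    settings = settings or StudySettings()
    aset = build_action_set(base, n_actions, "logarithmic", settings.v_step)
    rows = []
    for method_name, train_list in (
        ("single_family", single_sample_list),
        ("two_family", two_family_list),
    ):
        for seed in seeds:
            unseen_list = settings.build_list(
                len(train_list), [unseen_family], seed=3_000_000 + 11 * seed
            )
            _, _, tr, un = _train_and_eval(
                train_list, unseen_list, aset, RewardParams(), settings, seed
            )
            rows.append(
                {
                    "method": method_name,
                    "list_size": len(train_list),
                    "unseen_family": unseen_family,
                    "seed": seed,
                    "config_hash": _config_hash(
                        {"study": "generalization", "method": method_name, "seed": seed,
                         "settings": asdict(settings)}
                    ),
                    **_report_fields(tr, "train"),
                    **_report_fields(un, "unseen"),
                }
            )
    return pd.DataFrame(rows)


def run_baseline_comparison(
    stacks: StateDatasetList,
    agent: DQNAgent,
    searches: Sequence[str] = ("sweep", "golden_section", "fibonacci"),
    n_episodes_per_stack: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean time steps of the trained agent vs classical searches.

    One row per (texture family, method); the step-counting convention
    (:data:`PROBE_CONVENTION`) is attached as ``df.attrs['convention']``
    and repeated in a column.
    """
    search_fns = {
        "sweep": sweep_search,
        "golden_section": golden_section_search,
        "fibonacci": fibonacci_search,
    }
    unknown = set(searches) - set(search_fns)
    if unknown:
        raise ValueError(f"unknown search methods: {sorted(unknown)}")

    rows = []
    families = sorted(stacks.family_counts)
    for family in families:
        members = [i for i, s in enumerate(stacks.stacks) if s.texture_family == family]
        fam_list = StateDatasetList(stacks=[stacks[i] for i in members])
        rep = evaluate(
            agent, fam_list, n_episodes=n_episodes_per_stack * len(members), seed=seed
        )
        rows.append(
            {
                "sample_family": family,
                "method": "agent",
                "mean_steps": rep.mean_steps,
                "success_rate": rep.success_rate,
                "convention": PROBE_CONVENTION,
            }
        )
        for name in searches:
            probes = [search_fns[name](stacks[i]).probes for i in members]
            rows.append(
                {
                    "sample_family": family,
                    "method": name,
                    "mean_steps": float(np.mean(probes)),
                    "success_rate": float(
                        np.mean(
                            [
                                search_fns[name](stacks[i]).best_index
                                == stacks[i].focus_index
                                for i in members
                            ]
                        )
                    ),
                    "convention": PROBE_CONVENTION,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["convention"] = PROBE_CONVENTION
    return df


def export_report(report: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a study table losslessly as CSV or JSON."""
    path = Path(path)
    if format == "csv":
        report.to_csv(path, index=False)
    elif format == "json":
        path.write_text(report.to_json(orient="table", index=False, double_precision=15))
    else:
        raise ValueError(f"unknown report format {format!r}; expected 'csv' or 'json'")


def import_report(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read a table written by :func:`export_report`."""
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return pd.read_json(path, orient="table")
    raise ValueError(f"unknown report format {format!r}; expected 'csv' or 'json'")
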