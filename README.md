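# rlfocus

Deep-reinforcement-learning autofocus for voltage-driven liquid-lens
microscopes — with a synthetic through-focus simulator, classical search
baselines, and a fully seeded experiment harness.

## The problem

An electrowetting liquid lens changes focal length with its drive voltage,
so autofocus is a search over a one-dimensional voltage grid (0.1 V steps).
Sweeping the voltage yields a *focal stack*: a defocused-focused-defocused
sequence of frames whose sharpness curve peaks at best focus.  Classical
methods (golden-section, Fibonacci search) bracket that peak with few image
captures but need a reliable scalar sharpness measure.  The reinforcement-
learning formulation instead treats the raw current frame as the **state**,
discrete signed voltage steps `a = tau * v` (control factor `tau`, resolution
`v = 0.1` V, `tau = 0` meaning *stop*) as the **actions**, and learns a
policy end to end with the hybrid per-step reward

    r = -alpha * Fc_norm  -  beta * ln(n / beta)  +  mu * Done  +/-  delta

where `Fc_norm` is the per-stack min-max-normalized Energy (squared-gradient)
clarity of the current frame, `n` the step count, `Done` flags a stop within
0.2 V of true focus, and `+delta`/`-delta` mark the stack's sharpest and
least-sharp frames (`alpha=100, beta=30, mu=200, delta=100`).  An episode is
*successful* if the agent stops within 0.2 V and *accurate* if it stops at
exactly 0 V deviation.

The package implements: the stack simulator (three texture families, voltage-
dependent anisotropic Gaussian defocus, augmentation, PNG+JSON disk format),
five sharpness measures, both published action-set constructions
(logarithmic powers and integer multiples of a base), the gated reward with
its five ablation variants, a gym-style episodic environment over random-
sampled state-dataset lists, a numpy DQN (replay, target network, double /
dueling / n-step options), classical searches with probe counting, and
scripted studies (action-space size, list size, reward ablation,
generalization, baseline comparison).

## Worked example

```python
import numpy as np
import rlfocus as rf

# the published 7-action sets
print(rf.build_action_set(5, 7, "logarithmic").control_factors)
# (-25, -5, -1, 0, 1, 5, 25)
print(rf.build_action_set(3, 7, "multiple").control_factors)
# (-6, -3, -1, 0, 1, 3, 6)

# a 100-frame synthetic sweep at 0.1 V spacing, and the classical baselines
tex = rf.make_texture("regular_grid", 64, contrast=0.9, seed=7)
stack = rf.render_stack(tex, n_frames=100, focus_index=50,
                        psf_sigma0=0.14, psf_slope=0.086, noise_sd=0.0)
print(stack.voltage_grid[0], stack.voltage_grid[-1])   # 35.0 44.9
print(rf.sweep_search(stack).probes)                   # 100
g = rf.golden_section_search(stack)
f = rf.fibonacci_search(stack)
print(g.best_index, g.probes, f.best_index, f.probes)  # 50 10 50 10
```

Both searches locate the exact sharpest frame (index 50, the true focus)
with 10 captures instead of the sweep's 100.  Training an agent on a toy
problem (two 16-frame stacks of 8x8 frames, the three basic actions) runs
in seconds:

```python
lst = rf.build_dataset_list(2, ["regular_grid"], n_frames=16, size=8, seed=3,
                            psf_sigma0=0.3, psf_slope=0.25, astigmatism=0.4)
env = rf.AutofocusEnv(lst, rf.build_action_set(2, 3),
                      reward_params=rf.RewardParams(literal_sign=True),
                      obs_resolution=8)
agent, log = rf.train(env, rf.AgentConfig(input_resolution=8, n_actions=3,
                                          train_steps=5000, eval_every=5000,
                                          learning_rate=1e-3, replay_capacity=5000,
                                          target_update_period=250, seed=0))
report = rf.evaluate(agent, lst, n_episodes=300, seed=1)
print(round(report.success_rate, 3), round(report.mean_steps, 2),
      round(report.mae_volts, 3))
# 1.0 10.74 0.111
```

The learned policy stops within the 0.2 V success tolerance on every
evaluation episode, using 10.7 actions on average, with a mean final-voltage
error of 0.11 V.  `report` also carries the accuracy rate, RMSE, the
non-termination fraction and the full deviation histogram in 0.1 V bins.
Full-scale training uses `build_dataset_split` (train/test lists as
disjoint fields of view of shared samples) and the study settings in
`rlfocus.experiments`; see `docs/methods.md` for the desk-scale learning
results and their limitations.

A command-line interface wraps the same pipelines:

```sh
rlfocus simulate -o out --set simulation.n_stacks=2
rlfocus train -o run --set agent.train_steps=20000
rlfocus study sampling -o study
```

## Layout

```
src/rlfocus/
  simulate.py     textures, focal stacks, dataset lists, disk round-trip
  measures.py     sharpness measures + per-stack normalization
  actions.py      action-set constructions, admissibility, index moves
  reward.py       hybrid reward, gates, ablation variants
  env.py          episodic environment, episode records, eval reports
  agent.py        numpy DQN: network, replay, training, evaluation
  search.py       sweep / golden-section / Fibonacci baselines
  experiments.py  scripted studies + report export
  config.py       YAML run config, overrides, seed fan-out
  cli.py          typer entry points
docs/methods.md   model, parameters, design decisions, limitations
scripts/acceptance.py
tests/
```
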