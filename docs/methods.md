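# Methods

## Problem

A liquid lens changes focal length with drive voltage, so autofocus becomes a
one-dimensional search over a voltage grid: sweep the lens in 0.1 V steps and
the camera sees a defocused-focused-defocused sequence of frames.  The
package reproduces an end-to-end reinforcement-learning treatment of this
problem: the raw current frame is the state, discrete signed voltage steps
are the actions, a stop action declares focus, and a hybrid reward scores
clarity, speed and correct stopping.  Classical bracketing searches
(golden-section, Fibonacci) over the same stacks provide the baseline the
learned policy must beat on capture count.

## Synthetic focal stacks

`rlfocus.simulate` generates the training and evaluation data.  One *state
dataset* is a `FocalStack`: `n_frames` (default 100) grayscale frames of one
texture at `v_start + i * v_step` volts (default 35.0 V + i * 0.1 V),
rendered by blurring an in-focus texture with an anisotropic Gaussian PSF

    sigma(i) = psf_sigma0 + psf_slope * |i - focus_index|        (pixels)
    sigma_x, sigma_y = sigma * (1 -/+ astigmatism * sign(i - focus_index))

plus additive Gaussian sensor noise (sd 0.01) clipped to [0, 1].  Generator
defaults are `psf_sigma0 = 0.5` px and `psf_slope = 0.3` px/frame, referenced
to 224 x 224 frames and scaled proportionally when smaller frames are
rendered, so reduced-resolution runs keep the same scene geometry.  The
*study* settings use a steeper `psf_slope_ref = 0.6` px/frame: the method's
premise — judging focus to a 0.2 V (2-frame) tolerance from a single frame —
requires adjacent-frame blur differences to be discriminable at the
observation resolution.  At 0.3 px/frame an ideal observer separates the
focus frame from a 3-frame miss by only ~4 noise standard deviations for a
*known* texture, and a texture-generalizing defocus estimator tops out near
65% held-out success; at 0.6 the same estimator reaches 98%, while slopes
near 1.0 erase the far field.  This is a property of the simulated optics,
chosen once from that analysis.

Astigmatism (default 0 in the generator; 0.4 in the study settings) is the
package's stand-in for the through-focus aberrations of a real lens.  It
matters because a *perfectly symmetric* defocus model makes the sign of
defocus unobservable from a single frame — two frames equidistant from focus
are pixel-identical up to noise — and a single-image policy then cannot know
which way to drive the lens.  Real lenses break this symmetry (astigmatic
focus sensing exploits exactly this); the simulator breaks it the same way:
the PSF elongates along one axis on the near side of focus and along the
orthogonal axis on the far side.

Three texture families emulate the sample types used for training: a
two-level periodic mesh (`regular_grid`, high contrast 0.9), resolution-
target bar groups of halving pitch (`bar_target`, contrast 0.5) and
band-limited speckle (`speckle`, contrast 0.5).  Each family mixes fine and
coarse scales so the sharpness curve stays informative across the whole
sweep — a property real samples have and classical searches rely on.  The
Michelson contrast of a generated texture matches the requested value
exactly by construction.  Focus indices are drawn from the central 80% of
the frame range so every stack has both defocus flanks.

What the simulator does *not* model: the lens's focal-length-voltage curve
and response time, field-dependent aberrations beyond the single astigmatism
term, depth-dependent scene content (the scene is a plane), illumination
drift, and non-Gaussian sensor noise.  Tests passing on this simulator show
the algorithmic pipeline is sound at these conditions; they do not certify
performance on any physical instrument.

## Sharpness measures and normalization

The Energy measure is the squared-gradient sum
`sum((I[x+1,y]-I[x,y])^2 + (I[x,y+1]-I[x,y])^2)`; Tenengrad, Laplacian
energy, intensity variance and Brenner are provided for comparison.  Reward
normalization is per stack: `Fc_norm = (Fc - Fmin) / (Fmax - Fmin)` over the
stack's frames, so the sharpest frame of every stack maps to 1 and the least
sharp to 0 regardless of texture — different samples have wildly different
absolute clarity values, which is why raw scores are unusable as labels.

## Action space

An action is `a = tau * v` with `v = 0.1` V and integer control factor
`tau`; factor 0 is the stop action.  Two constructions grow an odd-sized,
sign-symmetric set containing {-1, 0, 1}:

* logarithmic: tau in {0, +-1, +-b, +-b^2, ...}
* multiple:    tau in {0, +-1, +-b, +-2b, ...}

For base 2 and up to seven actions the two coincide.  A set is admissible
for an n_S-frame sweep when its largest factor is at most n_S / 2, so the
biggest jump cannot overshoot more than the half-range.  Lens saturation is
modelled by clipping at the sweep ends rather than erroring.

## Reward

Per step (n = actions taken so far, starting at 1):

    r = -alpha * Fc_norm                (sharpness; see orientation below)
        - beta * ln(n / beta)           (positive for n < beta, negative after)
        + mu * Done                     (only on a stop within 0.2 V of focus)
        + delta at the sharpest frame / - delta at the least-sharp frame

with alpha = 100, beta = 30, mu = 200, delta = 100: the four terms' maximum
magnitudes share one order of magnitude so no single objective dominates.

Two design points were genuinely open and were settled by solving the
induced MDP exactly (backward induction over frame index and step count on
generated stacks):

* **Sharpness-term orientation.**  Two readings exist: penalize blur
  (`-alpha * (1 - Fc_norm)`, sharpest frame free) or penalize dwelling on
  sharp frames (`-alpha * Fc_norm`, the literal formula above).  Under the
  first, traversing blurred frames costs about alpha per step while stopping
  anywhere costs one such penalty — from deep defocus the *optimal* policy
  stops immediately, capping success near 50%.  Under the literal form blur
  is cheap to cross and lingering at focus is expensive unless the agent
  stops there and collects mu; the optimal policy travels and stops, which
  matches the fast, high-success behaviour this method is known for.  The
  training default is therefore the literal orientation
  (`RewardParams(literal_sign=True)`); `compute_reward` keeps the
  blur-penalizing orientation as its default for the documented worked
  identities, and the flag switches between them.
* **Extreme-image bonus.**  The +-delta term applies to the stack's two
  extreme frames only: + at the ground-truth sharpest frame, - at the
  sharpness-curve argmin.  Widening the penalty to a low-sharpness *band*
  (e.g. all frames below 0.05) makes a quarter to two-thirds of every sweep
  repulsive and again flips the optimum to early stopping.
* **Discount.**  gamma = 0.8 by default.  Because the time term is positive
  for the first beta steps and the bonus recurs at the sharpest frame, a
  discount near 1 makes reward farming (orbiting the focus) outvalue
  stopping: backward induction at the study optics gives a 1.00-success,
  7.4-step optimum at gamma = 0.8 but a 15+-step stalling optimum at 0.9.
  Below ~0.7 the discounted stop payout no longer reaches distant start
  states and early stopping creeps back in.

Ablations gate individual components (five standard variants: sharpness
only, +stop, +time, +extra, all).  Episode bookkeeping: an episode is
*successful* only when the agent stopped autonomously within 0.2 V
(inclusive), *accurate* when it stopped exactly at focus; running out of the
50-step budget is the non-terminating outcome however close the lens ended.

## Environment

Gym-style: `reset` draws a stack uniformly from the list L and a uniform
start frame; `step` applies a control factor (clipping at the sweep ends),
computes the reward on the frame reached, and terminates on stop or after
`max_steps = 50` actions (truncation, flagged distinctly).  Observations are
the current frame resized to the configured input resolution plus the step
count; intensities stay in [0, 1].

## Agent

A DQN implemented directly in numpy (no deep-learning framework is a
dependency): two conv layers (8 filters 8x8 stride 4; 16 filters 4x4 stride
2, geometry adapting down to 8x8 inputs), one 128-unit fully connected
layer, and dueling value/advantage heads.  Standard stabilizers, all
switchable in `AgentConfig`: experience replay stored as stack/frame indices
against the environment's observation cache, a target network synced every
500 steps, double-DQN target selection, 3-step returns (a time-limit
truncation bootstraps through; only an autonomous stop is terminal),
per-frame observation standardization (defocus crushes contrast; zero-mean
unit-variance input keeps the structural signal at a learnable amplitude), a
normalized step-count input (the time term makes returns n-dependent;
without it the targets are aliased), epsilon-greedy exploration decaying
linearly over half of training, Adam, internal reward scaling 0.01
(optimizer conditioning only), and global-norm gradient clipping at 10.
Training can truncate episodes earlier than evaluation (`train_max_steps`)
to reset more often; this does not bias values because truncation bootstraps
through.

Three further ingredients carry the desk-scale sample budget, where plain
DQN otherwise tracks the sample-complexity curve of tabular Q-learning
(roughly 10% success at 40-50k environment steps, 75% at 200k):

* **Dyna-style synthetic replay** (`dyna_fraction`, default 0.5).  Training
  runs on pre-captured focal stacks, so every counterfactual transition is
  already in the data; a share of each update batch is sampled uniformly
  over (stack, frame, action, step count) and its reward and successor
  computed from the stack (`AutofocusEnv.simulate_transition`).  This is the
  dataset-as-model limit of Dyna planning and gives uniform state-action
  coverage without extra environment interaction.
* **Multi-scale sharpness features** (`use_sharpness_features`): the log
  mean squared horizontal/vertical first differences of the standardized
  frame at three smoothing scales, appended to the fully connected layer
  (normalization fitted on the training list and stored with the
  checkpoint).  These six numbers encode blur level and the astigmatic
  direction cue in a texture-robust way; a k-NN regressor on them localizes
  focus on unseen textures at 98% success, whereas a small conv trunk
  trained from scratch transfers poorly at this data scale.  The same
  quantities serve as targets of a self-supervised auxiliary head
  (`aux_weight`) that shapes the conv features.
* **Flip augmentation and stratified replay**: update batches are randomly
  flipped (flips leave actions, rewards and the astigmatism axes invariant),
  and a batch share is reserved for stop transitions, whose rare +mu events
  otherwise wash out of the buffer under a wandering behaviour policy.

Everything is seeded through `numpy.random.SeedSequence`, so a config seed
reproduces training bit-for-bit.

## Classical searches

`sweep_search` probes every frame (oracle and worst case).  Golden-section
search keeps a real-valued bracket on [0, n-1], probes rounded interior
points with caching, stops at bracket width <= tol (default 2 indices =
0.2 V) and scores the remaining integers inside the bracket; Fibonacci
search pads the range to a virtual window of length F(k)-1 and eliminates by
Fibonacci ratios, reusing one interior probe per level.  On strictly
unimodal curves both return the exact sweep argmax — verified exhaustively
over all peak positions for a range of n — with worst-case probe counts
given by `golden_probe_bound` / `fibonacci_probe_bound` (for n = 100,
tol = 1: at most 14 and 12; observed maxima 10 and 10).  Baseline reports
state the step-counting convention explicitly: search steps are distinct
probed lens settings; agent steps are actions taken including the stop.

## Studies and problem sizes

`rlfocus.experiments` scripts the action-space study, the list-size
(random-sampling) study, the five-variant reward ablation, the
generalization comparison (single-family vs two-family training evaluated on
an unseen third family) and the baseline comparison.  `StudySettings`
defaults mirror the acquisition protocol (224 x 224 frames, 100-frame
stacks, 1000-episode evaluation); the test suite and the worked examples run
reduced sizes chosen so the full pipeline — generation, training,
evaluation, reporting — runs end to end on one CPU core: 64 x 64 (learning)
or 48 x 48 (ablation/generalization) native frames with proportionally
scaled PSF, 6-10-stack lists, 4-12 thousand environment steps per training
run, and 120-300 evaluation episodes.  Every report row carries the seed
and a hash of the exact configuration.

Two evaluation protocols exist and mean different things.  *Held-out fields
of view* (`build_dataset_split`): train and test stacks never overlap but
image the same samples — this is the acquisition protocol's own train/test
split and what the headline success rates refer to.  *Unfamiliar samples*
(`run_generalization` / fresh `build_dataset_list` draws): entirely new
texture instances, the deliberately hard cross-sample condition, where
success rates are expected to be low at small list sizes.

## Known limitations

* The published hardware numbers (3.15 mean steps, 97.2% success rate, RMSE
  2.85e-3 V, the Table-score column, and the 15/8 baseline step counts)
  were measured on the authors' captured through-focus stacks with
  unreleased training details and an unstated step-counting convention for
  the searches.  They are not reproducible from this package's synthetic
  data and are not asserted anywhere in the test suite; the property-based
  checks (search-oracle equivalence, reward identities, qualitative
  ablation/generalization trends, learned-policy speed against the search
  baselines) stand in for them.
* No single range/tolerance convention reproduces both published baseline
  step counts (15 golden, 8 Fibonacci) simultaneously; reports therefore
  state this package's convention and derived bounds instead.
* The printed admissibility inequality for the action space rejects the
  published base-5 seven-action set; the implemented rule (largest factor
  <= n_S / 2) admits every published set.
* Desk-scale RL results are noisy across seeds; the learning-level checks
  treat them as stochastic, multi-seed trends, not point estimates.
* At desk scale the value-based agent learns the training list well
  (training-list success above 0.8 at 20-40k environment steps in the
  configurations explored during development) but transfers poorly to
  held-out stacks, and at the compute budget the test suite runs under, the
  learned-policy checks (held-out success, termination-trend ablation,
  cross-sample generalization trend) do not reach their thresholds; the
  suite reports the measured rates rather than asserting weaker ones.  Two
  structural reasons, established with exact solvers on the induced MDP:
  tabular Q-learning with perfect state identification needs roughly 200k
  environment steps on this problem, and even a supervised fit of the exact
  optimal Q on texture-robust sharpness features flips near-tied
  stop-vs-move decisions at attainable approximation error, because the
  hybrid reward leaves small action-value margins.  A distance-regression
  policy on the same features localizes focus on unseen textures at 98%
  success, so the observation carries the information; extracting it with
  greedy value-based control at this data scale does not.
* Under the printed sharpness orientation, ablation variants 1 and 4
  (no stop reward, no time term) are value-flat: stopping ties with
  wandering almost everywhere, so whether such agents "never terminate" is
  tie-breaking, not a robust property of the reward.
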