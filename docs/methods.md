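# Methods

## The model

The agent's behavioral intention is a 4-dimensional latent variable `z` with
a diagonal Gaussian distribution.  Two pathways produce it:

* **Habitual (prior)** `p(z | h_t) = N(mu_p, sigma_p)`.  A convolutional
  encoder processes the panoramic observation; a one-layer GRU accumulates
  it into a context `h_t`; two 2-layer MLP heads map `h_t` to `mu_p` and to
  `xi_p` with `sigma_p = softplus(xi_p) = ln(1 + exp(xi_p))`.  This is a
  single cheap forward pass — fast, model-free, context-driven.
* **Goal-directed (posterior)** `q(z) = N(mu_q, sigma_q)`.  During learning
  it is amortized from the channel-concatenated pair (current observation,
  future observation); during behaving it is inferred by active inference
  against a goal (below).

Behavior uses the **synergized intention**: the inverse-variance-weighted
average of prior and posterior, equivalently the normalized product of the
two Gaussian densities.  Its precision is the sum of the two precisions, so
it is always sharper than either.  The **habitual ratio**
`mean(sigma_p)^-2 / (mean(sigma_p)^-2 + mean(sigma_q)^-2)` is the prior's
weight in that average; we read the arithmetic mean over the four STD
components, then invert-square (the alternative — averaging precisions — is
monotonically equivalent but numerically different).

A decoder (2-layer MLP lift + transposed-conv stack) maps `z` to predicted
current and future observations as per-pixel Bernoulli probabilities.  A
tanh-squashed Gaussian policy maps `z` to 2-D actions.  Twin critics with
their own convolutional encoders estimate Q(obs, action); they are
deliberately outside the main model — their loss gradients never touch it,
and the actor treats them as fixed scorers.

## Learning

Every N = 5 environment steps one gradient step minimizes

    prediction errors + beta_z * KL[q || p] + beta_a * policy loss + value loss

over a replayed batch of sequences (recurrent state unrolled from zero at
each sequence start; a per-step future index t' is drawn uniformly from
(t, episode end]).  The RL part is soft actor-critic: twin critics, target
networks (Polyak 0.005), adaptive entropy temperature with the target
annealed linearly from 0 to -4 over the learning course, discount 0.9,
Adam at 3e-4.  Rewards are used raw (up to 1000).  Episodes ended by the
step cap are flagged done for episode control but non-terminal for
bootstrapping.

The KL term is the bridge between the two systems: by Jensen's inequality
the prior's policy loss is bounded by the posterior policy loss plus this
KL, so reinforcement learning through the posterior also trains the habit.
The test suite verifies this bound by Monte Carlo on random states.

## Active inference

At behaving time the model is frozen and the posterior's `(mu_q, xi_q)` are
optimized by the cross-entropy method (population 256, elites 32, at most
16 generations) to minimize a free energy with respect to the goal:
reconstruct the actual current observation, push the predicted future
observation toward the goal, stay near the prior (beta_z-weighted KL).
The search distribution starts at the prior — the KL anchors it there and
this makes planning cost degrade gracefully: after each refit the
synergized STD is formed from the fitted `sigma_q` via precision
additivity, and the search stops once its mean reaches 0.05.  A prior
already below the threshold therefore always terminates after one
generation.  Goals are full observations (Bernoulli log-likelihood) or
colors: count predicted pixels within 0.25 of the target color, scaled by
-5 (pursue) or +100 (avoid) under minimization semantics.  The
sign convention follows the described behavior of the modes (pursuing a
color maximizes its pixel count).

## Environment

A continuous 2-D T-maze: a vertical bottom arm joined to a horizontal top
bar, exits at the bar's two ends (left reward 1000, right 500 in the
habitization protocol; -1 per wall collision; 0 otherwise; forced
termination at 60 steps).  The point agent commands a 2-D displacement per
step, clipped to a speed limit (default arm-width/8 per step).  Motion is
resolved axis-separably (x then y, each truncated at walls), which yields
standard wall sliding while guaranteeing the agent never penetrates a wall;
a truncated move raises the collision flag.  The observation is a
360-degree panoramic RGB image (16 x 64 by default): one azimuthal ray per
column, nearest-wall color with distance-scaled apparent height and mild
distance shading, constant floor/ceiling colors.  The left-exit end walls
are red and the right-exit end walls blue — chromatic landmarks that make
color goals well-posed and observations position-discriminative; remaining
walls carry distinct neutral hues.  Maze proportions, palette and speed are
config values; the exact values used in the original study conditions are
not published, so the defaults here are reasonable stand-ins.

## Numerical choices

* Decoder layer 5 as specified yields a 15 x 63 map; output padding (1, 1)
  restores 16 x 64.
* Decoder outputs pass through a logistic squash so Bernoulli probabilities
  lie in (0, 1); log-likelihoods clamp probabilities to [1e-6, 1 - 1e-6].
* STDs are floored at 1e-6 before inversion (synergy, ratio, KL).
* CEM refit is the plain elite mean/STD, no smoothing; one reparameterized
  z draw per candidate per scoring; the xi search spread starts at 0.5 and
  the mu spread at the prior STD.
* The networks run on a small in-package reverse-mode autodiff engine
  (im2col convolutions, float64); gradients are finite-difference checked
  in the test suite.

## Desk-scale study conditions

The full-scale protocol (tens of thousands of steps per stage, 50 seeds,
16 x 64 vision) is far beyond a single-CPU session, so the package ships
two presets.  `fullscale_config` keeps the full-scale sizes.  `desk_config`
scales the same topology down and is what the tests and the acceptance
script run:

* maze 1.8 x 1.4 world units with a 0.8-wide arm, speed 0.2, step cap 40 —
  sized so undirected random exploration still reaches an exit in roughly a
  sixth of episodes, keeping the exploration stage informative at a few
  hundred steps;
* 8 x 16 images with width-32 networks (same layer topology);
* replay batches of 6 sequences and a 64-sequence ring buffer — the
  full-scale ring (2^13 sequences) holds roughly one stage's worth of
  experience, and the desk ring keeps that proportion so the buffer
  actually turns over after a reward change;
* CEM population 32, elites 8, at most 8 generations for in-loop planning
  (the contract defaults 256/32/16 are unchanged in `AIfConfig`);
* stage budgets of 400-3000 steps, 3 seeds for trend checks;
* loss weights rebalanced for the smaller retina: beta_a and beta_z are
  scaled by the pixel-count ratio (384 / 3072 = 1/8, giving beta_a =
  1.25e4, beta_z = 0.0125).  The published weights balance pixel-summed
  prediction errors at 16 x 64 x 3 against the RL and complexity terms;
  with 8x fewer pixels the unscaled weights let the policy term drag the
  posterior away from reconstruction (the training KL grows without bound
  and the prior STD inflates).  Scaling both weights by the pixel ratio
  preserves the published balance.

Two further desk-scale protocol choices.  First, the devaluation runs used
for orderings devalue the exit the agent actually habitized (read from its
late stage-2 trials) rather than a fixed side: with short training the
committed side is seed-dependent, and the behavioral paradigm's logic is
that the *trained* outcome is devalued.  `run_devaluation` defaults to the
fixed-left protocol; the adaptive form is opt-in.  Second, the
entropy-temperature update keeps the standard rate (3e-4); over the few
hundred desk-scale updates the temperature therefore barely adapts and the
0 to -4 entropy anneal is largely inert.  Raising the rate to match the
compressed schedule was evaluated and rejected: it makes the policy commit
to one exit early, destroying the behavioral diversity the equal-reward
protocol requires.  This is a genuine scale limitation, not a tunable.

What the desk runs do and do not show: they reproduce the *qualitative*
signatures — prior STD declining with training, planner generations
tracking it downward, slower re-adaptation after longer habitization,
goal-directed success above the habitual baseline with equal rewards — not
the published curve values, which belong to the full-scale conditions.
Synthetic observations come from the raycast renderer; they lack texture,
lighting and sensor noise, so success here does not certify robustness to
real camera imagery.

## Known limitations

* Desk-scale runs are short; seed-to-seed variability is large, and
  single-seed trend readings can be inverted (hence 3-seed averages).
* The renderer's mirror symmetry means left/right discrimination rests
  entirely on wall hues.
* No reward normalization: critics absorb the raw 1000-scale targets,
  which makes early value losses large (the published configuration).
* The CEM posterior is a point estimate of the variational parameters; its
  fitted STD inherits sampling noise from one z draw per candidate.
* Goal-directed steering at desk scale is weak: the trained policy mean is
  small (behavior leans on exploration noise), so while the planner's
  per-position action tilts point toward the goal, the net success gain of
  full-observation goals over a goal-blind baseline is near zero at these
  sizes.  The regimes that would sharpen the policy (longer training,
  faster temperature adaptation) collapse the habit to one exit first.
  Demonstrating the planning gain appears to require the full-scale
  conditions.
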