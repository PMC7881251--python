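# Methods

`kinetree` implements a complete modelling pipeline for motion-structure
identification: how an observer infers which latent pattern of shared
motion sources couples the velocities of objects in a dynamic scene. This
note documents the generative model, the observer and choice models, the
fitting and comparison machinery, the synthetic-participant generator, and
the numerical choices behind them.

## Stimulus model

### Structure algebra

Three dots move on a circle, driven by five latent motion sources: a
global source `g` (all dots), a cluster source `c` (dots 1 and 2), and one
individual source per dot. A binary basis matrix `B` (3×5) records the
dot–source wiring and a strength vector
Λ = (λ_g, λ_c, λ_1, λ_2, λ_3) ≥ 0, in rad·s^(−3/2), scales each source.
Four prototypes are defined: independent (I), global (G), clustered (C)
and hierarchical (H).

All experimental structures satisfy the **equal-marginal constraint**

    λ_g² + λ_c² + λ_k² = 2²   for every dot k's root-to-leaf path,

i.e. `diag(BΛ²Bᵀ) = (4, 4, 4)`. With marginal speed distributions pinned,
velocity *correlations* are the only cue to the structure. Concretely
(with `s² = 4 − 1/16 = 3.9375` the shared global+cluster budget):

| structure | λ_g²      | λ_c²      | λ_1, λ_2 | λ_3            |
|-----------|-----------|-----------|----------|----------------|
| I         | 0         | 0         | 2        | 2              |
| G         | 3.9375    | 0         | 1/4      | 1/4            |
| C         | 0         | 3.9375    | 1/4      | 2              |
| H         | 0.75·s²   | 0.25·s²   | 1/4      | √(4 − 0.75·s²) |

The individual strength of dot 3 — the dot outside the cluster — always
absorbs whatever the global source does not provide, `λ_3 = √(4 − λ_g²)`;
this is forced by the constraint (a table that kept λ_3 = 1/4 for C and H
would give dot 3 a marginal variance of 1/16 instead of 4 and make it
trivially identifiable by speed alone, defeating the design).

**C↔H morphs** interpolate at fixed marginals via the fraction
`f = λ_g²/(λ_g² + λ_c²)` of the shared budget carried by the global
source: λ_g² = f·s², λ_c² = (1−f)·s². f = 0 reproduces C exactly and
f = 0.75 reproduces H exactly; the 2-AFC task uses
f ∈ {0.00, 0.20, 0.35, 0.55, 0.75}.

The constant 4 (= 2²) is stored once (`MARGINAL_SPEED_SQ`) so alternative
stimulus families can rescale it. Angles are radians on [0, 2π),
velocities rad/s; the generative equations are unit-consistent under this
choice, which matches the mod-2π wrapping of the position dynamics.

### Scene dynamics

Dot positions z and velocities v follow a multivariate
Ornstein–Uhlenbeck process,

    dz = v dt,    dv = −v/τ dt + B Λ dW,

with friction time constant τ = 1.5 s and a 5-dimensional Wiener process.
Provided all individual strengths are positive, the stationary law is
v ~ N(0, (τ/2) B Λ² Bᵀ) with positions asymptotically independent-uniform
on the circle; scenes are initialized from it, so there is no burn-in.
Integration is Euler–Maruyama at `sim_dt` = 1 ms (per-step noise
`BΛ·√dt·ξ`, ξ five standard normals; no higher-order scheme), positions
wrapped mod 2π each step. The state is recorded at the 50 fps frame rate
(`frame_dt` = 20 ms) without sub-step averaging; a 4 s trial yields 201
frames at t = 0, 0.02, …, 4.0. Stored positions are noise-free: the
observation noise σ_obs is a property of the observer, not the stimulus.
The Euler discretization inflates the stationary velocity variance by the
factor 1/(1 − dt/2τ) ≈ 1.0003 at the default step — far below sampling
error at any feasible scene count.

Per-trial color permutations are metadata only; they never touch the
stored trajectories. Display geometry (dot diameter, orbit size) and the
frozen pre/post intervals of the live experiment carry no motion
information and are not modelled.

## Ideal observer

The observer sees only noisy positions x(t) ~ N(z(t), σ_obs² I) at frame
times and inverts the generative model by Kalman filtering with the
frame-resolution transition

    F = [[I, δt·I], [0, (1 − δt/τ)·I]],
    Q = [[0, 0], [0, δt·(P_m B) Λ² (P_m B)ᵀ]].

One forward filter runs per hypothesis — a structure S combined with a
dot-to-role permutation m from its multiplicity set M(S), where
M(I) = M(G) = {1} and M(C) = M(H) = {1, 2, 3} (the three ways to pick the
clustered pair). The trajectory log-likelihood accumulates the innovation
densities Σ_t log p(x(t) | x(0..t−1)); the structure-independent p(x(0))
factor is dropped because it cancels in every posterior and choice
probability (absolute log-likelihoods are therefore defined up to a
trial-level constant; all reported quantities are invariant to it).

Numerical choices:

* **Circularity.** Position innovations are wrapped to (−π, π] before the
  update, and the posterior position mean is wrapped to [0, 2π). With all
  dots always visible the posterior position uncertainty is ≪ π, so this
  minimal treatment is exact for practical purposes. A whole-scene
  rotation test (shift all angles by a constant mod 2π) confirms
  likelihood invariance through the seam.
* **Initialization.** Velocity prior = stationary N(0, (τ/2)(P_mB)Λ²(P_mB)ᵀ);
  position posterior after the first frame = N(x(0), σ_obs² I), which is
  the exact update of the uniform circular prior for σ_obs ≪ π.
* **σ_obs floor.** σ_obs = 0 would make the first innovation covariance
  singular; the filter floors it at 1e−6 rad. (The correlation-template
  model's "noise-free" empirical velocities never pass through the
  filter.)
* The innovation covariance sequence is data-independent, so gains are
  precomputed once per hypothesis and scenes are evaluated in batches;
  the filters for different hypotheses remain numerically independent.
* Natural logarithms throughout.

The posterior applies the multiplicity penalty,

    P(S | X) ∝ Σ_{m∈M(S)} exp( ll_{S,m} − log|M(S)| ) · P(S),

which makes the evidence-free posterior uniform despite C and H carrying
three hypotheses each. Log-odds log P(S|X) − log P(¬S|X) are computed as
a difference of log-sum-exps, so no epsilon clamping is needed for finite
inputs (reporting clamps at ±30 nats for display only).

An independent oracle — unrolling the linear-Gaussian model into the full
joint covariance of the stacked observations and evaluating one
multivariate normal density — agrees with the recursive filter to better
than 1e−8 nats on unwrapped scenes; this dual route is asserted in tests.

## Choice models

The full choice model wraps three imperfections around the Bayesian core:

    P(choice=S | X) = π_L/K + (1 − π_L) ·
        softmax_S( logsumexp_{m∈M(S)} β·(ll_{S,m} + b_S − log|M(S)|) ),

with lapse probability π_L, inverse temperature β > 0, and biases b_S
acting as log-priors relative to a reference structure (b_I ≡ 0 in the
4-AFC task; b_C ≡ 0 in the 2-AFC task, leaving β and b_H). The
multiplicity penalty sits *inside* the β exponent, exactly as the model
is defined. A consequence worth knowing: with all log-likelihoods equal,
choice probabilities are proportional to |M(S)|^(1−β) — uniform at β = 1,
but e.g. (3/8, 3/8, 1/8, 1/8) over (I, G, C, H) at β = 2. This is a
property of the model, documented and tested rather than "corrected".

**Bayesian predicted confidence** is the same formula at π_L = 0, β = 1
with the participant's fitted biases, evaluated at the chosen structure —
the subjective posterior belief of having chosen correctly. Analysis
curves use this deterministic quantity; a generative binary-confidence
rule (threshold θ) exists only in the synthetic-participant module and is
explicitly an extension for end-to-end testing.

**Non-Bayesian (correlation-template) model.** The core is replaced by
the negative r-norm distance between a trial's empirical pairwise
velocity correlations and each structure's analytic template, the
off-diagonals of (1/4)(P_mB)Λ²(P_mB)ᵀ. Empirical velocities are
finite differences of the presented positions with angular differences
unwrapped to (−π, π] (true per-frame steps are ≪ π at the experiment's
speeds, SD ≈ √3 rad/s × 0.02 s, so unwrapping is unambiguous); no
observation noise is involved. Shared parameters are (r, π_L), replacing
(σ_obs, π_L).

## Fitting

Two stages, mirroring the identifiability argument that σ_obs, π_L and β
all modulate the psychometric slope:

1. **Shared grid search** over σ_obs ∈ {0.1, …, 2.1} (step 0.1) and
   π_L ∈ {0.02, …, 0.40} (step 0.02), maximizing the summed response
   log-likelihood with per-participant parameters profiled out at every
   grid point. Kalman tables are cached per σ_obs; ties break toward
   smaller σ_obs, then smaller π_L; a grid point with a failed inner fit
   is marked invalid and recorded, never silently skipped.
2. **Per-participant ML** of (β, b_G, b_C, b_H), or (β, b_H) for 2-AFC,
   by L-BFGS-B on (log β, b) with the analytic gradient (verified against
   numerical differentiation). log β is bounded to [log 1e−3, log 1e3] to
   enforce β > 0; biases to ±20. Multi-starts are deterministic:
   β ∈ {0.1, 0.5, 1, 2, 5}, b = 0.

During the grid scan, each σ_obs column restarts from the full
multi-start and then warm-starts along π_L with one extra β = 1 start per
point. Warm-starting *across* σ_obs columns is unreliable — the
log-likelihood spread rescales with σ_obs and the profile optimum can
jump basins, which corrupts the profile surface; the per-column restart
removes this failure mode at about twice the cost.

Finite-sample behavior, measured by the recovery harness: at 200 trials
the per-participant ML estimates carry the usual O(1/n) bias away from
zero (bias estimates can inflate when a response category is nearly
separable, a lapse-bounded analogue of logistic-regression separation);
cohort means remain within ~2 Monte-Carlo s.e. of truth at 20
participants, and errors shrink roughly ∝ 1/√n by 800 trials. The shared
grid search recovers the generating (σ_obs, π_L) = (1.1, 0.14) to within
one grid step; the profile surface is flat along a mild σ_obs–β ridge, as
expected from the identifiability argument above.

**Cross-validation** is leave-one-out: per held-out trial, the
per-participant parameters are refitted on the remainder (warm-started
from the full fit) and the held-out choice distribution recorded; a fold
whose optimizer fails falls back to the full fit and is flagged. The
**shuffle control** permutes responses uniformly within same-structure
strata (same-morph-level for 2-AFC), preserving the confusion matrix
exactly while destroying the stimulus–response pairing. The **transfer
model** carries a 4-AFC fit to the 2-AFC task with bias b_H − b_C (the
relative log-prior between H and C) and unchanged β, σ_obs, π_L.

A tabular adapter (`sessions.save_session` / `load_session`) defines the
plain-text dialect for external datasets: a trials table (trial, scene,
structure, morph, pair, choice, confidence) plus a long-format scene
table. Rows failing validation raise immediately; the adapter never
filters.

## Model comparison

Variants: full; bias-free (all b_S = 0); lapse-free (π_L = 0); and the
correlation-template model with shared (r, π_L) refit by grid search
(r ∈ {0.5, 1, 1.5, 2, 3} by default — the norm order only needs coarse
resolution, and the grid brackets the city-block-to-Euclidean range a
template matcher plausibly spans). Each variant is refitted under its own
constraint; comparisons use per-participant LOO cross-validated summed
log-likelihoods, which also serve as the log-evidence surrogate for
random-effects Bayesian model selection.

**PXP.** Population model frequencies get a Dirichlet prior (α₀ = 1);
a variational loop alternates per-participant assignment posteriors and
Dirichlet updates. Exceedance probabilities are estimated by seeded
Monte-Carlo sampling of the fitted Dirichlet (10⁵ draws; the MC standard
error is reported). Protection: the Bayes omnibus risk—the posterior
probability of the null that all frequencies equal 1/K, from the
variational free energy against the null's exact evidence—mixes the
exceedance vector with uniform: PXP = (1 − BOR)·EP + BOR/K. Per-row
centering of the log evidences cancels in BOR and is used for numerical
stability. No BIC/AIC alternative is computed by default.

## Synthetic participants

The generator reproduces the experimental designs: 4-AFC sessions of
100 unique scenes (structures drawn uniformly) duplicated to 200 shuffled
trials with recorded repetition pairs and per-trial color permutations;
2-AFC sessions of 20 trials per morph level, shuffled, without
repetitions. Responses are sampled from the choice model under known
parameters; binary confidence is high iff the Bayesian predicted
confidence exceeds θ (default 0.6, near the middle of the 4-AFC
confidence range [0.25, 1]).

Cohort ground truth: shared (σ_obs, π_L) = (1.1, 0.14) rad — the
experiment-scale operating point; per-participant β log-uniform on
[0.5, 2] (bracketing mild probability-matching to moderately
deterministic responding, the regime where consistency lies strictly
between chance and 1) and biases i.i.d. N(0, 0.5²) (noticeable but not
dominant prior distortions). One master seed per session spawns
independent child streams for scene batches (one per structure/morph
group), trial order, colors, and responses, so regenerating responses
never perturbs scenes and whole sessions are exactly reproducible.

What the generator does *not* emulate: sequential dependencies between
trials (the models treat every trial in isolation, and so does the
generator), learning or attention drift, reaction times, and any
deviation of real observers from the fitted model family. Passing
recovery and comparison tests therefore certifies the pipeline's internal
consistency — that the code inverts its own generative assumptions at
experimental sample sizes — not that those assumptions hold for humans.

## Reporting

Confusion matrices are row-normalized empirical frequencies (empty rows
reported as undefined, not zero); the model version averages per-trial
predicted distributions by true structure, an identity asserted in tests.
Psychometric and confidence curves default to 10 equal-count bins over
the pooled x-variable (ideal-observer log-odds clamped at ±30 nats, or
logit Bayesian confidence), retaining counts for binomial error bars;
empty bins are reported missing. Binning is a display choice, so curve
comparisons are qualitative (shape, monotonicity), never bin-by-bin.
Repetition consistency is the fraction of duplicated-scene pairs with
identical choices; cohort s.e.m. uses the n−1 denominator.

## Problem sizes in the test suite

The end-to-end suite runs one 20-participant × 200-trial 4-AFC cohort at
the full experimental scene length (the same cohort serves recovery,
shuffle-control, and model-comparison checks), 5 000 scenes per prototype
for the stationarity check, 500 scenes per structure for the
ideal-observer confusion matrix, and an 8-participant 2-AFC cohort for
the morph psychometric — sizes at which every targeted effect is several
standard errors wide while the whole suite completes in minutes on one
CPU. Unit tests use shortened scenes (1 s) where scene length is
irrelevant to the property under test.

## Known limitations

* Only the 3-dot, 5-source family is implemented end to end (basis and
  strength dimensions are parameters, not literals, but deeper trees and
  larger choice sets would need new multiplicity sets and prototypes).
* The Kalman filter treats the circle by innovation wrapping; for
  observation noise approaching π (far beyond the fitted regime) the
  Gaussian-on-circle approximation would degrade.
* Per-participant ML estimates at 100–200 trials are noisy and can sit at
  the β bounds for nearly-separable response sets; cohort-level
  conclusions should rely on shared fits, cross-validation, and
  random-effects comparison, as implemented.
* The absolute trajectory log-likelihood omits the structure-independent
  p(x(0)) constant; only likelihood differences are meaningful.
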