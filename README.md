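# kinetree

Hierarchical motion-structure inference: stochastic circular dot stimuli,
a Kalman-filter ideal observer, probabilistic choice models, and
random-effects model comparison.

## The problem

When several objects move at once, their velocities are often coupled
through latent structure — birds in a flock share the flock's motion, a
nested object moves inside a moving reference frame. The structure itself
is never observable: it must be inferred from the velocity relations it
induces. `kinetree` implements a complete, testable pipeline for studying
that inference in the classic laboratory reduction: three dots on a
circle whose angular velocities are coupled by one of four structures —
independent (I), global (G), clustered (C) or hierarchical (H) — or by a
continuous morph between C and H. It is written for computational
cognitive scientists and psychophysicists who want to simulate the
stimuli, run the normative observer, fit choice models to (real or
synthetic) responses, and compare model variants.

## The model

**Stimulus.** Velocities follow a multivariate Ornstein–Uhlenbeck process
`dv = −v/τ dt + BΛ dW` (τ = 1.5 s) with basis matrix B wiring five latent
sources (global g, cluster c, three individual) to three dots, and
strengths Λ(S) defining structure S. All structures satisfy
`diag(BΛ²Bᵀ) = (4,4,4)`, so every dot has the same marginal speed
distribution and *correlation is the only cue*. Scenes are initialized in
the stationary law and integrated by Euler–Maruyama (1 ms), observed at
50 fps for 4 s.

**Ideal observer.** A bank of Kalman filters, one per hypothesis
(structure S, dot permutation m ∈ M(S)), accumulates trajectory
log-likelihoods `log p(X | P_m B Λ(S))` from innovations; the posterior
penalizes multiplicity so that an evidence-free posterior is uniform:

    P(S | X) ∝ Σ_{m∈M(S)} exp( log p(X | P_m B Λ(S)) − log|M(S)| )

**Choice model.** Human-style imperfections wrap the Bayesian core:
lapse π_L, inverse temperature β, structure biases b_S,

    P(choice=S|X) = π_L/K + (1−π_L) softmax_S( logsumexp_m β(ll_{S,m} + b_S − log|M(S)|) )

with shared (σ_obs, π_L) fitted by grid search and per-participant
(β, b_S) by maximum likelihood; leave-one-out cross-validation, a
within-structure response-shuffle control, a 4-AFC→2-AFC transfer model,
a non-Bayesian correlation-template alternative, and protected exceedance
probabilities (PXP) complete the pipeline. A synthetic-participant
generator reproduces the experimental session designs with known ground
truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from kinetree import (make_prototype, simulate_scene, evaluate_scene,
                      structure_posterior, experiment_defaults)

scene = simulate_scene(make_prototype("C"), experiment_defaults(), seed=3)
liks = evaluate_scene(scene, sigma_obs=1.1)     # 8 (structure, permutation) hypotheses
print(np.round(structure_posterior(liks).to_numpy(), 4))
```

```
[0.0165 0.     0.3272 0.6562]
```

The posterior over (I, G, C, H) for this clustered-motion trial puts most
mass on H and C and nearly none on I and G: the scene is genuinely
ambiguous between the two structures that share a strong pairwise
correlation — exactly the ambiguity the morph experiment exploits. Over
100 scenes per structure the observer's MAP choice is correct 72–100 % of
the time depending on structure, with C↔H the most confusable pair
(`examples/03_ideal_observer.py` prints the full confusion matrix).

The `examples/` directory walks through each capability — structure
algebra and morphs, scene simulation and equilibrium, the ideal observer,
two-stage fitting with the shuffle control, model comparison with PXP,
and the 2-AFC morph psychometric — each printing a few numbers and a line
on what they mean.

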