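"""Two-stage fitting on a synthetic cohort (parameter recovery).

Generates a small cohort of synthetic 4-AFC participants with known
(beta, b_S) and shared (sigma_obs = 1.1, pi_L = 0.14), runs the shared
grid search on a coarse grid plus the per-participant maximum-likelihood
fits, and prints recovered vs. true parameters.  Also demonstrates the
shuffle control: cross-validated log-likelihood collapses when responses
are permuted within same-structure strata, although the confusion matrix
is untouched.
"""

import numpy as np

from kinetree import (
    consistency,
    fit_participant,
    fit_shared,
    loo_cv_predict,
    make_cohort,
    shuffle_control,
)

datasets, specs = make_cohort(n_participants=4, seed=11, n_unique=50)
print("Cohort: 4 participants x 100 trials (50 unique scenes x 2).")

sf = fit_shared(datasets, scale_grid=[0.7, 0.9, 1.1, 1.3],
                pi_grid=[0.06, 0.14, 0.22])
print(f"\nShared fit: sigma_obs* = {sf.sigma_obs}, pi_L* = {sf.pi_lapse} "
      f"(truth: 1.1, 0.14)")

print("\nPer-participant fits at the shared optimum:")
for ds, spec, fit in zip(datasets, specs, sf.participant_fits):
    print(f"  {ds.participant}: beta {fit.beta:5.2f} (true {spec.params.beta:4.2f})  "
          f"b_H {fit.biases['H']:+5.2f} (true {spec.params.biases['H']:+5.2f})  "
          f"consistency {consistency(ds):.2f}")

ds = datasets[0]
cv = loo_cv_predict(ds, (sf.sigma_obs, sf.pi_lapse))
cv_shuf = loo_cv_predict(shuffle_control(ds, seed=1),
                         (sf.sigma_obs, sf.pi_lapse))
print(f"\nLOO CV log-likelihood, {ds.participant}: "
      f"original {cv.heldout_loglik:.1f} vs shuffled {cv_shuf.heldout_loglik:.1f}")
print("(original > shuffled: the model predicts responses at single-trial "
      "resolution, not just the confusion matrix)")
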