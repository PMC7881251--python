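"""Model comparison: cross-validated log-likelihoods and PXP.

Four choice-model variants are compared on the 4-AFC data:

* ``full`` — Bayesian core with lapse, biases, and inverse temperature;
* ``bias-free`` — all b_S = 0 (only beta free per participant);
* ``lapse-free`` — pi_L = 0 (beta and biases free);
* ``non-bayesian`` — the correlation-template core with shared (r, pi_L)
  refitted jointly across participants.

Each variant is refitted under its own constraint; comparisons use the
leave-one-out cross-validated summed log-likelihood per participant, which
also serves as the log model evidence surrogate for random-effects Bayesian
model selection.  The protected exceedance probability (PXP) estimates the
probability that each model is the most frequent in the population,
protected by the Bayes omnibus risk (BOR): the posterior probability that
all models are equally frequent, under which exceedance is uninformative
and replaced by 1/K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .fitting import (
    PI_GRID,
    R_GRID,
    SharedFit,
    fit_shared,
    loo_cv_predict,
)
from .sessions import SessionDataset

__all__ = [
    "MODEL_VARIANTS",
    "PxpResult",
    "cv_comparison_table",
    "pxp",
    "likelihood_ratio_report",
]

#: Fitting configuration of each compared variant.
MODEL_VARIANTS: Mapping[str, dict] = {
    "full": {"model": "bayes", "free_biases": True, "fix_pi": None},
    "bias-free": {"model": "bayes", "free_biases": False, "fix_pi": None},
    "lapse-free": {"model": "bayes", "free_biases": True, "fix_pi": 0.0},
    "non-bayesian": {"model": "nonbayes", "free_biases": True, "fix_pi": None},
}


def cv_comparison_table(
    datasets: Sequence[SessionDataset],
    shared_bayes: tuple[float, float],
    shared_nonbayes: tuple[float, float] | None = None,
    variants: Sequence[str] = tuple(MODEL_VARIANTS),
    nonbayes_r_grid: Sequence[float] = R_GRID,
    nonbayes_pi_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Participants x models table of LOO cross-validated log-likelihoods.

    ``shared_bayes`` = (sigma_obs, pi_L) is used by the Bayesian-core
    variants (the lapse-free variant pins pi_L = 0 itself).  The
    non-Bayesian variant refits its shared (r, pi_L) by grid search unless
    ``shared_nonbayes`` is given.
    """
    shared_by_variant: dict[str, tuple[float, float]] = {}
    for name in variants:
        cfg = MODEL_VARIANTS[name]
        if cfg["model"] == "bayes":
            shared_by_variant[name] = shared_bayes
        else:
            if shared_nonbayes is None:
                nb: SharedFit = fit_shared(
                    datasets, scale_grid=nonbayes_r_grid,
                    pi_grid=PI_GRID if nonbayes_pi_grid is None else nonbayes_pi_grid,
                    model="nonbayes",
                )
                shared_nonbayes = (nb.scale, nb.pi_lapse)
            shared_by_variant[name] = shared_nonbayes

    rows = {}
    for ds in datasets:
        row = {}
        for name in variants:
            cfg = MODEL_VARIANTS[name]
            cv = loo_cv_predict(ds, shared_by_variant[name], model=cfg["model"],
                                free_biases=cfg["free_biases"], fix_pi=cfg["fix_pi"])
            row[name] = cv.heldout_loglik
        rows[ds.participant] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(variants))


# -- protected exceedance probability ---------------------------------------

@dataclass
class PxpResult:
    """Random-effects model-selection summary."""

    models: tuple[str, ...]
    pxp: np.ndarray  # protected exceedance probabilities (sums to 1)
    xp: np.ndarray  # unprotected exceedance probabilities
    bor: float  # Bayes omnibus risk: P(all model frequencies equal | data)
    expected_freq: np.ndarray  # posterior mean model frequencies
    alpha: np.ndarray  # Dirichlet posterior parameters
    mc_se: np.ndarray  # Monte-Carlo standard error of the xp estimate

    def to_series(self) -> pd.Series:
        return pd.Series(self.pxp, index=list(self.models), name="pxp")


def _vb_dirichlet(log_evidence: np.ndarray, alpha0: float = 1.0,
                  tol: float = 1e-8, max_iter: int = 2000):
    """Variational random-effects estimation of model frequencies.

    Treats each participant's log model evidences as data and fits a
    Dirichlet posterior over population model frequencies.  Returns the
    Dirichlet parameters, the per-participant assignment posteriors, and
    the variational free energy of the random-effects model.
    """
    n, k = log_evidence.shape
    lev = log_evidence - log_evidence.max(axis=1, keepdims=True)
    alpha = np.full(k, alpha0)
    for _ in range(max_iter):
        e_log_r = digamma(alpha) - digamma(alpha.sum())
        log_u = lev + e_log_r
        u = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    log_u = lev + e_log_r
    u = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
    # free energy: E_q[log p] + H[q] with the Dirichlet normalizers
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(u > 0, u * np.log(u), 0.0))
    f1 = (
        np.sum(u * lev)
        + ent
        + gammaln(k * alpha0) - k * gammaln(alpha0)
        - gammaln(alpha.sum()) + np.sum(gammaln(alpha))
    )
    return alpha, u, float(f1)


def pxp(
    cv_logliks: pd.DataFrame | np.ndarray,
    alpha0: float = 1.0,
    n_draws: int = 100_000,
    seed: int = 0,
) -> PxpResult:
    """Protected exceedance probabilities from per-participant log evidences.

    Rows are participants, columns models; entries are (cross-validated)
    log-likelihoods standing in for log model evidence.  Exceedance
    probabilities are estimated by Monte-Carlo sampling of the fitted
    Dirichlet (seeded); protection mixes in the uniform distribution with
    weight BOR, the posterior probability of the null that all models are
    equally frequent.
    """
    if isinstance(cv_logliks, pd.DataFrame):
        models = tuple(cv_logliks.columns)
        lev = cv_logliks.to_numpy(dtype=float)
    else:
        lev = np.asarray(cv_logliks, dtype=float)
        models = tuple(f"model{i}" for i in range(lev.shape[1]))
    if lev.ndim != 2 or lev.shape[0] < 2 or lev.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 models")
    if not np.all(np.isfinite(lev)):
        raise ValueError("log evidences must be finite")

    alpha, _, f1 = _vb_dirichlet(lev, alpha0=alpha0)
    k = lev.shape[1]
    # null model: frequencies fixed at 1/K
    lev_c = lev - lev.max(axis=1, keepdims=True)  # same centering as the VB fit
    f0 = float(np.sum(logsumexp(lev_c, axis=1, b=np.full(k, 1.0 / k))))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    winner = np.argmax(draws, axis=1)
    xp = np.bincount(winner, minlength=k) / n_draws
    mc_se = np.sqrt(xp * (1.0 - xp) / n_draws)
    pxp_val = (1.0 - bor) * xp + bor / k
    return PxpResult(
        models=models,
        pxp=pxp_val,
        xp=xp,
        bor=bor,
        expected_freq=alpha / alpha.sum(),
        alpha=alpha,
        mc_se=mc_se,
    )


def likelihood_ratio_report(
    table: pd.DataFrame,
    reference: str = "full",
    n_trials: int | Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-participant log-likelihood differences against a reference model.

    Adds a random-choice baseline column (n_trials * log(1/K)) when the
    trial count is supplied; K is inferred as 4 for the 4-AFC task.
    """
    if reference not in table.columns:
        raise ValueError(f"reference model {reference!r} not in table")
    out = pd.DataFrame(index=table.index)
    for model in table.columns:
        out[f"delta_{model}"] = table[model] - table[reference]
    if n_trials is not None:
        n = np.asarray(n_trials)
        out["random_baseline"] = n * np.log(0.25)
        out[f"{reference}_vs_random"] = table[reference] - out["random_baseline"]
    return out
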