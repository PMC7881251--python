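"""Maximum-likelihood fitting, cross-validation, and controls.

Fitting follows the two-stage scheme of the experiments:

1. ``fit_shared``: the observation noise sigma_obs and lapse rate pi_L are
   shared across participants and found by grid search (defaults
   sigma_obs in {0.1, 0.2, ..., 2.1} rad, pi_L in {0.02, 0.04, ..., 0.40}),
   maximizing the summed response log-likelihood with the per-participant
   parameters profiled out at every grid point.  Kalman likelihood tables
   are cached per sigma_obs value; grid ties break toward smaller sigma_obs,
   then smaller pi_L.
2. ``fit_participant``: per participant, (beta, b_G, b_C, b_H) in the 4-AFC
   task — or (beta, b_H) with b_C = 0 in the 2-AFC task — by quasi-Newton
   maximization (L-BFGS-B on log beta and the biases, analytic gradient,
   deterministic multi-starts at beta in {0.1, 0.5, 1, 2, 5}).

``loo_cv_predict`` produces leave-one-out cross-validated choice
distributions; ``shuffle_control`` permutes responses within same-structure
strata (destroying the stimulus-response pairing while preserving the
confusion matrix exactly); ``transfer_params`` carries a 4-AFC fit to the
2-AFC task with bias b_H - b_C.

The same machinery fits the restricted model variants (bias-free,
lapse-free) and the non-Bayesian correlation-template model, whose shared
parameters are (r, pi_L) on an ``R_GRID`` x pi_L grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .choice import ChoiceModelParams, correlation_distances, lapse_softmax
from .sessions import SessionDataset

__all__ = [
    "SIGMA_GRID",
    "PI_GRID",
    "R_GRID",
    "BETA_STARTS",
    "ParticipantFit",
    "SharedFit",
    "CVResult",
    "fit_participant",
    "fit_shared",
    "loo_cv_predict",
    "shuffle_control",
    "transfer_params",
]

SIGMA_GRID: np.ndarray = np.round(np.arange(0.1, 2.1 + 1e-9, 0.1), 10)
PI_GRID: np.ndarray = np.round(np.arange(0.02, 0.40 + 1e-9, 0.02), 10)
#: Norm orders scanned for the correlation-template model's shared fit.
R_GRID: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0)
#: Deterministic multi-start inverse temperatures (biases start at 0).
BETA_STARTS: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0)

_LOG_BETA_BOUNDS = (np.log(1e-3), np.log(1e3))
_BIAS_BOUNDS = (-20.0, 20.0)


@dataclass
class ParticipantFit:
    """Per-participant ML fit: inverse temperature, biases, attained loglik."""

    beta: float
    biases: dict
    loglik: float
    free_bias_labels: tuple[str, ...]
    x: np.ndarray
    success: bool
    message: str = ""
    n_starts: int = 1

    def bias_vector(self) -> np.ndarray:
        return np.array([self.biases[lab] for lab in self.free_bias_labels])


@dataclass
class SharedFit:
    """Result of the shared-parameter grid search."""

    scale: float  # sigma_obs (Bayesian core) or r (correlation core)
    pi_lapse: float
    loglik: float
    grid_loglik: pd.DataFrame  # index = scale grid, columns = pi grid
    participant_fits: list
    model: str = "bayes"
    failures: list = field(default_factory=list)

    @property
    def sigma_obs(self) -> float:
        return self.scale


@dataclass
class CVResult:
    """Leave-one-out predictions for one session."""

    labels: tuple[str, ...]
    probs: np.ndarray  # (n_trials, K) held-out predicted distributions
    heldout_loglik: float
    insample_loglik: float
    flagged_folds: list


# -- likelihood core ---------------------------------------------------------

def _free_bias_labels(labels: Sequence[str], free_biases: bool) -> tuple[str, ...]:
    """Reference structure is the first label (I in 4-AFC, C in 2-AFC)."""
    return tuple(labels[1:]) if free_biases else ()


def _design(core: np.ndarray, pairs, labels):
    """Column bookkeeping: label index and log-multiplicity per hypothesis."""
    label_idx = np.array([labels.index(lab) for lab, _ in pairs])
    counts = np.array([np.sum(label_idx == labels.index(lab)) for lab, _ in pairs])
    return label_idx, np.log(counts.astype(float))


def _nll_and_grad(x, core, label_idx, log_mult, choice_idx, pi, n_labels,
                  free_idx):
    """Negative summed log-likelihood of responses and its gradient.

    ``x = (log beta, b_free...)``; ``free_idx`` maps each free bias to its
    label index.  Gradients are exact (softmax algebra), not numerical.
    """
    beta = np.exp(x[0])
    b = np.zeros(n_labels)
    b[free_idx] = x[1:]
    n = core.shape[0]
    k = n_labels

    t = core + b[label_idx] - log_mult  # (N, P): d(logit)/d(beta) weights
    a = beta * t
    logits = np.full((n, k), -np.inf)
    for j in range(k):
        cols = np.flatnonzero(label_idx == j)
        amax = a[:, cols].max(axis=1)
        logits[:, j] = amax + np.log(np.sum(np.exp(a[:, cols] - amax[:, None]), axis=1))
    lmax = logits.max(axis=1, keepdims=True)
    p = np.exp(logits - lmax)
    p /= p.sum(axis=1, keepdims=True)

    rows = np.arange(n)
    p_choice = p[rows, choice_idx]
    # floor guards the lapse-free (pi = 0) variant, where a response can
    # have vanishing model probability and the exact NLL is +inf
    total = np.maximum(pi / k + (1.0 - pi) * p_choice, 1e-300)
    nll = -np.sum(np.log(total))

    # d(logit_j)/d(beta): within-structure softmax average of t
    w = np.exp(a - logits[:, label_idx])  # (N, P)
    tbar = np.zeros((n, k))
    for j in range(k):
        cols = np.flatnonzero(label_idx == j)
        tbar[:, j] = np.sum(w[:, cols] * t[:, cols], axis=1)

    scale = (1.0 - pi) * p_choice / total  # (N,)
    inner_beta = tbar[rows, choice_idx] - np.sum(p * tbar, axis=1)
    grad = np.empty_like(x)
    grad[0] = -np.sum(scale * inner_beta) * beta  # chain rule for log beta
    for i, j in enumerate(free_idx):
        indicator = (choice_idx == j).astype(float)
        grad[1 + i] = -np.sum(scale * beta * (indicator - p[:, j]))
    return nll, grad


def _maximize(core, pairs, labels, choice_idx, pi, free_bias, starts, x0,
              maxiter=300):
    labels = tuple(labels)
    label_idx, log_mult = _design(core, pairs, labels)
    free_idx = np.array([labels.index(lab) for lab in free_bias], dtype=int)
    n_free = len(free_idx)
    bounds = [_LOG_BETA_BOUNDS] + [_BIAS_BOUNDS] * n_free

    inits = []
    if x0 is not None:
        inits.append(np.asarray(x0, dtype=float))
    for beta0 in starts:
        inits.append(np.concatenate([[np.log(beta0)], np.zeros(n_free)]))
    if not inits:
        raise ValueError("no optimizer starts provided")

    best = None
    messages = []
    for init in inits:
        res = minimize(
            _nll_and_grad, init, method="L-BFGS-B", jac=True, bounds=bounds,
            args=(core, label_idx, log_mult, choice_idx, pi, len(labels), free_idx),
            options={"maxiter": maxiter},
        )
        messages.append(str(res.message))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all optimizer starts failed: {messages}")
    x = best.x
    return ParticipantFit(
        beta=float(np.exp(x[0])),
        biases={lab: float(x[1 + i]) for i, lab in enumerate(free_bias)},
        loglik=float(-best.fun),
        free_bias_labels=tuple(free_bias),
        x=x.copy(),
        success=bool(best.success),
        message=str(best.message),
        n_starts=len(inits),
    )


def _core_for(dataset: SessionDataset, model: str, scale: float):
    """The hypothesis-level core matrix: log-likelihoods or -distances."""
    if model == "bayes":
        table = dataset.likelihood_table(scale)
        return table.pairs, table.values
    if model == "nonbayes":
        return correlation_distances(dataset.velocity_correlations(), scale,
                                     labels=dataset.choice_labels)
    raise ValueError(f"unknown model {model!r}")


def fit_participant(
    dataset: SessionDataset,
    shared: tuple[float, float],
    model: str = "bayes",
    free_biases: bool = True,
    fix_pi: float | None = None,
    starts: Sequence[float] = BETA_STARTS,
    x0: np.ndarray | None = None,
    trial_mask: np.ndarray | None = None,
) -> ParticipantFit:
    """ML fit of the per-participant parameters at fixed shared parameters.

    ``shared`` is (sigma_obs, pi_L) for the Bayesian core or (r, pi_L) for
    the correlation core.  ``fix_pi`` overrides the shared lapse rate (the
    lapse-free variant passes 0.0).  ``trial_mask`` restricts the fit to a
    subset of trials (used by cross-validation).
    """
    scale, pi = shared
    pi = float(pi if fix_pi is None else fix_pi)
    pairs, core = _core_for(dataset, model, scale)
    choice_idx = dataset.choice_indices()
    if trial_mask is not None:
        core = core[trial_mask]
        choice_idx = choice_idx[trial_mask]
    labels = dataset.choice_labels
    free = _free_bias_labels(labels, free_biases)
    return _maximize(core, pairs, labels, choice_idx, pi, free, starts, x0)


def predict_choice_probs(
    dataset: SessionDataset,
    fit: ParticipantFit,
    shared: tuple[float, float],
    model: str = "bayes",
    fix_pi: float | None = None,
) -> np.ndarray:
    """Choice distributions (n_trials, K) under a fitted parameter set."""
    scale, pi = shared
    pi = float(pi if fix_pi is None else fix_pi)
    pairs, core = _core_for(dataset, model, scale)
    return lapse_softmax(core, pairs, dataset.choice_labels, fit.beta,
                         fit.biases, pi)


def fit_shared(
    datasets: Sequence[SessionDataset],
    scale_grid: Sequence[float] | None = None,
    pi_grid: Sequence[float] | None = None,
    model: str = "bayes",
    starts: Sequence[float] = BETA_STARTS,
    free_biases: bool = True,
) -> SharedFit:
    """Grid search for the shared parameters with inner per-participant fits.

    The first grid point uses the full deterministic multi-start; later
    points warm-start each participant from their previous solution (the
    profile optimum moves smoothly along the grid).  A grid point where any
    inner fit fails is marked invalid (NaN) and recorded, never silently
    skipped.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if scale_grid is None:
        scale_grid = SIGMA_GRID if model == "bayes" else np.asarray(R_GRID)
    scale_grid = np.asarray(scale_grid, dtype=float)
    pi_grid = np.asarray(PI_GRID if pi_grid is None else pi_grid, dtype=float)
    if scale_grid.size == 0 or pi_grid.size == 0:
        raise ValueError("grids must be non-empty")

    total = np.full((scale_grid.size, pi_grid.size), np.nan)
    failures: list[tuple[float, float, str]] = []
    best = (-np.inf, None, None)

    for i, scale in enumerate(scale_grid):
        # the core values rescale with sigma, so each scale column restarts
        # from the full deterministic multi-start before warm-starting in pi
        warm: list[np.ndarray | None] = [None] * len(datasets)
        for j, pi in enumerate(pi_grid):
            tot = 0.0
            ok = True
            for k, ds in enumerate(datasets):
                use_starts = starts if warm[k] is None else (1.0,)
                try:
                    fit = fit_participant(ds, (scale, pi), model=model,
                                          free_biases=free_biases,
                                          starts=use_starts, x0=warm[k])
                except RuntimeError as err:
                    failures.append((float(scale), float(pi), str(err)))
                    ok = False
                    break
                warm[k] = fit.x
                tot += fit.loglik
            if not ok:
                continue
            total[i, j] = tot
            if tot > best[0]:  # strict: ties keep smaller sigma, then pi
                best = (tot, float(scale), float(pi))

    if best[1] is None:
        raise RuntimeError("shared grid search failed at every grid point")
    _, scale_star, pi_star = best
    final_fits = [
        fit_participant(ds, (scale_star, pi_star), model=model,
                        free_biases=free_biases, starts=starts)
        for ds in datasets
    ]
    grid = pd.DataFrame(total, index=np.round(scale_grid, 10),
                        columns=np.round(pi_grid, 10))
    return SharedFit(
        scale=scale_star,
        pi_lapse=pi_star,
        loglik=float(sum(f.loglik for f in final_fits)),
        grid_loglik=grid,
        participant_fits=final_fits,
        model=model,
        failures=failures,
    )


def loo_cv_predict(
    dataset: SessionDataset,
    shared: tuple[float, float],
    model: str = "bayes",
    free_biases: bool = True,
    fix_pi: float | None = None,
    starts: Sequence[float] = BETA_STARTS,
) -> CVResult:
    """Leave-one-out cross-validated choice distributions.

    Each fold refits the per-participant parameters on the other trials
    (warm-started from the full-data fit) and evaluates the held-out trial.
    A fold whose optimizer fails falls back to the full-data fit and is
    flagged, never silently imputed.
    """
    n = dataset.n_trials
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 trials")
    full = fit_participant(dataset, shared, model=model, free_biases=free_biases,
                           fix_pi=fix_pi, starts=starts)
    full_probs = predict_choice_probs(dataset, full, shared, model=model,
                                      fix_pi=fix_pi)
    choice_idx = dataset.choice_indices()
    probs = np.empty_like(full_probs)
    flagged = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fold = fit_participant(dataset, shared, model=model,
                                   free_biases=free_biases, fix_pi=fix_pi,
                                   starts=(), x0=full.x, trial_mask=mask)
        except RuntimeError:
            flagged.append(i)
            probs[i] = full_probs[i]
            continue
        fold_probs = predict_choice_probs(dataset, fold, shared, model=model,
                                          fix_pi=fix_pi)
        probs[i] = fold_probs[i]
    heldout = float(np.sum(np.log(probs[np.arange(n), choice_idx])))
    return CVResult(
        labels=dataset.choice_labels,
        probs=probs,
        heldout_loglik=heldout,
        insample_loglik=full.loglik,
        flagged_folds=flagged,
    )


def shuffle_control(dataset: SessionDataset, seed: int = 0) -> SessionDataset:
    """Permute responses among trials of the same true structure.

    Destroys the stimulus-response pairing while leaving the confusion
    matrix exactly unchanged.  2-AFC sessions stratify by morph level.
    """
    if dataset.choices is None:
        raise ValueError("cannot shuffle a session without responses")
    rng = np.random.default_rng(seed)
    if dataset.task == "4afc":
        strata = dataset.trial_labels
    else:
        strata = dataset.trial_morphs
    choices = np.array(dataset.choices, dtype=object)
    conf = None if dataset.confidences is None else dataset.confidences.copy()
    for value in pd.unique(strata):
        idx = np.flatnonzero(strata == value)
        perm = rng.permutation(idx.size)
        choices[idx] = choices[idx[perm]]
        if conf is not None:
            conf[idx] = conf[idx[perm]]
    return dataset.with_responses(choices, conf)


def transfer_params(
    fourafc_fit: ParticipantFit,
    sigma_obs: float = 1.1,
    pi_lapse: float = 0.14,
) -> ChoiceModelParams:
    """Carry a 4-AFC fit to the 2-AFC task.

    The 2-AFC bias is the relative log-prior b_H - b_C (b_C = 0 becomes the
    reference); beta and the shared parameters transfer unchanged.
    """
    b = fourafc_fit.biases
    return ChoiceModelParams(
        sigma_obs=sigma_obs,
        pi_lapse=pi_lapse,
        beta=fourafc_fit.beta,
        biases={"H": float(b.get("H", 0.0) - b.get("C", 0.0))},
    )
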