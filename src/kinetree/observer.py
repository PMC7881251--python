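"""Kalman-filter ideal observer for motion-structure identification.

The observer inverts the generative model of the stimulus: latent positions
``z`` and velocities ``v`` evolve with the linear transition implied by the
Ornstein-Uhlenbeck dynamics at frame resolution,

    F = [[I, dt I], [0, (1 - dt/tau) I]],
    Q = [[0, 0], [0, dt (P_m B) Lambda^2 (P_m B)^T]],

and only noisy positions x(t) ~ N(z(t), sigma_obs^2 I) are observed.  For
each candidate hypothesis — a structure S together with a dot permutation
m in M(S) — a forward Kalman filter accumulates the trajectory
log-likelihood from the pre-fit residuals (innovations):

    log p(X | P_m B Lambda(S)) = sum_t log p(x(t) | x(0..t-1)).

The structure-independent p(x(0)) factor is dropped; it cancels in every
posterior.  Position innovations are wrapped to (-pi, pi] so the filter is
correct on the circle (posterior position uncertainty is far below pi for
visible dots, so this minimal treatment suffices).

The posterior over structures applies the multiplicity penalty |M(S)|:

    P(S | X)  propto  sum_{m in M(S)} exp(ll_{S,m} - log |M(S)|) P(S),

which makes the evidence-free posterior uniform even though C and H carry
three hypotheses each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp

from .simulate import Scene, TWO_PI
from .structures import (
    MULTIPLICITY,
    PERMUTATIONS,
    STRUCTURE_LABELS,
    MotionStructure,
    hypothesis_pairs,
    make_prototype,
)

__all__ = [
    "KalmanModel",
    "StructureLikelihoods",
    "LikelihoodTable",
    "kalman_loglik",
    "evaluate_scene",
    "evaluate_positions",
    "structure_posterior",
    "log_odds",
    "SIGMA_OBS_FLOOR",
]

#: Observation-noise floor (rad).  sigma_obs = 0 would make the innovation
#: covariance singular at the first update; the floor regularizes it.
SIGMA_OBS_FLOOR = 1e-6

_LOG_2PI = float(np.log(2.0 * np.pi))


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Map angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, TWO_PI)


@dataclass(frozen=True)
class KalmanModel:
    """Transition/noise matrices of one (structure, permutation) hypothesis."""

    transition: np.ndarray  # F, 6x6 (positions then velocities)
    process_noise: np.ndarray  # Q, 6x6
    initial_cov: np.ndarray  # P0, 6x6
    sigma_obs: float
    frame_dt: float
    structure: MotionStructure
    permutation: int


def build_kalman_model(
    s: MotionStructure,
    m: int,
    sigma_obs: float,
    frame_dt: float = 0.02,
    tau: float = 1.5,
) -> KalmanModel:
    sigma = max(float(sigma_obs), SIGMA_OBS_FLOOR)
    perm = PERMUTATIONS[m]
    mixed = perm @ s.mixing_matrix
    diffusion = mixed @ mixed.T  # (P_m B) Lambda^2 (P_m B)^T
    eye3 = np.eye(3)
    transition = np.block(
        [[eye3, frame_dt * eye3], [np.zeros((3, 3)), (1.0 - frame_dt / tau) * eye3]]
    )
    process_noise = np.zeros((6, 6))
    process_noise[3:, 3:] = frame_dt * diffusion
    # posterior after x(0): z ~ N(x0, sigma^2 I); v ~ stationary prior
    initial_cov = np.zeros((6, 6))
    initial_cov[:3, :3] = sigma**2 * eye3
    initial_cov[3:, 3:] = 0.5 * tau * diffusion
    return KalmanModel(
        transition=transition,
        process_noise=process_noise,
        initial_cov=initial_cov,
        sigma_obs=sigma,
        frame_dt=frame_dt,
        structure=s,
        permutation=m,
    )


def _gain_sequence(model: KalmanModel, n_frames: int):
    """Precompute per-step Kalman gains and innovation-covariance factors.

    The covariance recursion does not depend on the data, so one pass serves
    every scene evaluated under this hypothesis.
    """
    F = model.transition
    Q = model.process_noise
    r = model.sigma_obs**2
    P = model.initial_cov.copy()
    gains, chols, logdets = [], [], []
    for _ in range(1, n_frames):
        P = F @ P @ F.T + Q
        S = P[:3, :3] + r * np.eye(3)
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                f"singular innovation covariance for hypothesis "
                f"({model.structure.label}, P_{model.permutation}): {err}"
            ) from err
        K = cho_solve(cho_factor(S, lower=True), P[:3, :]).T  # P[:, :3] S^-1
        P = P - K @ P[:3, :]
        P = 0.5 * (P + P.T)
        gains.append(K)
        chols.append(L)
        logdets.append(2.0 * float(np.sum(np.log(np.diag(L)))))
    return gains, chols, logdets


def _run_filter(positions: np.ndarray, model: KalmanModel) -> np.ndarray:
    """Batched log-likelihoods for positions of shape (n_scenes, n_frames, 3)."""
    if not np.all(np.isfinite(positions)):
        raise ValueError("scene positions contain non-finite values")
    n_scenes, n_frames, _ = positions.shape
    loglik = np.zeros(n_scenes)
    if n_frames < 2:
        return loglik  # no transitions: only the dropped p(x(0)) term
    gains, chols, logdets = _gain_sequence(model, n_frames)
    F = model.transition
    mean = np.zeros((n_scenes, 6))
    mean[:, :3] = positions[:, 0]
    for t in range(1, n_frames):
        pred = mean @ F.T
        innov = wrap_angle(positions[:, t] - pred[:, :3])
        y = solve_triangular(chols[t - 1], innov.T, lower=True)
        loglik -= 0.5 * (np.sum(y * y, axis=0) + logdets[t - 1] + 3.0 * _LOG_2PI)
        mean = pred + innov @ gains[t - 1].T
        mean[:, :3] %= TWO_PI
    return loglik


def kalman_loglik(
    scene: Scene,
    s: MotionStructure,
    m: int = 1,
    sigma_obs: float = 1.1,
    tau: float = 1.5,
) -> float:
    """Trajectory log-likelihood (nats) of one scene under one hypothesis."""
    model = build_kalman_model(s, m, sigma_obs, frame_dt=scene.frame_dt, tau=tau)
    return float(_run_filter(scene.positions[None, :, :], model)[0])


# -- likelihood tables -------------------------------------------------------

@dataclass
class StructureLikelihoods:
    """Log-likelihoods of one trial under every (structure, permutation) pair."""

    pairs: tuple[tuple[str, int], ...]
    values: np.ndarray
    trial_id: int | str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pairs),):
            raise ValueError("values must align with hypothesis pairs")

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab, _ in self.pairs:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def __getitem__(self, key: tuple[str, int]) -> float:
        return float(self.values[self.pairs.index(key)])


@dataclass
class LikelihoodTable:
    """Trials x hypotheses log-likelihood matrix for one session."""

    pairs: tuple[tuple[str, int], ...]
    values: np.ndarray  # (n_trials, n_pairs)
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.values.shape[0])

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab, _ in self.pairs:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def row(self, i: int) -> StructureLikelihoods:
        return StructureLikelihoods(self.pairs, self.values[i], trial_id=self.trial_ids[i])

    def to_frame(self) -> pd.DataFrame:
        records = []
        for i, tid in enumerate(self.trial_ids):
            for j, (lab, m) in enumerate(self.pairs):
                records.append(
                    {"trial": tid, "structure": lab, "permutation": m,
                     "loglik": self.values[i, j]}
                )
        return pd.DataFrame.from_records(records)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, path) -> "LikelihoodTable":
        df = pd.read_csv(path, sep="\t")
        trial_ids = df["trial"].drop_duplicates().to_numpy()
        pairs = tuple(
            (row.structure, int(row.permutation))
            for row in df[df["trial"] == trial_ids[0]].itertuples()
        )
        wide = df.pivot_table(index="trial", columns=["structure", "permutation"],
                              values="loglik", sort=False)
        values = np.column_stack([wide[(lab, m)].loc[trial_ids].to_numpy() for lab, m in pairs])
        return cls(pairs=pairs, values=values, trial_ids=trial_ids)


def evaluate_positions(
    positions: np.ndarray,
    choice_labels: Sequence[str] = STRUCTURE_LABELS,
    sigma_obs: float = 1.1,
    frame_dt: float = 0.02,
    tau: float = 1.5,
    trial_ids: np.ndarray | None = None,
) -> LikelihoodTable:
    """Evaluate a batch of scenes under every hypothesis of a choice set.

    ``positions`` has shape (n_scenes, n_frames, 3).  Hypotheses share one
    pass over the data but remain numerically independent filters.
    """
    positions = np.asarray(positions, dtype=float)
    pairs = hypothesis_pairs(choice_labels)
    values = np.empty((positions.shape[0], len(pairs)))
    for j, (lab, m) in enumerate(pairs):
        model = build_kalman_model(make_prototype(lab), m, sigma_obs,
                                   frame_dt=frame_dt, tau=tau)
        values[:, j] = _run_filter(positions, model)
    return LikelihoodTable(pairs=pairs, values=values, trial_ids=trial_ids)


def evaluate_scene(
    scene: Scene,
    choice_labels: Sequence[str] = STRUCTURE_LABELS,
    sigma_obs: float = 1.1,
    tau: float = 1.5,
) -> StructureLikelihoods:
    """Evaluate one scene; returns the 8-entry table for the 4-AFC set."""
    table = evaluate_positions(
        scene.positions[None, :, :], choice_labels, sigma_obs,
        frame_dt=scene.frame_dt, tau=tau,
    )
    return table.row(0)


# -- posterior over structures ----------------------------------------------

def _structure_evidence(liks: StructureLikelihoods) -> tuple[tuple[str, ...], np.ndarray]:
    """Per-structure log evidence with the multiplicity penalty applied."""
    labels = liks.labels
    ev = np.empty(len(labels))
    for i, lab in enumerate(labels):
        cols = [j for j, (l, _) in enumerate(liks.pairs) if l == lab]
        if lab in MULTIPLICITY and len(cols) != len(MULTIPLICITY[lab]):
            raise ValueError(f"incomplete hypothesis set for structure {lab!r}")
        ev[i] = logsumexp(liks.values[cols]) - np.log(len(cols))
    return labels, ev


def structure_posterior(
    liks: StructureLikelihoods,
    prior_logits: Iterable[float] | None = None,
) -> pd.Series:
    """Ideal-observer posterior P(S | X) over the choice set.

    Uses log-sum-exp throughout; a uniform prior is the default.
    """
    labels, ev = _structure_evidence(liks)
    if prior_logits is not None:
        ev = ev + np.asarray(list(prior_logits), dtype=float)
    post = np.exp(ev - logsumexp(ev))
    return pd.Series(post / post.sum(), index=list(labels), name="posterior")


def log_odds(liks: StructureLikelihoods, s: str) -> float:
    """log P(S|X) - log P(not S|X) under the uniform-prior posterior.

    Computed directly in log space (difference of log-sum-exps), so no
    epsilon clamping is needed for finite likelihood entries.
    """
    labels, ev = _structure_evidence(liks)
    idx = labels.index(s)
    others = np.delete(ev, idx)
    return float(ev[idx] - logsumexp(others))
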