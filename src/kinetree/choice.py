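"""Probabilistic choice models on top of the ideal observer.

The full choice model wraps three known imperfections of human perceptual
decision making around the Bayesian core:

    P(choice=S | X) = pi_L / K
        + (1 - pi_L) * softmax_S( logsumexp_{m in M(S)}
              beta * (log p(X | P_m B Lambda(S)) + b_S - log|M(S)|) )

with lapse probability pi_L, inverse temperature beta, and per-structure
biases b_S acting as a log-prior relative to the reference structure
(b_I = 0 in the 4-AFC task; b_C = 0 in the 2-AFC task).  The multiplicity
penalty -log|M(S)| sits inside the beta exponent, exactly as the model is
defined; at beta = 1 it collapses the 3-permutation sums to the ideal
posterior, while at beta != 1 multi-permutation structures pick up a
|M(S)|^(1-beta) weight — a property of the model, not a bug.

Bayesian predicted confidence is the same formula at pi_L = 0, beta = 1
with the participant's fitted biases, evaluated at the chosen structure.

The non-Bayesian alternative keeps the identical architecture but replaces
the log-likelihood by the negative r-norm distance between a trial's
empirical velocity correlations and each structure's analytic prototype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .observer import LikelihoodTable, StructureLikelihoods, wrap_angle
from .simulate import Scene
from .structures import (
    MULTIPLICITY,
    correlation_prototype,
    make_prototype,
)

__all__ = [
    "ChoiceModelParams",
    "NonBayesParams",
    "bayes_choice_prob",
    "bayes_confidence",
    "empirical_velocity_correlation",
    "nonbayes_choice_prob",
    "correlation_distances",
    "choice_core_matrix",
    "lapse_softmax",
]

FOUR_AFC: tuple[str, ...] = ("I", "G", "C", "H")
TWO_AFC: tuple[str, ...] = ("C", "H")


@dataclass(frozen=True)
class ChoiceModelParams:
    """Parameters of the Bayesian-core choice model.

    ``sigma_obs`` (rad) and ``pi_lapse`` are shared across participants;
    ``beta`` and the biases are per-participant.  Unlisted biases are 0,
    which fixes the reference structure (I in 4-AFC, C in 2-AFC).
    """

    sigma_obs: float = 1.1
    pi_lapse: float = 0.14
    beta: float = 1.0
    biases: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_lapse <= 1.0:
            raise ValueError("pi_lapse must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def bias(self, label: str) -> float:
        return float(self.biases.get(label, 0.0))

    def with_(self, **kwargs) -> "ChoiceModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NonBayesParams:
    """Parameters of the correlation-template model (r replaces sigma_obs)."""

    r: float = 1.0
    pi_lapse: float = 0.30
    beta: float = 1.0
    biases: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("norm order r must be positive")
        if not 0.0 <= self.pi_lapse <= 1.0:
            raise ValueError("pi_lapse must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def bias(self, label: str) -> float:
        return float(self.biases.get(label, 0.0))


def _label_columns(pairs: Sequence[tuple[str, int]], labels: Sequence[str]):
    cols = []
    for lab in labels:
        c = [j for j, (l, _) in enumerate(pairs) if l == lab]
        if not c:
            raise ValueError(f"no hypothesis entries for structure {lab!r}")
        cols.append(c)
    return cols


def lapse_softmax(
    core: np.ndarray,
    pairs: Sequence[tuple[str, int]],
    labels: Sequence[str],
    beta: float,
    biases: Mapping[str, float],
    pi_lapse: float,
) -> np.ndarray:
    """Shared lapse-mixture softmax over (structure, permutation) columns.

    ``core`` has shape (..., n_pairs): the log-likelihood (Bayesian core) or
    negative correlation distance (non-Bayesian core) per hypothesis column.
    Returns choice probabilities with shape (..., K).
    """
    if len(labels) == 0:
        raise ValueError("empty choice set")
    core = np.asarray(core, dtype=float)
    cols = _label_columns(pairs, labels)
    logits = np.empty(core.shape[:-1] + (len(labels),))
    for i, (lab, c) in enumerate(zip(labels, cols)):
        a = beta * (core[..., c] + float(biases.get(lab, 0.0)) - np.log(len(c)))
        logits[..., i] = logsumexp(a, axis=-1)
    p = np.exp(logits - logsumexp(logits, axis=-1, keepdims=True))
    p /= p.sum(axis=-1, keepdims=True)
    k = len(labels)
    return pi_lapse / k + (1.0 - pi_lapse) * p


def _core_values(liks: StructureLikelihoods | LikelihoodTable):
    return liks.pairs, liks.values


def bayes_choice_prob(
    liks: StructureLikelihoods | LikelihoodTable,
    params: ChoiceModelParams,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Choice probabilities of the Bayesian-core model.

    Accepts a single trial's :class:`StructureLikelihoods` (returns shape
    (K,)) or a whole :class:`LikelihoodTable` (returns (n_trials, K)).
    """
    pairs, values = _core_values(liks)
    labels = tuple(labels) if labels is not None else liks.labels
    return lapse_softmax(values, pairs, labels, params.beta, params.biases,
                         params.pi_lapse)


def bayes_confidence(
    liks: StructureLikelihoods,
    biases: Mapping[str, float],
    chosen: str,
    labels: Sequence[str] | None = None,
) -> float:
    """Bayesian predicted confidence in the chosen structure.

    The choice-model probability at pi_L = 0, beta = 1 with the
    participant's biases: the subjective posterior belief of having chosen
    correctly, stripped of decision noise and lapses.
    """
    labels = tuple(labels) if labels is not None else liks.labels
    if chosen not in labels:
        raise ValueError(f"chosen structure {chosen!r} not in choice set {labels}")
    p = lapse_softmax(liks.values, liks.pairs, labels, 1.0, biases, 0.0)
    return float(p[labels.index(chosen)])


# -- non-Bayesian (correlation-template) core --------------------------------

def empirical_velocity_correlation(scene: Scene | np.ndarray, frame_dt: float | None = None):
    """Pairwise Pearson correlations of finite-difference velocities.

    Velocities are (x(t) - x(t - dt)) / dt with differences unwrapped across
    the 0/2pi seam; no observation noise is involved.  Returns
    (rho12, rho13, rho23).
    """
    if isinstance(scene, Scene):
        positions = scene.positions
        frame_dt = scene.frame_dt
    else:
        positions = np.asarray(scene, dtype=float)
        if frame_dt is None:
            raise ValueError("frame_dt required when passing a raw position array")
    if positions.shape[0] < 3:
        raise ValueError("need at least 3 frames to correlate velocities")
    diffs = wrap_angle(np.diff(positions, axis=0)) / frame_dt  # (T-1, 3)
    sd = diffs.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance velocity channel; correlations undefined")
    corr = np.corrcoef(diffs, rowvar=False)
    return np.array([corr[0, 1], corr[0, 2], corr[1, 2]])


def correlation_distances(
    rho: np.ndarray,
    r: float,
    labels: Sequence[str] = FOUR_AFC,
) -> tuple[tuple[tuple[str, int], ...], np.ndarray]:
    """Negative r-norm distances to every structure/permutation prototype.

    Returns (pairs, core) where ``core[..., j] = -||rho - rho_proto_j||_r``,
    ready for :func:`lapse_softmax`.  ``rho`` may be (3,) or (n_trials, 3).
    """
    rho = np.asarray(rho, dtype=float)
    pairs = tuple((lab, m) for lab in labels for m in MULTIPLICITY[lab])
    protos = np.stack([
        correlation_prototype(make_prototype(lab), m) for lab, m in pairs
    ])  # (n_pairs, 3)
    diff = np.abs(rho[..., None, :] - protos)  # (..., n_pairs, 3)
    dist = np.sum(diff**r, axis=-1) ** (1.0 / r)
    return pairs, -dist


def nonbayes_choice_prob(
    rho: np.ndarray,
    params: NonBayesParams,
    labels: Sequence[str] = FOUR_AFC,
) -> np.ndarray:
    """Choice probabilities of the correlation-template model."""
    pairs, core = correlation_distances(rho, params.r, labels)
    return lapse_softmax(core, pairs, labels, params.beta, params.biases,
                         params.pi_lapse)
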