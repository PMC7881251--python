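"""Synthetic experiments: sessions of scenes plus model-driven responses.

This module generates complete, ground-truth-known stand-ins for the human
experiments so that every stage of the pipeline (observer, fitting, model
comparison, reporting) can be exercised end to end:

* 4-AFC sessions: ``n_unique`` scenes with uniformly drawn structures, each
  duplicated, presented in shuffled order (default 100 unique -> 200 trials),
  with per-trial color permutations.
* 2-AFC sessions: morphed C<->H scenes at the tested fraction levels
  (default 0.00, 0.20, 0.35, 0.55, 0.75; 20 trials each; no repetitions).
* Responses sampled from the Bayesian-core (or correlation-template) choice
  model under known parameters.  Binary confidence reports use a threshold
  theta on the Bayesian predicted confidence — a generative extension for
  end-to-end testing; analysis curves always use the deterministic
  confidence itself.

Seeding: one master seed per session spawns independent child streams for
scene batches, trial shuffling, and responses, so regenerating responses
never perturbs the scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .choice import (
    ChoiceModelParams,
    NonBayesParams,
    lapse_softmax,
    nonbayes_choice_prob,
)
from .sessions import FOUR_AFC, TWO_AFC, SessionDataset
from .simulate import SimulationSettings, experiment_defaults, simulate_scenes
from .structures import STRUCTURE_LABELS, make_prototype, morph_ch

__all__ = [
    "SyntheticParticipantSpec",
    "generate_4afc_session",
    "generate_2afc_session",
    "simulate_responses",
    "make_cohort",
    "MORPH_LEVELS",
]

#: Morph fractions tested in the 2-AFC experiment.
MORPH_LEVELS: tuple[float, ...] = (0.00, 0.20, 0.35, 0.55, 0.75)


@dataclass(frozen=True)
class SyntheticParticipantSpec:
    """Ground-truth generator for one synthetic participant.

    ``conf_threshold`` (theta) turns the deterministic Bayesian predicted
    confidence into a binary report: high iff confidence > theta.
    """

    params: ChoiceModelParams | NonBayesParams
    conf_threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conf_threshold < 1.0:
            raise ValueError("conf_threshold must lie in (0, 1)")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_4afc_session(
    n_unique: int = 100,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    participant: str = "synthetic",
) -> SessionDataset:
    """One 4-AFC session: uniform structures, duplicated trials, shuffled."""
    if n_unique < 1:
        raise ValueError("need at least one unique scene")
    settings = settings or experiment_defaults()
    rng_struct, rng_scenes, rng_order, rng_colors = _spawn(seed, 4)

    labels = rng_struct.choice(STRUCTURE_LABELS, size=n_unique)
    positions = np.empty((n_unique, settings.n_frames, 3))
    for lab in STRUCTURE_LABELS:  # one seeded batch per structure group
        idx = np.flatnonzero(labels == lab)
        if idx.size:
            pos, _ = simulate_scenes(make_prototype(lab), idx.size,
                                     settings=settings, seed=rng_scenes)
            positions[idx] = pos

    scene_index = np.repeat(np.arange(n_unique), 2)
    pair_ids = np.repeat(np.arange(n_unique), 2)
    order = rng_order.permutation(2 * n_unique)
    perms = np.stack([rng_colors.permutation(3) for _ in range(2 * n_unique)])
    return SessionDataset(
        participant=participant,
        task="4afc",
        positions=positions,
        scene_index=scene_index[order],
        scene_labels=labels.astype(object),
        scene_morphs=np.full(n_unique, np.nan),
        pair_ids=pair_ids[order],
        color_permutations=perms,
        frame_dt=settings.frame_dt,
        tau=settings.tau,
    )


def generate_2afc_session(
    morph_levels: Sequence[float] = MORPH_LEVELS,
    per_level: int = 20,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    participant: str = "synthetic",
) -> SessionDataset:
    """One 2-AFC session: ``per_level`` morph scenes per level, shuffled."""
    levels = [float(f) for f in morph_levels]
    if any(not 0.0 <= f <= 1.0 for f in levels):
        raise ValueError("morph levels must lie in [0, 1]")
    settings = settings or experiment_defaults()
    rng_scenes, rng_order, rng_colors = _spawn(seed, 3)

    n_unique = len(levels) * per_level
    morphs = np.repeat(levels, per_level)
    positions = np.empty((n_unique, settings.n_frames, 3))
    for f in levels:
        idx = np.flatnonzero(morphs == f)
        pos, _ = simulate_scenes(morph_ch(f), idx.size, settings=settings,
                                 seed=rng_scenes)
        positions[idx] = pos

    labels = np.array(
        ["C" if f == 0.0 else ("H" if f == 0.75 else "") for f in morphs],
        dtype=object,
    )
    order = rng_order.permutation(n_unique)
    perms = np.stack([rng_colors.permutation(3) for _ in range(n_unique)])
    return SessionDataset(
        participant=participant,
        task="2afc",
        positions=positions,
        scene_index=order,  # no repetitions: trials are a shuffled pass
        scene_labels=labels,
        scene_morphs=morphs,
        pair_ids=None,
        color_permutations=perms,
        frame_dt=settings.frame_dt,
        tau=settings.tau,
    )


def simulate_responses(
    dataset: SessionDataset,
    spec: SyntheticParticipantSpec,
) -> SessionDataset:
    """Sample choices (and confidence reports) from the spec's choice model."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    labels = dataset.choice_labels
    params = spec.params
    if isinstance(params, NonBayesParams):
        probs = nonbayes_choice_prob(dataset.velocity_correlations(), params,
                                     labels=labels)
        conf_table = dataset.likelihood_table(1.1)  # confidence stays Bayesian
    else:
        table = dataset.likelihood_table(params.sigma_obs)
        probs = lapse_softmax(table.values, table.pairs, labels,
                              params.beta, params.biases, params.pi_lapse)
        conf_table = table

    cum = np.cumsum(probs, axis=1)
    draws = rng.uniform(size=len(cum))
    choice_idx = (draws[:, None] > cum).sum(axis=1)
    choices = np.array([labels[i] for i in choice_idx], dtype=object)

    conf_probs = lapse_softmax(conf_table.values, conf_table.pairs, labels,
                               1.0, params.biases, 0.0)
    bayes_conf = conf_probs[np.arange(len(choice_idx)), choice_idx]
    confidences = bayes_conf > spec.conf_threshold
    return dataset.with_responses(choices, confidences)


def make_cohort(
    n_participants: int = 12,
    seed: int = 0,
    n_unique: int = 100,
    task: str = "4afc",
    sigma_obs: float = 1.1,
    pi_lapse: float = 0.14,
    beta_range: tuple[float, float] = (0.5, 2.0),
    bias_sd: float = 0.5,
    settings: SimulationSettings | None = None,
    morph_levels: Sequence[float] = MORPH_LEVELS,
    per_level: int = 20,
) -> tuple[list[SessionDataset], list[SyntheticParticipantSpec]]:
    """A cohort of synthetic participants with known ground-truth parameters.

    Per-participant inverse temperatures are log-uniform on ``beta_range``
    and biases are independent N(0, bias_sd^2); the shared observation noise
    and lapse rate default to the experiment-scale values (1.1 rad, 0.14).
    """
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    session_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_participants)]
    free_biases = ("G", "C", "H") if task == "4afc" else ("H",)

    datasets, specs = [], []
    for j in range(n_participants):
        beta = float(np.exp(param_rng.uniform(np.log(beta_range[0]),
                                              np.log(beta_range[1]))))
        biases = {lab: float(param_rng.normal(0.0, bias_sd)) for lab in free_biases}
        params = ChoiceModelParams(sigma_obs=sigma_obs, pi_lapse=pi_lapse,
                                   beta=beta, biases=biases)
        spec = SyntheticParticipantSpec(params=params, seed=session_seeds[j])
        if task == "4afc":
            ds = generate_4afc_session(n_unique=n_unique, seed=session_seeds[j],
                                       settings=settings, participant=f"synth{j:02d}")
        else:
            ds = generate_2afc_session(morph_levels=morph_levels, per_level=per_level,
                                       seed=session_seeds[j], settings=settings,
                                       participant=f"synth{j:02d}")
        datasets.append(simulate_responses(ds, spec))
        specs.append(spec)
    return datasets, specs
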