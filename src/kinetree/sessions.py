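"""Session containers: trials, responses, and cached observer evaluations.

A :class:`SessionDataset` is the unit of fitting and cross-validation: one
participant's trials (scenes plus ground-truth metadata) and, once present,
their responses (choice and binary confidence).  Scenes are stored once per
unique stimulus; repeated presentations reference the same stored scene via
``scene_index``, which both halves the observer workload and makes the
repetition pairing explicit.

Kalman likelihood tables are cached per observation-noise value and the
empirical velocity correlations once per session, since the fitting stage
re-reads both many times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .observer import LikelihoodTable, evaluate_positions

FOUR_AFC: tuple[str, ...] = ("I", "G", "C", "H")
TWO_AFC: tuple[str, ...] = ("C", "H")

__all__ = ["SessionDataset", "FOUR_AFC", "TWO_AFC", "save_session", "load_session"]


@dataclass
class SessionDataset:
    """Trials and (optional) responses for one participant and task."""

    participant: str
    task: str  # "4afc" or "2afc"
    positions: np.ndarray  # (n_unique_scenes, n_frames, 3)
    scene_index: np.ndarray  # (n_trials,) -> row of positions
    scene_labels: np.ndarray  # per unique scene: structure label or ""
    scene_morphs: np.ndarray  # per unique scene: morph fraction or nan
    pair_ids: np.ndarray | None = None  # (n_trials,) repetition-pair id
    color_permutations: np.ndarray | None = None  # (n_trials, 3)
    choices: np.ndarray | None = None  # (n_trials,) structure labels
    confidences: np.ndarray | None = None  # (n_trials,) bool, high = True
    frame_dt: float = 0.02
    tau: float = 1.5
    _tables: dict = field(default_factory=dict, repr=False)
    _rho: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.task not in ("4afc", "2afc"):
            raise ValueError(f"unknown task {self.task!r}")
        self.scene_index = np.asarray(self.scene_index, dtype=int)
        if self.choices is not None and len(self.choices) != self.n_trials:
            raise ValueError("responses must reference existing trials")
        if self.task == "4afc" and self.pair_ids is not None:
            _, counts = np.unique(self.pair_ids, return_counts=True)
            if not np.all(counts == 2):
                raise ValueError("repetition-pair ids must partition trials into pairs")

    # -- basic geometry ------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return int(self.scene_index.size)

    @property
    def choice_labels(self) -> tuple[str, ...]:
        return FOUR_AFC if self.task == "4afc" else TWO_AFC

    @property
    def trial_labels(self) -> np.ndarray:
        """Ground-truth structure label per trial ("" for pure morphs)."""
        return self.scene_labels[self.scene_index]

    @property
    def trial_morphs(self) -> np.ndarray:
        return self.scene_morphs[self.scene_index]

    @property
    def has_responses(self) -> bool:
        return self.choices is not None

    def with_responses(
        self,
        choices: Sequence[str],
        confidences: Sequence[bool] | None = None,
    ) -> "SessionDataset":
        """Copy of this session with responses attached (caches shared)."""
        out = SessionDataset(
            participant=self.participant,
            task=self.task,
            positions=self.positions,
            scene_index=self.scene_index,
            scene_labels=self.scene_labels,
            scene_morphs=self.scene_morphs,
            pair_ids=self.pair_ids,
            color_permutations=self.color_permutations,
            choices=np.asarray(choices, dtype=object),
            confidences=None if confidences is None else np.asarray(confidences, dtype=bool),
            frame_dt=self.frame_dt,
            tau=self.tau,
        )
        out._tables = self._tables
        out._rho = self._rho
        return out

    # -- cached observer evaluations ----------------------------------------

    def likelihood_table(self, sigma_obs: float) -> LikelihoodTable:
        """Per-trial likelihood table at ``sigma_obs`` (cached per value)."""
        key = round(float(sigma_obs), 9)
        if key not in self._tables:
            self._tables[key] = evaluate_positions(
                self.positions, self.choice_labels, sigma_obs,
                frame_dt=self.frame_dt, tau=self.tau,
            )
        unique = self._tables[key]
        return LikelihoodTable(
            pairs=unique.pairs,
            values=unique.values[self.scene_index],
            trial_ids=np.arange(self.n_trials),
        )

    def velocity_correlations(self) -> np.ndarray:
        """Empirical (rho12, rho13, rho23) per trial (cached)."""
        from .choice import empirical_velocity_correlation

        if self._rho is None:
            self._rho = np.stack([
                empirical_velocity_correlation(p, frame_dt=self.frame_dt)
                for p in self.positions
            ])
        return self._rho[self.scene_index]

    def choice_indices(self) -> np.ndarray:
        """Responses as indices into ``choice_labels``."""
        if self.choices is None:
            raise ValueError("session has no responses")
        labels = self.choice_labels
        lookup = {lab: i for i, lab in enumerate(labels)}
        try:
            return np.array([lookup[c] for c in self.choices], dtype=int)
        except KeyError as err:
            raise ValueError(f"response {err} outside choice set {labels}") from err

    # -- tabular views -------------------------------------------------------

    def trials_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "scene": self.scene_index,
                "structure": self.trial_labels,
                "morph": self.trial_morphs,
                "pair": self.pair_ids if self.pair_ids is not None else -1,
            }
        )
        if self.choices is not None:
            df["choice"] = self.choices
        if self.confidences is not None:
            df["confidence"] = np.where(self.confidences, "high", "low")
        return df


# -- plain-text session IO (the dialect the tabular adapter targets) ---------

def save_session(dataset: SessionDataset, prefix) -> None:
    """Write ``<prefix>.trials.tsv`` and ``<prefix>.scenes.tsv``."""
    prefix = str(prefix)
    dataset.trials_frame().to_csv(prefix + ".trials.tsv", sep="\t", index=False)
    n_unique, n_frames, _ = dataset.positions.shape
    rows = {
        "scene": np.repeat(np.arange(n_unique), n_frames),
        "frame": np.tile(np.arange(n_frames), n_unique),
    }
    flat = dataset.positions.reshape(-1, 3)
    for k, name in enumerate(("x1", "x2", "x3")):
        rows[name] = flat[:, k]
    pd.DataFrame(rows).to_csv(prefix + ".scenes.tsv", sep="\t", index=False,
                              float_format="%.17g")
    meta = pd.DataFrame(
        {
            "scene": np.arange(n_unique),
            "structure": dataset.scene_labels,
            "morph": dataset.scene_morphs,
        }
    )
    meta.to_csv(prefix + ".scene_meta.tsv", sep="\t", index=False, float_format="%.17g")


def load_session(prefix, participant: str = "p0", task: str = "4afc",
                 frame_dt: float = 0.02, tau: float = 1.5) -> SessionDataset:
    """Read a session written by :func:`save_session`.

    Rows failing validation (responses outside the task's choice set,
    malformed pairing) raise immediately — the adapter never filters.
    """
    prefix = str(prefix)
    trials = pd.read_csv(prefix + ".trials.tsv", sep="\t")
    scenes = pd.read_csv(prefix + ".scenes.tsv", sep="\t")
    meta = pd.read_csv(prefix + ".scene_meta.tsv", sep="\t")
    n_unique = int(scenes["scene"].max()) + 1
    n_frames = int(scenes["frame"].max()) + 1
    positions = scenes[["x1", "x2", "x3"]].to_numpy().reshape(n_unique, n_frames, 3)
    labels = meta["structure"].fillna("").astype(str).to_numpy(dtype=object)
    labels[labels == "nan"] = ""
    choices = trials["choice"].to_numpy(dtype=object) if "choice" in trials else None
    conf = None
    if "confidence" in trials:
        conf = (trials["confidence"] == "high").to_numpy()
    pair = trials["pair"].to_numpy()
    ds = SessionDataset(
        participant=participant,
        task=task,
        positions=positions,
        scene_index=trials["scene"].to_numpy(),
        scene_labels=labels,
        scene_morphs=meta["morph"].to_numpy(dtype=float),
        pair_ids=None if np.all(pair < 0) else pair,
        choices=choices,
        confidences=conf,
        frame_dt=frame_dt,
        tau=tau,
    )
    if choices is not None:
        ds.choice_indices()  # validates responses against the choice set
    return ds
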