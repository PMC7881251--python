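"""Algebra of hierarchical motion structures.

A motion structure couples the angular velocities of 3 dots on a circle
through 5 latent motion sources: one *global* source ``g`` driving all dots,
one *cluster* source ``c`` driving dots 1 and 2, and one *individual* source
per dot.  A binary basis matrix ``B`` (3 dots x 5 sources) records which
source drives which dot, and a vector of non-negative motion strengths
``(lam_g, lam_c, lam_1, lam_2, lam_3)`` (units rad s^-3/2) scales each
source's contribution.  The product ``B @ diag(strengths)`` is the mixing
matrix of the Ornstein-Uhlenbeck velocity process that generates scenes.

All structures used experimentally keep every dot's stationary speed
distribution identical by constraining the squared strengths along each
dot's root-to-leaf path to sum to ``MARGINAL_SPEED_SQ = 4``:

    lam_g^2 + lam_c^2 + lam_1^2 = lam_g^2 + lam_c^2 + lam_2^2
                                = lam_g^2 + lam_3^2 = 2^2.

With the marginals pinned, velocity *correlation* is the only cue to the
latent structure.  Four prototypes are used: independent (I), global (G),
clustered (C) and hierarchical (H), plus a continuum of C<->H morphs indexed
by the fraction f = lam_g^2 / (lam_g^2 + lam_c^2) carried by the global
source (f=0 is C, f=0.75 is H).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "MARGINAL_SPEED_SQ",
    "BASIS",
    "PERMUTATIONS",
    "MULTIPLICITY",
    "STRUCTURE_LABELS",
    "MotionStructure",
    "make_prototype",
    "morph_ch",
    "velocity_covariance",
    "correlation_prototype",
    "save_structure",
    "load_structure",
]

#: Squared marginal speed scale shared by every dot (= 2^2).  Alternative
#: stimulus families can rescale it; everything downstream reads this constant.
MARGINAL_SPEED_SQ: float = 4.0

#: Shared squared strength of the global+cluster pair for prototypes G, C, H
#: and all morphs: 4 - 1/16.  The residual 1/16 is the individual component
#: of the two clustered dots.
_SHARED_SQ: float = MARGINAL_SPEED_SQ - 1.0 / 16.0

#: Binary basis: rows = dots (1, 2, 3); columns = sources (g, c, 1, 2, 3).
BASIS = np.array(
    [
        [1, 1, 1, 0, 0],
        [1, 1, 0, 1, 0],
        [1, 0, 0, 0, 1],
    ],
    dtype=float,
)

#: The three dot-to-role permutation matrices.  ``PERMUTATIONS[m]`` for
#: m = 1, 2, 3; index 0 is unused so that indices match the conventional
#: 1-based labels P_1, P_2, P_3.
PERMUTATIONS: tuple[np.ndarray, ...] = (
    None,  # type: ignore[assignment]
    np.eye(3),
    np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=float),
    np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float),
)

#: Which permutations realize each structure.  I and G are invariant under
#: relabeling; C and H have three distinct dot-pairings.
MULTIPLICITY: Mapping[str, tuple[int, ...]] = {
    "I": (1,),
    "G": (1,),
    "C": (1, 2, 3),
    "H": (1, 2, 3),
}

STRUCTURE_LABELS: tuple[str, ...] = ("I", "G", "C", "H")


class UnknownStructureError(ValueError):
    """Raised for a structure label outside the implemented family."""


@dataclass(frozen=True)
class MotionStructure:
    """A motion structure: basis matrix plus source strengths.

    Parameters
    ----------
    strengths:
        Length-5 non-negative vector (lam_g, lam_c, lam_1, lam_2, lam_3)
        in rad s^-3/2.
    basis:
        Binary dot-by-source matrix; defaults to the shared 3x5 basis.
    label:
        Optional prototype name ("I", "G", "C", "H").  Morphs are unlabeled
        and carry ``morph_fraction`` instead.
    morph_fraction:
        For C<->H morphs, the fraction lam_g^2/(lam_g^2+lam_c^2); None
        otherwise.
    """

    strengths: np.ndarray
    basis: np.ndarray = field(default_factory=lambda: BASIS.copy())
    label: str | None = None
    morph_fraction: float | None = None

    def __post_init__(self) -> None:
        strengths = np.asarray(self.strengths, dtype=float)
        basis = np.asarray(self.basis, dtype=float)
        if strengths.shape != (basis.shape[1],):
            raise ValueError(
                f"strengths shape {strengths.shape} incompatible with basis {basis.shape}"
            )
        if np.any(strengths < 0):
            raise ValueError("motion strengths must be non-negative")
        object.__setattr__(self, "strengths", strengths)
        object.__setattr__(self, "basis", basis)

    @property
    def mixing_matrix(self) -> np.ndarray:
        """B @ diag(strengths): maps 5 white-noise sources to 3 dot velocities."""
        return self.basis * self.strengths[None, :]

    @property
    def source_covariance(self) -> np.ndarray:
        """B Lambda^2 B^T — the diffusion matrix of the velocity process."""
        bl = self.mixing_matrix
        return bl @ bl.T

    @property
    def path_speed_sq(self) -> np.ndarray:
        """Per-dot sum of squared strengths along the root-to-leaf path."""
        return np.diag(self.source_covariance).copy()

    def satisfies_path_sum(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.path_speed_sq, MARGINAL_SPEED_SQ, atol=atol))

    @property
    def morph_ratio(self) -> float:
        """lam_g^2 / (lam_g^2 + lam_c^2); the C<->H morph coordinate."""
        g2 = self.strengths[0] ** 2
        c2 = self.strengths[1] ** 2
        total = g2 + c2
        if total == 0.0:
            return 0.0
        return float(g2 / total)


def make_prototype(name: str) -> MotionStructure:
    """Return one of the four experiment prototypes I, G, C, H.

    Strengths are chosen so that every dot has the same marginal speed
    distribution (path-sum of squared strengths = 4 on every basis row).
    The two clustered dots carry individual strength 1/4 whenever a shared
    source is active; the third dot's individual strength absorbs whatever
    the global source does not provide, ``sqrt(4 - lam_g^2)``.
    """
    shared = np.sqrt(_SHARED_SQ)
    if name == "I":
        strengths = np.array([0.0, 0.0, 2.0, 2.0, 2.0])
    elif name == "G":
        strengths = np.array([shared, 0.0, 0.25, 0.25, 0.25])
    elif name == "C":
        strengths = np.array([0.0, shared, 0.25, 0.25, 2.0])
    elif name == "H":
        lam_g = np.sqrt(0.75 * _SHARED_SQ)
        lam_c = np.sqrt(0.25 * _SHARED_SQ)
        lam_3 = np.sqrt(MARGINAL_SPEED_SQ - 0.75 * _SHARED_SQ)
        strengths = np.array([lam_g, lam_c, 0.25, 0.25, lam_3])
    else:
        raise UnknownStructureError(f"unknown structure label {name!r}")
    return MotionStructure(strengths=strengths, label=name)


def morph_ch(f: float) -> MotionStructure:
    """Morph between the clustered (f=0) and hierarchical (f=0.75) prototypes.

    ``f`` is the fraction of the shared squared strength carried by the
    global source: lam_g^2 = f * (4 - 1/16), lam_c^2 = (1-f) * (4 - 1/16).
    Individual strengths keep all marginal speed distributions fixed.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"morph fraction must lie in [0, 1], got {f}")
    lam_g_sq = f * _SHARED_SQ
    strengths = np.array(
        [
            np.sqrt(lam_g_sq),
            np.sqrt((1.0 - f) * _SHARED_SQ),
            0.25,
            0.25,
            np.sqrt(MARGINAL_SPEED_SQ - lam_g_sq),
        ]
    )
    return MotionStructure(strengths=strengths, morph_fraction=float(f))


def velocity_covariance(s: MotionStructure, tau: float) -> np.ndarray:
    """Stationary velocity covariance (tau/2) B Lambda^2 B^T in rad^2/s^2."""
    if tau <= 0:
        raise ValueError("friction time constant tau must be positive")
    return 0.5 * tau * s.source_covariance


def correlation_prototype(s: MotionStructure, m: int = 1) -> np.ndarray:
    """Prototype pairwise velocity correlations (rho12, rho13, rho23).

    The off-diagonal entries of (1/4) (P_m B) Lambda^2 (P_m B)^T.  Requires
    the path-sum constraint so that the entries are normalized correlations.
    """
    if not s.satisfies_path_sum():
        raise ValueError(
            "correlation prototypes are only defined for equal-marginal "
            f"structures; path sums are {s.path_speed_sq}"
        )
    perm = PERMUTATIONS[m]
    mixed = perm @ s.mixing_matrix
    cov = (mixed @ mixed.T) / MARGINAL_SPEED_SQ
    return np.array([cov[0, 1], cov[0, 2], cov[1, 2]])


# -- plain-text config round-trip -------------------------------------------

def _structure_to_dict(s: MotionStructure, tau: float | None = None) -> dict:
    spec: dict = {"strengths": [float(v) for v in s.strengths]}
    if s.label is not None:
        spec["label"] = s.label
    if s.morph_fraction is not None:
        spec["morph_fraction"] = float(s.morph_fraction)
    if tau is not None:
        spec["tau"] = float(tau)
    return spec


def save_structure(s: MotionStructure, path, tau: float | None = None) -> None:
    """Write a structure specification as a YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump(_structure_to_dict(s, tau=tau), fh, sort_keys=True)


def load_structure(path) -> MotionStructure:
    """Read a structure specification written by :func:`save_structure`.

    A config with a ``morph_fraction`` key and no strengths is rebuilt via
    :func:`morph_ch`; a ``label``-only config via :func:`make_prototype`;
    explicit strengths win if present.
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if "strengths" in spec:
        return MotionStructure(
            strengths=np.asarray(spec["strengths"], dtype=float),
            label=spec.get("label"),
            morph_fraction=spec.get("morph_fraction"),
        )
    if "morph_fraction" in spec:
        return morph_ch(spec["morph_fraction"])
    if "label" in spec:
        return make_prototype(spec["label"])
    raise ValueError(f"structure config {path} has no strengths, morph_fraction or label")


def structure_for_trial(label: str | None, morph_fraction: float | None) -> MotionStructure:
    """Resolve a trial's generating structure from its metadata."""
    if morph_fraction is not None:
        return morph_ch(morph_fraction)
    if label is None:
        raise ValueError("trial carries neither a structure label nor a morph fraction")
    return make_prototype(label)


def hypothesis_pairs(choice_labels: Iterable[str]) -> tuple[tuple[str, int], ...]:
    """All (structure, permutation) hypotheses for a choice set.

    For the 4-AFC set this yields 1 + 1 + 3 + 3 = 8 pairs.
    """
    return tuple((lab, m) for lab in choice_labels for m in MULTIPLICITY[lab])
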