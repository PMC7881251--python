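"""Stochastic generation of circular motion scenes.

Dot velocities follow a multivariate Ornstein-Uhlenbeck process

    dz = v dt
    dv = -v / tau dt + B Lambda dW

with a 5-dimensional Wiener process W and friction time constant tau
(default 1.5 s).  Positions live on a circle and are wrapped to [0, 2pi)
after every integration step.  Provided all individual strengths are
positive the process has the stationary law

    v ~ N(0, (tau/2) B Lambda^2 B^T),   z_k ~ Uniform[0, 2pi) independent,

and scenes are initialized from it, so trajectories are in equilibrium from
the first frame.  Integration uses Euler-Maruyama at ``sim_dt`` (default
1 ms); the state is recorded at the frame rate (default 50 fps) without
averaging.  Stored positions are noise-free: observation noise belongs to
the observer model, not the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .structures import MotionStructure, velocity_covariance

__all__ = [
    "Scene",
    "SimulationSettings",
    "experiment_defaults",
    "simulate_scene",
    "simulate_scenes",
    "write_scene",
    "read_scene",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SimulationSettings:
    """Integration and display settings for scene generation."""

    duration: float = 4.0  # s of visible motion
    sim_dt: float = 0.001  # Euler-Maruyama step, s
    frame_dt: float = 0.02  # video frame interval, s (50 fps)
    tau: float = 1.5  # velocity friction time constant, s

    @property
    def n_frames(self) -> int:
        """Observation frames at t = 0, frame_dt, ..., duration (inclusive)."""
        return int(round(self.duration / self.frame_dt)) + 1

    @property
    def steps_per_frame(self) -> int:
        ratio = self.frame_dt / self.sim_dt
        steps = int(round(ratio))
        if abs(ratio - steps) > 1e-9 or steps < 1:
            raise ValueError(
                f"frame_dt {self.frame_dt} must be an integer multiple of sim_dt {self.sim_dt}"
            )
        return steps


def experiment_defaults() -> SimulationSettings:
    """Settings of the identification experiments: 4 s at 50 fps, 1 ms steps."""
    return SimulationSettings()


@dataclass
class Scene:
    """One simulated trial: frame times and angular dot positions.

    ``positions`` has shape (n_frames, 3), wrapped to [0, 2pi).  Latent
    velocities (rad/s) are retained when requested; they are the true OU
    state, useful for diagnostics but unavailable to any observer.
    ``color_permutation`` records which on-screen color each trajectory
    channel was shown in; it never alters the stored trajectories.
    """

    frame_times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None = None
    structure_label: str | None = None
    morph_fraction: float | None = None
    color_permutation: tuple[int, int, int] = (0, 1, 2)
    seed: int | None = None
    tau: float = 1.5
    frame_dt: float = 0.02

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.frame_times.size, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{self.frame_times.size} frames x 3 dots"
            )
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("latent velocities must match positions in shape")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


def _check_stationary(s: MotionStructure) -> None:
    # individual strengths are the last 3 entries for the 3-dot basis
    if np.any(s.strengths[2:] <= 0):
        raise ValueError(
            "stationary initialization requires positive individual motion "
            f"strengths; got {s.strengths[2:]}"
        )


def simulate_scenes(
    s: MotionStructure,
    n_scenes: int,
    settings: SimulationSettings | None = None,
    seed: int | np.random.Generator | None = None,
    keep_velocities: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate many scenes at once (vectorized over scenes).

    Returns ``positions`` with shape (n_scenes, n_frames, 3) and, when
    requested, matching latent velocities.  All scenes share one random
    stream; for per-scene reproducibility use :func:`simulate_scene`.
    """
    settings = settings or experiment_defaults()
    _check_stationary(s)
    rng = np.random.default_rng(seed)

    n_frames = settings.n_frames
    steps = settings.steps_per_frame
    dt = settings.sim_dt
    tau = settings.tau
    mixing = s.mixing_matrix  # (3, 5)
    n_sources = mixing.shape[1]

    # stationary draw: v ~ N(0, (tau/2) B Lambda^2 B^T), z ~ U[0, 2pi)
    cov_v = velocity_covariance(s, tau)
    chol = np.linalg.cholesky(cov_v + 1e-15 * np.eye(3))
    v = rng.standard_normal((n_scenes, 3)) @ chol.T
    z = rng.uniform(0.0, TWO_PI, size=(n_scenes, 3))

    positions = np.empty((n_scenes, n_frames, 3))
    velocities = np.empty((n_scenes, n_frames, 3)) if keep_velocities else None
    positions[:, 0] = z
    if velocities is not None:
        velocities[:, 0] = v

    decay = 1.0 - dt / tau
    noise_scale = np.sqrt(dt)
    mix_t = mixing.T  # (5, 3)
    for frame in range(1, n_frames):
        for _ in range(steps):
            xi = rng.standard_normal((n_scenes, n_sources))
            v = v * decay + (xi @ mix_t) * noise_scale
            z = z + v * dt
            z %= TWO_PI
        positions[:, frame] = z
        if velocities is not None:
            velocities[:, frame] = v
    return positions, velocities


def simulate_scene(
    s: MotionStructure,
    settings: SimulationSettings | None = None,
    seed: int | np.random.Generator | None = None,
    keep_velocities: bool = True,
    color_permutation: Sequence[int] = (0, 1, 2),
) -> Scene:
    """Simulate a single scene from structure ``s``.

    Identical seed and parameters give bitwise-identical trajectories.
    """
    settings = settings or experiment_defaults()
    positions, velocities = simulate_scenes(
        s, 1, settings=settings, seed=seed, keep_velocities=keep_velocities
    )
    times = np.arange(settings.n_frames) * settings.frame_dt
    return Scene(
        frame_times=times,
        positions=positions[0],
        velocities=None if velocities is None else velocities[0],
        structure_label=s.label,
        morph_fraction=s.morph_fraction,
        color_permutation=tuple(color_permutation),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        tau=settings.tau,
        frame_dt=settings.frame_dt,
    )


# -- scene file IO -----------------------------------------------------------

_COLOR_NAMES = ("red", "green", "blue")


def write_scene(scene: Scene, path) -> None:
    """Write a scene as a TSV of frames plus a YAML sidecar ``<path>.meta``.

    Floats use repr precision so read/write round-trips exactly.
    """
    path = str(path)
    cols = ["time"] + [f"x_{c}" for c in _COLOR_NAMES]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t, row in zip(scene.frame_times, scene.positions):
            fh.write("\t".join(repr(float(v)) for v in (t, *row)) + "\n")
    meta = {
        "structure_label": scene.structure_label,
        "morph_fraction": scene.morph_fraction,
        "color_permutation": list(scene.color_permutation),
        "seed": None if scene.seed is None else int(scene.seed),
        "tau": float(scene.tau),
        "frame_dt": float(scene.frame_dt),
    }
    with open(path + ".meta", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_scene(path) -> Scene:
    """Read a scene written by :func:`write_scene`."""
    path = str(path)
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    with open(path + ".meta") as fh:
        meta = yaml.safe_load(fh)
    return Scene(
        frame_times=data[:, 0],
        positions=data[:, 1:4],
        structure_label=meta.get("structure_label"),
        morph_fraction=meta.get("morph_fraction"),
        color_permutation=tuple(meta.get("color_permutation", (0, 1, 2))),
        seed=meta.get("seed"),
        tau=meta.get("tau", 1.5),
        frame_dt=meta.get("frame_dt", 0.02),
    )
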