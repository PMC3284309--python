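"""Geometric polymer models: deterministic 3D ensembles from angle schedules.

Both models describe a freely overlapping chain of rigid links (a coarse
C-alpha-trace analogue; no steric exclusion).  Every joint of a given frame
shares the same pair of angles: a deflection ``theta`` between successive
bond directions and a rotation ``phi`` about the previous bond, applied in a
parallel-transported local frame (see :mod:`polyclust._geometry`).

* **Rotation model** — ``theta`` and ``phi`` grow linearly with time
  (``epsilon * (t-1)`` and ``2 * epsilon * (t-1)``, ``epsilon = 7*pi/(n-1)``),
  carrying the chain from fully extended to a tightly wound helix.  The walk
  through angle space is linear, so any nonlinearity in the resulting RMSD
  landscape is attributable to the RMSD metric itself.

* **Cyclical model** — the same linear angle walk, but ``theta`` follows a
  triangle wave ``0 -> pi -> 0`` (and ``phi`` the same wave scaled by two),
  repeated ``cycles`` times, so the chain collapses and re-extends while
  revisiting identical conformations in reverse order.  Decrementing (rather
  than wrapping) the angles keeps every structure the same handedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import transported_frame_chain
from .containers import InvalidParameterError, StructureEnsemble

DEFAULT_LINK_LENGTH = 3.88  # Angstroms, consecutive C-alpha spacing
DEFAULT_N_LINKS = 10


@dataclass(frozen=True)
class ChainGeometry:
    """Chain composition: number of rigid links and their common length (A)."""

    n_links: int = DEFAULT_N_LINKS
    link_length: float = DEFAULT_LINK_LENGTH

    def __post_init__(self) -> None:
        if self.n_links < 2:
            raise InvalidParameterError(f"n_links must be >= 2, got {self.n_links}")
        if self.link_length <= 0:
            raise InvalidParameterError(
                f"link_length must be positive, got {self.link_length}"
            )

    @property
    def n_particles(self) -> int:
        return self.n_links + 1


@dataclass(frozen=True)
class AngleSchedule:
    """Per-frame joint angles (radians) and the per-step increment."""

    phi_series: np.ndarray
    theta_series: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        if len(self.phi_series) != len(self.theta_series):
            raise InvalidParameterError(
                "phi_series and theta_series must have equal length"
            )

    @property
    def n_frames(self) -> int:
        return len(self.phi_series)


def build_chain(phi: float, theta: float, geometry: ChainGeometry) -> np.ndarray:
    """Build one chain conformation with uniform joint angles.

    Particle 0 is at the origin and bond 1 points along +z; ``theta = 0``
    yields the fully extended chain.  Returns an ``(n_links + 1, 3)`` array
    with every bond exactly ``link_length`` long.
    """
    return transported_frame_chain(geometry.n_links, geometry.link_length,
                                   phi, theta)


def rotation_schedule(n_frames: int) -> AngleSchedule:
    """Linear angle schedule of the rotation model, ``epsilon = 7*pi/(n-1)``."""
    if n_frames < 2:
        raise InvalidParameterError(f"n_frames must be >= 2, got {n_frames}")
    eps = 7.0 * np.pi / (n_frames - 1)
    steps = np.arange(n_frames, dtype=np.float64)
    return AngleSchedule(phi_series=2.0 * eps * steps,
                         theta_series=eps * steps, epsilon=eps)


def cyclical_schedule(n_frames: int, cycles: int = 3) -> AngleSchedule:
    """Triangle-wave schedule of the cyclical model.

    ``theta`` ramps 0 -> pi -> 0 with step magnitude
    ``epsilon = 2*pi*cycles/(n-1)`` (the stated ``6*pi/(n-1)`` for the
    default three cycles), repeated ``cycles`` times over the trajectory;
    ``phi`` is the same wave scaled by two.
    """
    if n_frames < 2:
        raise InvalidParameterError(f"n_frames must be >= 2, got {n_frames}")
    if cycles < 1:
        raise InvalidParameterError(f"cycles must be >= 1, got {cycles}")
    eps = 2.0 * np.pi * cycles / (n_frames - 1)
    period = (n_frames - 1) / cycles
    peak = period / 2.0
    steps = np.arange(n_frames, dtype=np.float64)
    phase = np.mod(steps, period)
    theta = eps * np.minimum(phase, period - phase)
    return AngleSchedule(phi_series=2.0 * theta, theta_series=theta, epsilon=eps)


def ensemble_from_schedule(schedule: AngleSchedule,
                           geometry: ChainGeometry) -> StructureEnsemble:
    """Build one chain per frame of an angle schedule (deterministic)."""
    coords = np.empty((schedule.n_frames, geometry.n_particles, 3))
    for t in range(schedule.n_frames):
        coords[t] = build_chain(schedule.phi_series[t], schedule.theta_series[t],
                                geometry)
    return StructureEnsemble(coords)


def rotation_ensemble(n_frames: int,
                      geometry: ChainGeometry = ChainGeometry()) -> StructureEnsemble:
    """The rotation-model trajectory: extended chain winding into a helix."""
    return ensemble_from_schedule(rotation_schedule(n_frames), geometry)


def cyclical_ensemble(n_frames: int,
                      geometry: ChainGeometry = ChainGeometry(),
                      cycles: int = 3) -> StructureEnsemble:
    """The cyclical-model trajectory: repeated collapse/re-extension cycles."""
    return ensemble_from_schedule(cyclical_schedule(n_frames, cycles), geometry)
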