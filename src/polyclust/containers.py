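"""Core in-memory containers shared by every stage of the pipeline.

The universal trajectory object is :class:`StructureEnsemble`: an ordered
stack of frames, each frame a set of 3D particle positions.  Frame times are
1-based indices throughout the public API, matching the convention used for
the analytic polymer models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidParameterError(ValueError):
    """A model or algorithm parameter violates its documented constraint."""


class InvalidInputError(ValueError):
    """Structurally inconsistent input (shape/size mismatches, bad files)."""


@dataclass(frozen=True)
class StructureEnsemble:
    """Ordered frames of 3D particle coordinates.

    Parameters
    ----------
    coordinates : ndarray, shape (n_frames, n_particles, 3)
        Particle positions per frame, in Angstroms or reduced length units.
    frame_times : ndarray, shape (n_frames,), optional
        Strictly increasing 1-based frame indices.  Defaults to ``1..n``.
    """

    coordinates: np.ndarray
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise InvalidInputError(
                f"coordinates must have shape (frames, particles, 3), got {coords.shape}"
            )
        object.__setattr__(self, "coordinates", coords)
        if self.frame_times is None:
            times = np.arange(1, coords.shape[0] + 1)
        else:
            times = np.asarray(self.frame_times)
            if times.shape != (coords.shape[0],):
                raise InvalidInputError(
                    "frame_times length does not match the number of frames"
                )
            if times.size > 1 and not np.all(np.diff(times) > 0):
                raise InvalidInputError("frame_times must be strictly increasing")
        object.__setattr__(self, "frame_times", times)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, frame: int) -> np.ndarray:
        """Return the coordinate array of a single frame (0-based index)."""
        return self.coordinates[frame]


def concatenate_ensembles(first: StructureEnsemble,
                          second: StructureEnsemble) -> StructureEnsemble:
    """Concatenate two ensembles, renumbering frame times ``1..n1+n2``.

    Raises
    ------
    InvalidInputError
        If the particle counts differ.
    """
    if first.n_frames == 0:
        return StructureEnsemble(second.coordinates.copy())
    if second.n_frames == 0:
        return StructureEnsemble(first.coordinates.copy())
    if first.n_particles != second.n_particles:
        raise InvalidInputError(
            f"particle count mismatch: {first.n_particles} vs {second.n_particles}"
        )
    coords = np.concatenate([first.coordinates, second.coordinates], axis=0)
    return StructureEnsemble(coords)
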