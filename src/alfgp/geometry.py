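"""Molecular conformers and multi-frame XYZ trajectory I/O.

A :class:`MolecularGeometry` is one conformer — element symbols plus Cartesian
coordinates in ångström — and is the unit every downstream stage (featurization,
labelling, training) consumes.  Trajectories are plain lists of geometries;
file I/O uses the standard XYZ format (count line, comment line, ``element x y
z``) through MDAnalysis.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MolecularGeometry",
    "read_xyz",
    "write_xyz",
    "BOHR_PER_ANGSTROM",
    "ANGSTROM_PER_BOHR",
]

#: CODATA-2018 conversion between the two distance units the package supports.
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

_MIN_PAIR_DISTANCE = 1e-6  # Å; below this two atoms are considered coincident


@dataclass
class MolecularGeometry:
    """One molecular conformer.

    Parameters
    ----------
    elements
        Element symbols, length ``N``.
    coordinates
        ``N x 3`` Cartesian positions in ångström.
    frame_index
        Index of this conformer within its source trajectory.
    """

    elements: list[str]
    coordinates: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(
                f"coordinates must be N x 3, got shape {self.coordinates.shape}"
            )
        if len(self.elements) != self.coordinates.shape[0]:
            raise ValueError(
                f"{len(self.elements)} elements but "
                f"{self.coordinates.shape[0]} coordinate rows"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def validate(self, min_atoms: int = 3) -> None:
        """Raise if the geometry cannot be featurized.

        Checks the size floor and that no two atoms coincide.
        """
        if self.n_atoms < min_atoms:
            raise ValueError(
                f"geometry has {self.n_atoms} atoms; at least {min_atoms} required"
            )
        d = np.linalg.norm(
            self.coordinates[:, None, :] - self.coordinates[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] <= _MIN_PAIR_DISTANCE:
            raise ValueError(
                f"atoms {i} and {j} are coincident (distance {d[i, j]:.2e} Å)"
            )

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))

    def transformed(
        self,
        rotation: np.ndarray | None = None,
        translation: np.ndarray | None = None,
    ) -> "MolecularGeometry":
        """Return a rigidly transformed copy (coordinates @ Rᵀ + t)."""
        coords = self.coordinates
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return MolecularGeometry(list(self.elements), coords, self.frame_index)


def read_xyz(path: str | Path) -> list[MolecularGeometry]:
    """Read a (multi-frame) XYZ file into a list of geometries."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses noisily
        universe = mda.Universe(str(path), format="XYZ")
        elements = [str(n) for n in universe.atoms.names]
        frames = [
            MolecularGeometry(elements, universe.atoms.positions.astype(float), ts.frame)
            for ts in universe.trajectory
        ]
    return frames


def write_xyz(
    path: str | Path, frames: MolecularGeometry | list[MolecularGeometry]
) -> None:
    """Write one or more geometries as a multi-frame XYZ file."""
    if isinstance(frames, MolecularGeometry):
        frames = [frames]
    if not frames:
        raise ValueError("no frames to write")
    buf = io.StringIO()
    for geom in frames:
        buf.write(f"{geom.n_atoms}\n")
        buf.write(f"frame {geom.frame_index}\n")
        for el, (x, y, z) in zip(geom.elements, geom.coordinates):
            buf.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")
    Path(path).write_text(buf.getvalue())
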