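"""Atomic local frames (ALF) and the 3N−6 internal feature representation.

Every atom of a conformer gets its own right-handed axis system spanned by
three atoms: the origin atom itself, a bonded neighbour defining the x-axis
and a second bonded neighbour fixing the xy-plane (the z-axis follows from the
right-hand rule).  The neighbours are chosen by Cahn–Ingold–Prelog-style
priorities: highest priority → x-axis, second highest → xy-plane.

Features of one atom's environment, in order:

1. distance origin → x-axis atom (Å),
2. distance origin → xy-plane atom (Å),
3. the x-axis–origin–xy-plane valence angle (rad),

followed by the spherical polar coordinates ``(r, θ, φ)`` — physics
convention, θ ∈ [0, π] polar, φ ∈ [−π, π] azimuthal — of every remaining atom
expressed in the local frame, atoms enumerated in ascending original index.
That gives ``3 + (3N − 9) = 3N − 6`` features; every third non-ALF feature is
an azimuthal angle with period 2π and is flagged in the cyclic mask so kernels
can treat it periodically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MolecularGeometry, BOHR_PER_ANGSTROM, ANGSTROM_PER_BOHR

__all__ = [
    "ALFDefinition",
    "FeatureVector",
    "FrameConstructionError",
    "DegenerateFrameError",
    "feature_count",
    "cyclic_mask_for",
    "connectivity",
    "determine_alf",
    "local_axes",
    "compute_features",
    "features_matrix",
    "reconstruct_geometry",
    "convert_feature_units",
    "COVALENT_RADII",
]

# Single-bond covalent radii in Å (Cordero et al. values for the usual
# organic/bio elements; extend as needed).  Bond rule: d < 1.2 * (r_i + r_j).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Fe": 1.32, "Zn": 1.22,
    "Br": 1.20, "I": 1.39,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Fe": 26, "Zn": 30,
    "Br": 35, "I": 53,
}

BOND_SCALE = 1.2
_DEGENERATE_TOL = 1e-8  # rad; ALF angle this close to 0 or π is degenerate


class FrameConstructionError(ValueError):
    """An atomic local frame could not be constructed."""


class DegenerateFrameError(FrameConstructionError):
    """The three ALF atoms are (numerically) collinear."""


def feature_count(n_atoms: int) -> int:
    """Number of ALF features for an ``n_atoms`` molecule: 3 + (3N−9) = 3N−6."""
    if n_atoms < 3:
        raise ValueError(f"need at least 3 atoms, got {n_atoms}")
    return 3 * n_atoms - 6


def cyclic_mask_for(n_atoms: int) -> np.ndarray:
    """Boolean mask over the 3N−6 features, True on azimuthal (φ) dimensions.

    The azimuthal features sit at 0-based indices 5, 8, 11, … — every third
    feature after the three frame-defining ones.
    """
    mask = np.zeros(feature_count(n_atoms), dtype=bool)
    mask[5::3] = True
    return mask


@dataclass(frozen=True)
class ALFDefinition:
    """Per-atom (origin, x-axis, xy-plane) atom indices."""

    origin: tuple[int, ...]
    x_axis: tuple[int, ...]
    xy_plane: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.origin)
        if not (len(self.x_axis) == len(self.xy_plane) == n):
            raise ValueError("origin/x_axis/xy_plane must have equal length")
        for o, x, p in zip(self.origin, self.x_axis, self.xy_plane):
            if len({o, x, p}) != 3:
                raise ValueError(f"ALF indices for atom {o} are not distinct")

    def triple(self, atom_index: int) -> tuple[int, int, int]:
        return (
            self.origin[atom_index],
            self.x_axis[atom_index],
            self.xy_plane[atom_index],
        )

    def to_table(self) -> str:
        """Plain-text export: atom_index origin x_axis xy_plane (0-based)."""
        lines = ["# alf-table v1 (0-based indices)",
                 "# atom_index origin x_axis xy_plane"]
        for i, (o, x, p) in enumerate(
            zip(self.origin, self.x_axis, self.xy_plane)
        ):
            lines.append(f"{i} {o} {x} {p}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "ALFDefinition":
        rows = [
            tuple(int(t) for t in line.split())
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        rows.sort(key=lambda r: r[0])
        return cls(
            origin=tuple(r[1] for r in rows),
            x_axis=tuple(r[2] for r in rows),
            xy_plane=tuple(r[3] for r in rows),
        )


@dataclass
class FeatureVector:
    """One atom's 3N−6 ALF features plus the cyclic-dimension mask."""

    values: np.ndarray
    cyclic_mask: np.ndarray
    atom_index: int = 0
    unit: str = "angstrom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cyclic_mask = np.asarray(self.cyclic_mask, dtype=bool)
        if self.values.shape != self.cyclic_mask.shape:
            raise ValueError("values and cyclic_mask shapes differ")

    def __len__(self) -> int:
        return self.values.size


def connectivity(geometry: MolecularGeometry) -> list[list[int]]:
    """Bonded-neighbour lists from the covalent-radius distance rule."""
    try:
        radii = np.array([COVALENT_RADII[e] for e in geometry.elements])
    except KeyError as exc:
        raise FrameConstructionError(f"no covalent radius for element {exc}") from exc
    coords = geometry.coordinates
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cutoff = BOND_SCALE * (radii[:, None] + radii[None, :])
    bonded = (d < cutoff) & ~np.eye(geometry.n_atoms, dtype=bool)
    return [list(np.nonzero(row)[0]) for row in bonded]


def _priority_key(
    candidate: int, origin: int, neighbours: list[list[int]], z: np.ndarray
) -> tuple:
    """CIP-style priority key for a neighbour of ``origin``.

    Atomic number first; ties resolved by breadth-first neighbour spheres
    (sorted-descending atomic-number multisets per sphere), exploring the bond
    graph away from the origin.  Larger key = higher priority.
    """
    key = [(int(z[candidate]),)]
    visited = {origin, candidate}
    frontier = [candidate]
    while frontier:
        nxt: list[int] = []
        for a in frontier:
            for b in neighbours[a]:
                if b not in visited:
                    visited.add(b)
                    nxt.append(b)
        if not nxt:
            break
        key.append(tuple(sorted((int(z[b]) for b in nxt), reverse=True)))
        frontier = nxt
    return tuple(key)


def determine_alf(geometry: MolecularGeometry) -> ALFDefinition:
    """Assign each atom's local frame by CIP-style neighbour priorities.

    The highest-priority bonded neighbour becomes the x-axis atom and the
    second highest the xy-plane atom.  When an atom has a single bonded
    neighbour (terminal atoms), the xy-plane atom is taken from the
    neighbour's own remaining bonded atoms, again by priority.  Exact
    priority ties are broken by the lower atom index, so the result is
    deterministic and independent of input order.
    """
    geometry.validate(min_atoms=3)
    neigh = connectivity(geometry)
    z = np.array([ATOMIC_NUMBERS[e] for e in geometry.elements])

    def ranked(cands: list[int], origin: int) -> list[int]:
        # descending priority; residual ties -> ascending atom index
        return sorted(
            cands, key=lambda c: (_priority_key(c, origin, neigh, z), -c), reverse=True
        )

    origin_idx, x_idx, p_idx = [], [], []
    for a in range(geometry.n_atoms):
        if not neigh[a]:
            raise FrameConstructionError(
                f"atom {a} ({geometry.elements[a]}) has no bonded neighbour"
            )
        order = ranked(neigh[a], a)
        x = order[0]
        if len(order) > 1:
            p = order[1]
        else:
            # terminal atom: borrow the xy-plane atom from the x-axis atom's
            # other neighbours
            second = ranked([b for b in neigh[x] if b != a], x)
            if not second:
                raise FrameConstructionError(
                    f"atom {a} ({geometry.elements[a]}) has no second frame atom"
                )
            p = second[0]
        origin_idx.append(a)
        x_idx.append(x)
        p_idx.append(p)
    return ALFDefinition(tuple(origin_idx), tuple(x_idx), tuple(p_idx))


def local_axes(
    geometry: MolecularGeometry, alf: ALFDefinition, atom_index: int
) -> np.ndarray:
    """Rows of the returned 3×3 matrix are the x̂, ŷ, ẑ axes of the atom's ALF.

    ``C @ (r - r_origin)`` maps global Cartesian displacements into the local
    frame; ``C`` is a proper rotation (det +1, right-handed).
    """
    o, x, p = alf.triple(atom_index)
    coords = geometry.coordinates
    vx = coords[x] - coords[o]
    vp = coords[p] - coords[o]
    nx = np.linalg.norm(vx)
    npl = np.linalg.norm(vp)
    if nx == 0 or npl == 0:
        raise DegenerateFrameError(f"zero-length ALF vector at atom {atom_index}")
    xhat = vx / nx
    cosang = float(np.clip(np.dot(xhat, vp / npl), -1.0, 1.0))
    if min(np.arccos(cosang), np.pi - np.arccos(cosang)) < _DEGENERATE_TOL:
        raise DegenerateFrameError(
            f"collinear ALF atoms {o}, {x}, {p} for atom {atom_index}"
        )
    zhat = np.cross(xhat, vp)
    zhat /= np.linalg.norm(zhat)
    yhat = np.cross(zhat, xhat)
    return np.vstack([xhat, yhat, zhat])


def compute_features(
    geometry: MolecularGeometry, alf: ALFDefinition, atom_index: int
) -> FeatureVector:
    """The 3N−6 ALF feature vector of one atom's environment."""
    geometry.validate(min_atoms=3)
    o, x, p = alf.triple(atom_index)
    coords = geometry.coordinates
    axes = local_axes(geometry, alf, atom_index)
    r_x = geometry.distance(o, x)
    r_p = geometry.distance(o, p)
    vx = (coords[x] - coords[o]) / r_x
    vp = (coords[p] - coords[o]) / r_p
    angle = float(np.arccos(np.clip(np.dot(vx, vp), -1.0, 1.0)))

    values = [r_x, r_p, angle]
    for j in range(geometry.n_atoms):
        if j in (o, x, p):
            continue
        local = axes @ (coords[j] - coords[o])
        r = np.linalg.norm(local)
        theta = float(np.arccos(np.clip(local[2] / r, -1.0, 1.0)))
        phi = float(np.arctan2(local[1], local[0]))
        values.extend([r, theta, phi])
    return FeatureVector(
        np.array(values), cyclic_mask_for(geometry.n_atoms), atom_index=atom_index
    )


def features_matrix(
    frames: list[MolecularGeometry], alf: ALFDefinition, atom_index: int
) -> np.ndarray:
    """Stack one atom's features over a trajectory: n_frames × (3N−6)."""
    return np.array(
        [compute_features(g, alf, atom_index).values for g in frames]
    )


def reconstruct_geometry(
    features: FeatureVector,
    alf: ALFDefinition,
    n_atoms: int,
    elements: list[str],
    frame_index: int = 0,
) -> MolecularGeometry:
    """Rebuild Cartesian coordinates (in the atom's local frame) from features.

    Inverse of :func:`compute_features` up to a global rotation + translation:
    the origin atom sits at the origin, the x-axis atom on +x and the
    xy-plane atom in the upper (y > 0) half of the xy-plane.
    """
    if len(features) != feature_count(n_atoms):
        raise ValueError(
            f"feature vector length {len(features)} != {feature_count(n_atoms)}"
        )
    o, x, p = alf.triple(features.atom_index)
    v = features.values
    coords = np.zeros((n_atoms, 3))
    coords[x] = [v[0], 0.0, 0.0]
    coords[p] = [v[1] * np.cos(v[2]), v[1] * np.sin(v[2]), 0.0]
    others = [j for j in range(n_atoms) if j not in (o, x, p)]
    for k, j in enumerate(others):
        r, theta, phi = v[3 + 3 * k : 6 + 3 * k]
        coords[j] = [
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
            r * np.cos(theta),
        ]
    return MolecularGeometry(list(elements), coords, frame_index)


def convert_feature_units(
    values: np.ndarray, n_atoms: int, to: str
) -> np.ndarray:
    """Convert the distance entries of feature vectors between Å and bohr.

    Angle entries are untouched.  ``values`` may be a single feature vector or
    an ``n × D`` stack.
    """
    factor = {"bohr": BOHR_PER_ANGSTROM, "angstrom": ANGSTROM_PER_BOHR}[to]
    values = np.array(values, dtype=float)
    dist = np.zeros(feature_count(n_atoms), dtype=bool)
    dist[[0, 1]] = True
    dist[3::3] = True
    values[..., dist] *= factor
    return values
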