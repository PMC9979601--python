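"""Seeded synthetic conformer sampling and surrogate atomic-property labels.

This module stands in for the expensive parts of a force-field training
campaign — molecular-dynamics conformer generation and ab initio atomic
properties — with desk-scale generators, so the featurization, regression,
active-learning and electrostatics stages can be exercised end to end with
no external software.

Conformers are produced by perturbing *all* 3N−6 internal degrees of freedom
of a template: the atom-0 ALF feature vector is distorted (distances by
± an amplitude, polar angles likewise, azimuthal angles either by a bounded
kick or — in "full rotation" mode — redrawn uniformly on [−π, π)) and the
Cartesian geometry is rebuilt with the feature-inversion routine.  Frames
whose distortion produces an atomic clash are resampled and counted.

Labels come from a smooth, deterministic property surface with explicitly
periodic azimuthal dependence:

* Morse-like terms ``De (1 − exp(−a (r − r₀)))²`` in every distance feature
  (r₀ = the template's value),
* low-order cosine series ``Σ_k a_k cos(kθ)`` in polar/valence angles,
* full sine+cosine series in every azimuthal feature, 2π-periodic by
  construction,

plus optional Gaussian label noise.  Each labelled point also carries a
simulated integration error L(Ω): a log-normal bulk near 1e-4 a.u. with a
configurable heavy tail (default 2%) landing above the 0.001 a.u. scrubbing
threshold, so the scrubbing stage has real work to do.  All labels and
errors are reproducible from the seed and the frame index alone, independent
of evaluation order.

No physical realism is claimed: the labels are surrogate "a.u." quantities,
and the pipeline never assumes they are physical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .active_learning import LabeledPoint
from .alf import (
    ALFDefinition,
    FeatureVector,
    compute_features,
    cyclic_mask_for,
    determine_alf,
    feature_count,
    reconstruct_geometry,
)
from .geometry import MolecularGeometry, read_xyz

__all__ = [
    "TEMPLATES",
    "load_template",
    "DistortionConfig",
    "sample_conformers",
    "OracleSpec",
    "surface_value",
    "label",
    "SyntheticOracle",
]

TEMPLATES = ("water", "glycine19", "glucose24", "ibuprofen33")
_CLASH_DISTANCE = 0.5  # Å; closer pairs mean the distortion broke the molecule


def load_template(name: str) -> MolecularGeometry:
    """One of the packaged idealized templates (water, glycine19,
    glucose24, ibuprofen33)."""
    if name not in TEMPLATES:
        raise ValueError(f"unknown template {name!r}; choose from {TEMPLATES}")
    with resources.as_file(
        resources.files("alfgp.data").joinpath(f"{name}.xyz")
    ) as path:
        return read_xyz(path)[0]


@dataclass(frozen=True)
class DistortionConfig:
    """Amplitudes of the internal-coordinate distortions.

    Defaults emulate a room-temperature ensemble: a few hundredths of an Å
    on distances and ~0.15 rad on angles.  With ``full_rotations`` azimuthal
    angles are redrawn uniformly on [−π, π) instead (think free methyl
    rotors); expect heavy clash-resampling on crowded molecules.
    """

    amplitude_r: float = 0.05   # Å
    amplitude_theta: float = 0.15  # rad, polar + valence angles
    amplitude_phi: float = 0.3    # rad, azimuthal kicks when not full rotation
    full_rotations: bool = False
    max_tries: int = 200

    def __post_init__(self) -> None:
        if min(self.amplitude_r, self.amplitude_theta, self.amplitude_phi) < 0:
            raise ValueError("distortion amplitudes must be non-negative")


def sample_conformers(
    template: MolecularGeometry,
    n_frames: int,
    distortion: DistortionConfig | None = None,
    seed: int = 0,
    alf: ALFDefinition | None = None,
) -> tuple[list[MolecularGeometry], int]:
    """Distorted conformer trajectory; returns (frames, n_clashes_resampled)."""
    distortion = distortion or DistortionConfig()
    template.validate()
    alf = alf or determine_alf(template)
    base = compute_features(template, alf, 0)
    n = template.n_atoms
    mask = base.cyclic_mask
    theta_dims = np.zeros(len(base), dtype=bool)
    theta_dims[2] = True
    theta_dims[4::3] = True
    r_dims = ~(mask | theta_dims)

    rng = np.random.default_rng(seed)
    frames: list[MolecularGeometry] = []
    clashes = 0
    for k in range(n_frames):
        for attempt in range(distortion.max_tries):
            v = base.values.copy()
            v[r_dims] += rng.uniform(
                -distortion.amplitude_r, distortion.amplitude_r, r_dims.sum()
            )
            v[theta_dims] += rng.uniform(
                -distortion.amplitude_theta,
                distortion.amplitude_theta,
                theta_dims.sum(),
            )
            if distortion.full_rotations:
                v[mask] = rng.uniform(-np.pi, np.pi, mask.sum())
            else:
                v[mask] += rng.uniform(
                    -distortion.amplitude_phi, distortion.amplitude_phi, mask.sum()
                )
                v[mask] = np.mod(v[mask] + np.pi, 2 * np.pi) - np.pi
            # keep distances positive and polar angles inside [0, π]
            v[r_dims] = np.maximum(v[r_dims], 0.1)
            v[theta_dims] = np.clip(v[theta_dims], 1e-3, np.pi - 1e-3)
            geom = reconstruct_geometry(
                FeatureVector(v, mask, atom_index=0), alf, n, template.elements, k
            )
            d = np.linalg.norm(
                geom.coordinates[:, None, :] - geom.coordinates[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() >= _CLASH_DISTANCE:
                frames.append(geom)
                break
            clashes += 1
        else:
            raise RuntimeError(
                f"frame {k}: no clash-free distortion in {distortion.max_tries} tries"
            )
    return frames, clashes


@dataclass(frozen=True)
class OracleSpec:
    """Definition of the surrogate property surface and its noise model.

    The surface coefficients are drawn once from ``seed`` and frozen; the
    surface itself is deterministic given features + coefficients and
    2π-periodic in every azimuthal feature by construction.
    """

    reference_features: np.ndarray
    cyclic_mask: np.ndarray
    seed: int = 0
    sigma_label: float = 0.0       # a.u., Gaussian label noise
    n_harmonics: int = 3
    morse_depth: float = 0.5       # a.u., De scale of the radial terms
    morse_width: float = 1.5       # 1/Å
    angle_scale: float = 0.1       # a.u., polar-angle cosine series scale
    phi_scale: float = 0.1         # a.u., azimuthal series scale
    locality_decay: float = 2.5    # e-folding of term size per non-ALF atom rank
    error_tail_fraction: float = 0.02  # share of L(Ω) above 0.001 a.u.

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reference_features",
            np.asarray(self.reference_features, dtype=float),
        )
        object.__setattr__(
            self, "cyclic_mask", np.asarray(self.cyclic_mask, dtype=bool)
        )
        if self.reference_features.shape != self.cyclic_mask.shape:
            raise ValueError("reference features and cyclic mask shapes differ")
        if self.sigma_label < 0:
            raise ValueError("sigma_label must be >= 0")

    @property
    def n_dim(self) -> int:
        return self.reference_features.size

    def coefficients(self) -> dict[str, np.ndarray]:
        """Frozen per-dimension coefficients, derived from the seed."""
        rng = np.random.default_rng(self.seed)
        D, H = self.n_dim, self.n_harmonics
        # Atomic properties are dominated by the local environment: terms
        # belonging to the k-th non-ALF atom decay as exp(-(k+1)/decay), so a
        # handful of feature dimensions carry most of the signal.
        rank = np.zeros(D)
        if D > 3:
            rank[3:] = np.repeat(np.arange(1, (D - 3) // 3 + 1), 3)
        w = np.exp(-rank / self.locality_decay)
        return {
            "morse_depth": self.morse_depth * w * rng.uniform(0.5, 1.5, D),
            "morse_width": self.morse_width * rng.uniform(0.7, 1.3, D),
            "angle_cos": self.angle_scale * w[:, None] * rng.normal(size=(D, H)),
            "phi_cos": self.phi_scale * w[:, None] * rng.normal(size=(D, H)),
            "phi_sin": self.phi_scale * w[:, None] * rng.normal(size=(D, H)),
        }


def surface_value(features: np.ndarray, spec: OracleSpec) -> np.ndarray:
    """Noiseless surrogate property surface (vectorized over rows)."""
    F = np.atleast_2d(np.asarray(getattr(features, "values", features), float))
    if F.shape[1] != spec.n_dim:
        raise ValueError(f"feature length {F.shape[1]} != oracle dim {spec.n_dim}")
    c = spec.coefficients()
    mask = spec.cyclic_mask
    theta = np.zeros(spec.n_dim, dtype=bool)
    theta[2] = True
    if spec.n_dim > 4:
        theta[4::3] = True
    radial = ~(mask | theta)
    ref = spec.reference_features
    out = np.zeros(F.shape[0])
    for d in np.nonzero(radial)[0]:
        disp = F[:, d] - ref[d]
        out += c["morse_depth"][d] * (1.0 - np.exp(-c["morse_width"][d] * disp)) ** 2
    ks = np.arange(1, spec.n_harmonics + 1)
    for d in np.nonzero(theta)[0]:
        out += np.cos(np.outer(F[:, d], ks)) @ c["angle_cos"][d]
    for d in np.nonzero(mask)[0]:
        arg = np.outer(F[:, d], ks)
        out += np.cos(arg) @ c["phi_cos"][d] + np.sin(arg) @ c["phi_sin"][d]
    return out


def _point_rng(spec: OracleSpec, source_frame: int, features: np.ndarray) -> np.random.Generator:
    """Deterministic per-point RNG: seed ⊕ frame (or a feature digest)."""
    if source_frame >= 0:
        entropy = source_frame
    else:
        entropy = zlib.crc32(np.round(features, 9).tobytes())
    return np.random.default_rng([spec.seed, entropy])


def _integration_error(rng: np.random.Generator, tail_fraction: float) -> float:
    if rng.uniform() < tail_fraction:
        return 0.001 * (1.0 + rng.exponential(1.0))  # heavy tail, scrubbed
    return float(np.exp(rng.normal(np.log(1e-4), 0.5)))  # bulk near 1e-4 a.u.


def label(
    features: FeatureVector | np.ndarray,
    spec: OracleSpec,
    source_frame: int = -1,
) -> LabeledPoint:
    """Label one feature vector: surface + noise, with a simulated L(Ω)."""
    values = np.asarray(getattr(features, "values", features), dtype=float)
    rng = _point_rng(spec, source_frame, values)
    y = float(surface_value(values, spec)[0])
    if spec.sigma_label > 0:
        y += float(rng.normal(0.0, spec.sigma_label))
    return LabeledPoint(
        features=values,
        label=y,
        integration_error=_integration_error(rng, spec.error_tail_fraction),
        source_frame=source_frame,
    )


class SyntheticOracle:
    """File-free labeller satisfying the active-learning oracle contract.

    Holds a featurized trajectory (one atom's feature matrix) and labels any
    frame index on demand, deterministically in the seed and frame index.
    """

    def __init__(self, features_all_frames: np.ndarray, spec: OracleSpec) -> None:
        self.features = np.atleast_2d(np.asarray(features_all_frames, float))
        self.spec = spec

    def __call__(self, frame_indices) -> list[LabeledPoint]:
        return [
            label(self.features[int(f)], self.spec, source_frame=int(f))
            for f in frame_indices
        ]

    def labels_frame(self) -> "pd.DataFrame":  # noqa: F821 - typing only
        """Whole-trajectory label table (frame, value, L(Ω))."""
        import pandas as pd

        pts = self(range(self.features.shape[0]))
        return pd.DataFrame(
            {
                "frame": [p.source_frame for p in pts],
                "value": [p.label for p in pts],
                "integration_error": [p.integration_error for p in pts],
            }
        )
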