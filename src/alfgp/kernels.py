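"""Correlation kernels for ALF feature spaces.

The total covariance between two feature vectors is a product of one factor
per dimension: a squared-exponential (RBF) factor for every ordinary
dimension and an exponential sine-squared (periodic) factor for every
azimuthal dimension, whose period is fixed at 2π because azimuthal angles
live on the circle.  Canonical forms used throughout the package
(``kernel_form = "rbf-expsin2-v1"``):

    noncyclic:  exp( − Δ_d² / (2 l_d²) )
    cyclic:     exp( − 2 sin²(Δ_d / 2) / l_d² )

Both factors lie in (0, 1] and equal 1 at zero (or 2π-shifted) separation, so
the kernel is a correlation function: the covariance matrix has unit diagonal
before the nugget is added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KernelSpec", "KERNEL_FORM", "kernel_value", "kernel_matrix",
           "build_covariance", "IllConditionedError"]

KERNEL_FORM = "rbf-expsin2-v1"
PERIOD = 2.0 * np.pi  # azimuthal angles repeat every full turn
MIN_NUGGET = 1e-12


class IllConditionedError(np.linalg.LinAlgError):
    """Covariance matrix could not be Cholesky-factorized even after retry."""


@dataclass
class KernelSpec:
    """Product-kernel hyperparameters.

    Parameters
    ----------
    lengthscales
        One positive lengthscale per feature dimension.
    cyclic_mask
        True on azimuthal dimensions (handled by the periodic factor).
    nugget
        Variance added to the covariance diagonal (jitter); may be as small
        as 1e-8 on scrubbed, smooth data.
    """

    lengthscales: np.ndarray
    cyclic_mask: np.ndarray
    nugget: float = 1e-8
    period: float = PERIOD

    def __post_init__(self) -> None:
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        self.cyclic_mask = np.atleast_1d(np.asarray(self.cyclic_mask, dtype=bool))
        if self.lengthscales.shape != self.cyclic_mask.shape:
            raise ValueError("lengthscales and cyclic_mask shapes differ")
        if np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be positive")
        if self.nugget < MIN_NUGGET:
            raise ValueError(f"nugget must be >= {MIN_NUGGET}")
        if not np.isclose(self.period, PERIOD):
            raise ValueError("the period of azimuthal dimensions is fixed at 2*pi")

    @property
    def n_dim(self) -> int:
        return self.lengthscales.size


def kernel_value(x1: np.ndarray, x2: np.ndarray, spec: KernelSpec) -> float:
    """Covariance of two feature vectors; symmetric, in (0, 1], k(x, x) = 1."""
    x1 = np.asarray(getattr(x1, "values", x1), dtype=float)
    x2 = np.asarray(getattr(x2, "values", x2), dtype=float)
    if x1.shape != (spec.n_dim,) or x2.shape != (spec.n_dim,):
        raise ValueError(
            f"feature dimension mismatch: {x1.shape}, {x2.shape} vs D={spec.n_dim}"
        )
    return float(kernel_matrix(x1[None, :], x2[None, :], spec)[0, 0])


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Cross-covariance matrix between two stacks of feature vectors."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != spec.n_dim or X2.shape[1] != spec.n_dim:
        raise ValueError("feature dimension mismatch with kernel spec")
    mask = spec.cyclic_mask
    l = spec.lengthscales
    exponent = np.zeros((X1.shape[0], X2.shape[0]))
    if np.any(~mask):
        # Σ Δ²/(2 l²) via a weighted squared euclidean distance
        scale = 1.0 / (l[~mask] * np.sqrt(2.0))
        exponent += cdist(X1[:, ~mask] * scale, X2[:, ~mask] * scale, "sqeuclidean")
    for d in np.nonzero(mask)[0]:
        half_diff = 0.5 * (X1[:, d, None] - X2[None, :, d])
        exponent += 2.0 * np.sin(half_diff) ** 2 / l[d] ** 2
    return np.exp(-exponent)


def build_covariance(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Training covariance R = K(X, X) + σ²I (unit diagonal before nugget)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one training point")
    R = kernel_matrix(X, X, spec)
    R[np.diag_indices_from(R)] += spec.nugget
    return R


def cholesky_with_retry(R: np.ndarray, nugget: float) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of R; one retry with 10× nugget before raising.

    Scrubbed training data should be smooth, so persistent failure signals a
    genuinely bad input set rather than something to paper over.
    """
    try:
        return np.linalg.cholesky(R), nugget
    except np.linalg.LinAlgError:
        bumped = R + 9.0 * nugget * np.eye(R.shape[0])
        warnings.warn(
            "covariance not positive definite; retrying with 10x nugget",
            stacklevel=2,
        )
        try:
            return np.linalg.cholesky(bumped), 10.0 * nugget
        except np.linalg.LinAlgError as exc:
            smallest = float(np.linalg.eigvalsh(R)[0])
            raise IllConditionedError(
                f"covariance is ill-conditioned even at 10x nugget "
                f"(smallest eigenvalue {smallest:.3e})"
            ) from exc
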