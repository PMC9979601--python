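"""Per-atom Gaussian process regression with a concentrated likelihood.

One model predicts one scalar property of one atom from that atom's ALF
features.  The prior is a constant-mean GP with the product correlation
kernel of :mod:`alfgp.kernels`; both the constant mean μ and the process
variance are profiled out of the marginal likelihood analytically, leaving a
"concentrated" log-likelihood that depends only on the lengthscales (the
nugget is held fixed).  Maximizing it is delegated to the particle-swarm
optimizer.

The public surface follows the Model/Results convention: build an
:class:`AtomicGPR` from training data, call :meth:`AtomicGPR.fit`, and use the
returned :class:`GPRResults` for prediction, predictive variance, summaries
and serialization.  After fitting, prediction weights w = R⁻¹(y − 1μ̂) are
precomputed once so each prediction is a single O(n) dot product instead of
an O(n³) solve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .kernels import (
    KERNEL_FORM,
    IllConditionedError,
    KernelSpec,
    build_covariance,
    cholesky_with_retry,
    kernel_matrix,
)

__all__ = [
    "AtomicGPR",
    "GPRResults",
    "concentrated_mean",
    "concentrated_log_likelihood",
]

MODEL_SCHEMA_VERSION = "1.0"
_SIGMA2_FLOOR = 1e-16  # keeps the likelihood finite for constant targets


def _factorize(X: np.ndarray, spec: KernelSpec) -> tuple[np.ndarray, float]:
    R = build_covariance(X, spec)
    return cholesky_with_retry(R, spec.nugget)


def _profile(L: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profiled mean, process variance and log|R| from the Cholesky factor."""
    n = y.size
    ones = np.ones(n)
    Rinv_y = cho_solve((L, True), y)
    Rinv_1 = cho_solve((L, True), ones)
    mu = float(ones @ Rinv_y / (ones @ Rinv_1))
    resid = y - mu
    sigma2 = float(resid @ cho_solve((L, True), resid)) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return mu, sigma2, logdet


def concentrated_mean(X: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """Analytically optimal constant mean μ̂ = (1ᵀR⁻¹y)/(1ᵀR⁻¹1)."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 training points")
    L, _ = _factorize(X, spec)
    return _profile(L, y)[0]


def concentrated_log_likelihood(
    X: np.ndarray, y: np.ndarray, spec: KernelSpec
) -> float:
    """Marginal log-likelihood with μ and the process variance profiled out.

    With σ̂² = (y − 1μ̂)ᵀ R⁻¹ (y − 1μ̂) / n the concentrated value is

        −(n/2)·[ln(2π σ̂²) + 1] − ½ ln|R|

    which depends on the lengthscales only.  Invariant to reordering of the
    training points.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 training points")
    L, _ = _factorize(X, spec)
    _, sigma2, logdet = _profile(L, y)
    sigma2 = max(sigma2, _SIGMA2_FLOOR)
    return float(-0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * logdet)


class AtomicGPR:
    """GP regression model for one atom's scalar property.

    Parameters
    ----------
    X
        n × D training feature matrix (one atom's ALF features per row).
    y
        Training targets, length n.
    cyclic_mask
        True on azimuthal feature dimensions; default all-False.
    nugget
        Diagonal jitter σ²; 1e-8 is appropriate for scrubbed data.
    property_tag, atom_tag
        Labels carried through to files and reports (e.g. ``"iqa"``, ``"O1"``).
    unit
        Distance unit of the feature columns, recorded in metadata.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cyclic_mask: np.ndarray | None = None,
        nugget: float = 1e-8,
        property_tag: str = "iqa",
        atom_tag: str = "atom0",
        unit: str = "angstrom",
    ) -> None:
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or self.y.size != self.X.shape[0]:
            raise ValueError("y must be 1-D with one entry per row of X")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 training points")
        if cyclic_mask is None:
            cyclic_mask = np.zeros(self.X.shape[1], dtype=bool)
        self.cyclic_mask = np.asarray(cyclic_mask, dtype=bool)
        if self.cyclic_mask.shape != (self.X.shape[1],):
            raise ValueError("cyclic_mask length must equal the feature dimension")
        self.nugget = float(nugget)
        self.property_tag = property_tag
        self.atom_tag = atom_tag
        self.unit = unit

    @property
    def n_train(self) -> int:
        return self.X.shape[0]

    @property
    def n_dim(self) -> int:
        return self.X.shape[1]

    def spec(self, lengthscales: np.ndarray) -> KernelSpec:
        return KernelSpec(lengthscales, self.cyclic_mask, nugget=self.nugget)

    def loglike(self, log10_lengthscales: np.ndarray) -> float:
        """Concentrated log-likelihood at the given log₁₀ lengthscales."""
        try:
            return concentrated_log_likelihood(
                self.X, self.y, self.spec(10.0 ** np.asarray(log10_lengthscales))
            )
        except IllConditionedError:
            return -np.inf

    def fit(
        self,
        lengthscales: np.ndarray | float | None = None,
        pso_config: "PSOConfig | None" = None,
        seed: int | None = None,
        warm_start: np.ndarray | None = None,
    ) -> "GPRResults":
        """Fit the model and return results.

        With explicit ``lengthscales`` only the mean, process variance and
        prediction weights are computed.  Otherwise the lengthscales are
        found by PSO maximization of the concentrated log-likelihood in
        log₁₀ space.
        """
        trace = None
        if lengthscales is None:
            from .pso import PSOConfig, optimize_hyperparameters

            config = pso_config or PSOConfig()
            if seed is not None:
                config = config.replace(seed=seed)
            pso_result = optimize_hyperparameters(
                self.X,
                self.y,
                cyclic_mask=self.cyclic_mask,
                nugget=self.nugget,
                config=config,
                warm_start=warm_start,
            )
            spec = pso_result.spec
            trace = pso_result.trace
        else:
            ls = np.asarray(lengthscales, dtype=float)
            if ls.ndim == 0:
                ls = np.full(self.n_dim, float(ls))
            spec = self.spec(ls)
        return GPRResults(self, spec, optimizer_trace=trace)


class GPRResults:
    """Fitted per-atom GP: hyperparameters, profiled mean and variance,
    precomputed prediction weights, and prediction/variance methods."""

    def __init__(
        self,
        model: AtomicGPR,
        spec: KernelSpec,
        optimizer_trace: np.ndarray | None = None,
    ) -> None:
        self.model = model
        self.spec = spec
        self.optimizer_trace = optimizer_trace
        L, effective_nugget = _factorize(model.X, spec)
        if effective_nugget != spec.nugget:
            self.spec = KernelSpec(
                spec.lengthscales, spec.cyclic_mask, nugget=effective_nugget
            )
        self._L = L
        mu, sigma2, logdet = _profile(L, model.y)
        self.mu_hat = mu
        self.sigma2_process = max(sigma2, _SIGMA2_FLOOR)
        n = model.n_train
        self.loglike = float(
            -0.5 * n * (np.log(2.0 * np.pi * self.sigma2_process) + 1.0)
            - 0.5 * logdet
        )
        self.weights = cho_solve((L, True), model.y - mu)
        self._Rinv_1 = cho_solve((L, True), np.ones(n))
        self._one_Rinv_one = float(np.sum(self._Rinv_1))

    # ------------------------------------------------------------------ #
    def _cross(self, X_star: np.ndarray) -> np.ndarray:
        X_star = np.atleast_2d(np.asarray(getattr(X_star, "values", X_star), float))
        if X_star.shape[1] != self.model.n_dim:
            raise ValueError(
                f"feature dimension {X_star.shape[1]} != model dimension "
                f"{self.model.n_dim}"
            )
        return kernel_matrix(X_star, self.model.X, self.spec)

    def predict(self, X_star: np.ndarray) -> np.ndarray | float:
        """Posterior mean μ̂ + rᵀw at one or more query points."""
        scalar = np.asarray(getattr(X_star, "values", X_star)).ndim == 1
        out = self.mu_hat + self._cross(X_star) @ self.weights
        return float(out[0]) if scalar else out

    def predict_variance(
        self, X_star: np.ndarray, scale: str = "correlation"
    ) -> np.ndarray | float:
        """Mean-corrected kriging variance.

        On the default correlation scale

            s²(x*) = 1 − rᵀR⁻¹r + (1 − 1ᵀR⁻¹r)² / (1ᵀR⁻¹1)

        so at a training point s² ≈ σ² (the nugget) and far from all training
        points it reverts to the constant 1 + 1/(1ᵀR⁻¹1).  With
        ``scale="process"`` the value is multiplied by the profiled process
        variance to give property units squared.
        """
        arr = np.asarray(getattr(X_star, "values", X_star))
        scalar = arr.ndim == 1
        r = self._cross(X_star)  # m × n
        v = solve_triangular(self._L, r.T, lower=True)  # n × m
        quad = np.sum(v * v, axis=0)
        one_Rinv_r = r @ self._Rinv_1
        var = 1.0 - quad + (1.0 - one_Rinv_r) ** 2 / self._one_Rinv_one
        var = np.maximum(var, 0.0)
        if scale == "process":
            var = var * self.sigma2_process
        elif scale != "correlation":
            raise ValueError("scale must be 'correlation' or 'process'")
        return float(var[0]) if scalar else var

    @property
    def far_field_variance(self) -> float:
        """Correlation-scale variance limit far from the training set."""
        return 1.0 + 1.0 / self._one_Rinv_one

    def residual_norm(self) -> float:
        """‖R·w − (y − 1μ̂)‖ — should be ≲ 1e-8·‖y‖ for a healthy fit."""
        R = build_covariance(self.model.X, self.spec)
        return float(
            np.linalg.norm(R @ self.weights - (self.model.y - self.mu_hat))
        )

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        m = self.model
        l = self.spec.lengthscales
        lines = [
            "Atomic GPR results",
            "==================",
            f"property:           {m.property_tag}   atom: {m.atom_tag}",
            f"training points:    {m.n_train}",
            f"feature dimension:  {m.n_dim} "
            f"({int(m.cyclic_mask.sum())} cyclic)",
            f"kernel form:        {KERNEL_FORM} (unit: {m.unit})",
            f"nugget:             {self.spec.nugget:.3e}",
            f"concentrated logL:  {self.loglike:.6g}",
            f"mean (mu-hat):      {self.mu_hat:.8g}",
            f"process variance:   {self.sigma2_process:.6g}",
            f"lengthscale range:  [{l.min():.4g}, {l.max():.4g}] "
            f"(median {np.median(l):.4g})",
            f"far-field variance: {self.far_field_variance:.6g} (correlation scale)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        m = self.model
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kernel_form": KERNEL_FORM,
            "unit": m.unit,
            "property_tag": m.property_tag,
            "atom_tag": m.atom_tag,
            "nugget": self.spec.nugget,
            "lengthscales": self.spec.lengthscales.tolist(),
            "cyclic_mask": m.cyclic_mask.astype(int).tolist(),
            "mu_hat": self.mu_hat,
            "sigma2_process": self.sigma2_process,
            "loglike": self.loglike,
            "weights": self.weights.tolist(),
            "X_train": m.X.tolist(),
            "y_train": m.y.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GPRResults":
        data = json.loads(Path(path).read_text())
        major = str(data.get("schema_version", "")).split(".")[0]
        if major != MODEL_SCHEMA_VERSION.split(".")[0]:
            raise ValueError(
                f"unsupported model schema version {data.get('schema_version')!r}"
            )
        if data.get("kernel_form") != KERNEL_FORM:
            raise ValueError(f"unknown kernel form {data.get('kernel_form')!r}")
        model = AtomicGPR(
            np.array(data["X_train"]),
            np.array(data["y_train"]),
            cyclic_mask=np.array(data["cyclic_mask"], dtype=bool),
            nugget=data["nugget"],
            property_tag=data["property_tag"],
            atom_tag=data["atom_tag"],
            unit=data["unit"],
        )
        return cls(model, model.spec(np.array(data["lengthscales"])))
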