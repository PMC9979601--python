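"""Per-atom training-set construction by variance-based active learning.

The trajectory is split into disjoint training, sample and validation sets.
The training set starts from the min–max–mean initialization (frames holding
each feature's minimum, maximum and nearest-to-mean value, ≤ 3D points after
deduplication) plus a configurable number of random frames.  Each iteration
then (1) retrains the GP, (2) scores the validation set, (3) labels the
sample-pool points with the highest predictive variance and (4) moves the
survivors of scrubbing into the training set.  Points whose integration error
L(Ω) exceeds 0.001 a.u. are scrubbed — removed before they ever reach the
model, because a badly integrated label is noise the jitter-level nugget
cannot absorb.

Every atom owns its training set and sample pool; only the validation set is
shared, so per-atom runs parallelize trivially.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .gpr import AtomicGPR, GPRResults
from .pso import PSOConfig

__all__ = [
    "LabeledPoint",
    "DataSplit",
    "ALConfig",
    "min_max_mean_init",
    "scrub",
    "select_highest_variance",
    "ActiveLearner",
    "ALResult",
    "SCRUB_THRESHOLD",
]

#: Integration-error scrubbing threshold, atomic units.
SCRUB_THRESHOLD = 0.001


@dataclass
class LabeledPoint:
    """One labelled conformer for one atom: features, target value and the
    integration error L(Ω) of the label's numerical integration."""

    features: np.ndarray
    label: float
    integration_error: float = 0.0
    source_frame: int = -1

    def __post_init__(self) -> None:
        self.features = np.asarray(
            getattr(self.features, "values", self.features), dtype=float
        )
        if not np.isfinite(self.label):
            raise ValueError("label must be finite")
        if self.integration_error < 0:
            raise ValueError("integration error L(Omega) must be >= 0")


@dataclass
class DataSplit:
    """Disjoint frame-index sets over one trajectory."""

    training: np.ndarray
    sample: np.ndarray
    validation: np.ndarray

    def __post_init__(self) -> None:
        self.training = np.asarray(self.training, dtype=int)
        self.sample = np.asarray(self.sample, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        self.check_disjoint()

    def check_disjoint(self) -> None:
        t, s, v = set(self.training), set(self.sample), set(self.validation)
        if t & s or t & v or s & v:
            raise ValueError("training/sample/validation sets overlap")


def min_max_mean_init(features_all_frames: np.ndarray) -> np.ndarray:
    """Frames holding each dimension's min, max and nearest-to-mean value.

    Returns at most 3D distinct frame indices (duplicates removed), sorted
    ascending.  Nearest-to-mean ties resolve to the lower frame index, as do
    ties for the extrema (first occurrence).
    """
    F = np.atleast_2d(np.asarray(features_all_frames, dtype=float))
    if F.size == 0:
        raise ValueError("empty feature matrix")
    selected: set[int] = set()
    means = F.mean(axis=0)
    for d in range(F.shape[1]):
        col = F[:, d]
        selected.add(int(np.argmin(col)))
        selected.add(int(np.argmax(col)))
        selected.add(int(np.argmin(np.abs(col - means[d]))))
    return np.array(sorted(selected), dtype=int)


def scrub(
    points: Sequence[LabeledPoint], threshold: float = SCRUB_THRESHOLD
) -> list[LabeledPoint]:
    """Drop points whose integration error exceeds the threshold.

    The rule is "greater than", so a point sitting exactly at the threshold
    is kept.  Order is preserved.
    """
    if threshold <= 0:
        raise ValueError("scrub threshold must be positive")
    kept = [p for p in points if p.integration_error <= threshold]
    if points and not kept:
        warnings.warn("scrubbing removed every point", stacklevel=2)
    return kept


def select_highest_variance(
    results: GPRResults, sample_pool: np.ndarray, batch: int
) -> np.ndarray:
    """Indices (into the pool) of the ``batch`` highest-variance points.

    Returned in descending variance order, ties broken by the lower pool
    index.  Pool points far from the training set have high variance and are
    therefore preferred — exploration over exploitation.
    """
    pool = np.atleast_2d(np.asarray(sample_pool, dtype=float))
    if pool.shape[0] == 0:
        raise ValueError("sample pool is empty")
    if batch < 1:
        raise ValueError("batch must be >= 1")
    if batch > pool.shape[0]:
        warnings.warn(
            f"batch {batch} exceeds pool size {pool.shape[0]}; selecting all",
            stacklevel=2,
        )
        batch = pool.shape[0]
    variances = np.asarray(results.predict_variance(pool))
    order = np.lexsort((np.arange(pool.shape[0]), -variances))
    return order[:batch]


@dataclass(frozen=True)
class ALConfig:
    """Active-learning loop settings.

    Split-size defaults mirror the reference study conditions (100 000-point
    sample pool, 500 validation points, 1000 random frames added to the
    min–max–mean seed); they are scaled proportionally when the trajectory
    is smaller.
    """

    batch: int = 5
    iterations: int = 10
    random_extra: int = 1000
    sample_size: int = 100_000
    validation_size: int = 500
    scrub_threshold: float = SCRUB_THRESHOLD
    target_rmse: float | None = None
    nugget: float = 1e-8
    seed: int = 0
    pso: PSOConfig = field(default_factory=PSOConfig)
    reoptimize_every: int = 1  # PSO every k-th iteration, warm-started

    def replace(self, **kw) -> "ALConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ALResult:
    """Final model plus the machine-readable learning-curve record."""

    results: GPRResults
    curve: pd.DataFrame
    split: DataSplit
    status: str
    selected_frames: list[list[int]]

    def save_curve(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# learning-curve v1 (0-based frame counts)\n")
            self.curve.to_csv(fh, sep="\t", index=False)


class ActiveLearner:
    """Runs the retrain → score → select → label → scrub → extend loop for
    one atom's property model.

    Parameters
    ----------
    features
        n_frames × D feature matrix for the atom (whole trajectory).
    oracle
        Callable mapping a sequence of frame indices to
        :class:`LabeledPoint` lists — the labelling stage.  Failures on
        individual frames are skipped and logged.
    cyclic_mask
        Azimuthal-dimension mask for the kernel.
    config
        Loop settings.
    """

    def __init__(
        self,
        features: np.ndarray,
        oracle: Callable[[Sequence[int]], list[LabeledPoint]],
        cyclic_mask: np.ndarray | None = None,
        config: ALConfig | None = None,
        atom_tag: str = "atom0",
        property_tag: str = "iqa",
    ) -> None:
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.oracle = oracle
        self.cyclic_mask = (
            np.zeros(self.features.shape[1], dtype=bool)
            if cyclic_mask is None
            else np.asarray(cyclic_mask, dtype=bool)
        )
        self.config = config or ALConfig()
        self.atom_tag = atom_tag
        self.property_tag = property_tag

    # ------------------------------------------------------------------ #
    def make_split(self) -> DataSplit:
        """Initial training / sample / validation split (seeded)."""
        cfg = self.config
        n = self.features.shape[0]
        rng = np.random.default_rng(cfg.seed)
        train = set(min_max_mean_init(self.features).tolist())
        remaining = np.array([i for i in range(n) if i not in train])
        rng.shuffle(remaining)
        n_extra = min(cfg.random_extra, remaining.size)
        train |= set(remaining[:n_extra].tolist())
        remaining = remaining[n_extra:]
        n_sample, n_val = cfg.sample_size, cfg.validation_size
        if n_sample + n_val > remaining.size:
            # scale both proportionally to what the trajectory allows
            frac = remaining.size / (n_sample + n_val)
            n_val = max(1, int(round(n_val * frac)))
            n_sample = remaining.size - n_val
        return DataSplit(
            training=np.array(sorted(train)),
            sample=np.sort(remaining[:n_sample]),
            validation=np.sort(remaining[n_sample : n_sample + n_val]),
        )

    def _label(self, frames: Sequence[int]) -> list[LabeledPoint]:
        out: list[LabeledPoint] = []
        for f in frames:
            try:
                out.extend(self.oracle([int(f)]))
            except Exception as exc:  # single-point oracle failures are survivable
                warnings.warn(f"oracle failed on frame {f}: {exc}", stacklevel=2)
        return out

    def fit_points(
        self,
        points: list[LabeledPoint],
        seed: int,
        warm_start: np.ndarray | None = None,
        lengthscales: np.ndarray | None = None,
    ) -> GPRResults:
        X = np.array([p.features for p in points])
        y = np.array([p.label for p in points])
        model = AtomicGPR(
            X,
            y,
            cyclic_mask=self.cyclic_mask,
            nugget=self.config.nugget,
            property_tag=self.property_tag,
            atom_tag=self.atom_tag,
        )
        if lengthscales is not None:
            return model.fit(lengthscales=lengthscales)
        return model.fit(
            pso_config=self.config.pso.replace(seed=seed), warm_start=warm_start
        )

    # ------------------------------------------------------------------ #
    def run(self) -> ALResult:
        """Execute the loop and return the final model + learning curve."""
        cfg = self.config
        split = self.make_split()
        labelled = self._label(split.training)
        train_points = scrub(labelled, cfg.scrub_threshold)
        n_scrubbed = len(labelled) - len(train_points)
        val_points = self._label(split.validation)
        X_val = np.array([p.features for p in val_points])
        y_val = np.array([p.label for p in val_points])
        pool = list(split.sample)

        rows, selected_trace = [], []
        status = "max-iterations"
        warm = None
        results = self.fit_points(train_points, seed=cfg.seed, warm_start=None)
        warm = np.log10(results.spec.lengthscales)
        for it in range(cfg.iterations + 1):
            pred = results.predict(X_val)
            err = y_val - pred
            rows.append(
                {
                    "iteration": it,
                    "n_train": len(train_points),
                    "n_pool": len(pool),
                    "n_scrubbed_total": n_scrubbed,
                    "loglike": results.loglike,
                    "val_mae": float(np.mean(np.abs(err))),
                    "val_rmse": float(np.sqrt(np.mean(err**2))),
                    "val_max": float(np.max(np.abs(err))),
                }
            )
            if it == cfg.iterations:
                break
            if cfg.target_rmse is not None and rows[-1]["val_rmse"] <= cfg.target_rmse:
                status = "target-reached"
                break
            if cfg.batch == 0:
                status = "no-op"
                break
            if not pool:
                status = "pool exhausted"
                break
            picked = select_highest_variance(
                results, self.features[pool], min(cfg.batch, len(pool))
            )
            picked_frames = [pool[i] for i in picked]
            selected_trace.append(picked_frames)
            for i in sorted(picked, reverse=True):
                del pool[i]
            new_labelled = self._label(picked_frames)
            new_points = scrub(new_labelled, cfg.scrub_threshold)
            n_scrubbed += len(new_labelled) - len(new_points)
            train_points = train_points + new_points
            if cfg.reoptimize_every and (it + 1) % cfg.reoptimize_every == 0:
                results = self.fit_points(
                    train_points, seed=cfg.seed + it + 1, warm_start=warm
                )
                warm = np.log10(results.spec.lengthscales)
            else:
                results = self.fit_points(
                    train_points, seed=cfg.seed, lengthscales=results.spec.lengthscales
                )
        curve = pd.DataFrame(rows)
        return ALResult(
            results=results,
            curve=curve,
            split=split,
            status=status,
            selected_frames=selected_trace,
        )
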