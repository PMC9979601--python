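"""Prediction-error metrics, S-curves and cross-property MAE correlation.

The individual prediction error of a validation point is the signed
difference true − predicted; the total prediction error of a molecule is the
difference of the sums over atoms (per-atom errors may and do cancel).
Plotting absolute errors against the validation-set percentile gives the
S-curve, read as "x% of validation points have an error below E".

The MAE correlation compares per-atom mean absolute errors of two properties
(e.g. atomic energy vs atomic charge): a strong positive Pearson correlation
justifies re-using a training set selected by active learning on one property
to train models of the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KCAL_TO_KJ",
    "prediction_error",
    "total_prediction_error",
    "SCurve",
    "s_curve",
    "percentile_at_threshold",
    "mae_correlation",
    "MAECorrelation",
]

#: The one place the thermochemical calorie is pinned.
KCAL_TO_KJ = 4.184


def prediction_error(true_values, predicted_values):
    """Signed prediction error(s), true − predicted."""
    t = np.asarray(true_values, dtype=float)
    p = np.asarray(predicted_values, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise ValueError("inputs must be finite")
    out = t - p
    return float(out) if out.ndim == 0 else out


def total_prediction_error(
    true_per_atom: np.ndarray, predicted_per_atom: np.ndarray
) -> float:
    """Σᵢ f(xᵢ*) − Σᵢ f̂(xᵢ*) over the atoms of one molecule.

    Equals the sum of the per-atom signed errors, so cancellation between
    atoms is allowed and expected.
    """
    t = np.asarray(true_per_atom, dtype=float)
    p = np.asarray(predicted_per_atom, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"atom-set mismatch: {t.shape} vs {p.shape}")
    return float(np.sum(t) - np.sum(p))


@dataclass
class SCurve:
    """Sorted absolute errors with their cumulative percentiles."""

    errors: np.ndarray       # ascending absolute errors
    percentiles: np.ndarray  # strictly increasing, in (0, 100]
    property_tag: str = ""
    atom_tag: str = ""
    unit: str = "kJ/mol"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                f"abs_error_{self.unit}": self.errors,
                "percentile": self.percentiles,
            }
        )


def s_curve(
    abs_errors: np.ndarray,
    property_tag: str = "",
    atom_tag: str = "",
    unit: str = "kJ/mol",
) -> SCurve:
    """Cumulative-percentile curve of absolute prediction errors.

    Input ordering is irrelevant; point k (1-based) of the sorted errors is
    assigned percentile 100·k/n.
    """
    e = np.sort(np.abs(np.asarray(abs_errors, dtype=float).ravel()))
    if e.size == 0:
        raise ValueError("need at least one error")
    pct = 100.0 * np.arange(1, e.size + 1) / e.size
    return SCurve(e, pct, property_tag, atom_tag, unit)


def percentile_at_threshold(curve: SCurve, threshold: float) -> float:
    """Percent of validation points with |error| ≤ threshold.

    Inclusive, right-continuous step convention; monotone non-decreasing in
    the threshold.
    """
    return float(100.0 * np.count_nonzero(curve.errors <= threshold) / curve.errors.size)


@dataclass
class MAECorrelation:
    """Pearson correlation between two properties' per-atom MAEs."""

    r: float
    r_squared: float
    table: pd.DataFrame

    def __str__(self) -> str:
        return (
            f"Pearson r = {self.r:.4f} (r² = {self.r_squared:.4f}) over "
            f"{len(self.table)} atoms"
        )


def mae_correlation(
    mae_a: dict[str, float] | pd.Series,
    mae_b: dict[str, float] | pd.Series,
    label_a: str = "property_a",
    label_b: str = "property_b",
) -> MAECorrelation:
    """Correlate two per-atom MAE series paired by atom tag.

    Needs ≥ 3 common atoms and nonzero variance in both series; returns the
    Pearson r, r² and the paired table (for plotting).
    """
    a = pd.Series(mae_a, dtype=float)
    b = pd.Series(mae_b, dtype=float)
    common = sorted(set(a.index) & set(b.index))
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired atoms, got {len(common)}")
    av, bv = a[common].to_numpy(), b[common].to_numpy()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    r = float(stats.pearsonr(av, bv).statistic)
    table = pd.DataFrame({"atom": common, label_a: av, label_b: bv})
    return MAECorrelation(r=r, r_squared=r * r, table=table)
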