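"""Matplotlib renderings of the standard diagnostics.

Figures are optional conveniences; every quantity they show is available in
the delimited report tables.
"""

from __future__ import annotations

import numpy as np

from .validation import SCurve

__all__ = ["plot_s_curve", "plot_interaction_heatmap", "plot_learning_curve"]


def plot_s_curve(curves: SCurve | list[SCurve], ax=None):
    """Percentile vs absolute error on a log-x axis, one line per curve."""
    import matplotlib.pyplot as plt

    if isinstance(curves, SCurve):
        curves = [curves]
    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        label = " ".join(t for t in (curve.property_tag, curve.atom_tag) if t)
        ax.plot(curve.errors, curve.percentiles, label=label or None)
    ax.set_xscale("log")
    ax.set_xlabel(f"absolute prediction error ({curves[0].unit})")
    ax.set_ylabel("percentile of validation set")
    ax.set_ylim(0, 100)
    if any(c.property_tag or c.atom_tag for c in curves):
        ax.legend(fontsize="small")
    return ax


def plot_interaction_heatmap(rmse: np.ndarray, log: bool = True, ax=None):
    """Per-atom-pair interaction RMSE; colour may be log-scaled, the stored
    values stay linear."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots()
    rmse = np.asarray(rmse, dtype=float)
    norm = None
    if log:
        positive = rmse[rmse > 0]
        if positive.size:
            norm = LogNorm(vmin=positive.min(), vmax=rmse.max())
    image = ax.imshow(rmse, norm=norm, cmap="viridis", origin="lower")
    ax.set_xlabel("monomer-2 atom index")
    ax.set_ylabel("monomer-1 atom index")
    ax.figure.colorbar(image, ax=ax, label="interaction RMSE (kJ/mol)")
    return ax


def plot_learning_curve(curve, ax=None):
    """Validation MAE/RMSE vs active-learning iteration."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["iteration"], curve["val_rmse"], marker="o", label="RMSE")
    ax.plot(curve["iteration"], curve["val_mae"], marker="s", label="MAE")
    ax.set_xlabel("active-learning iteration")
    ax.set_ylabel("validation error")
    ax.legend()
    return ax
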