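"""Figures: shaded transform-pair correlation heat maps and per-pair
scatter plots with fitted curves on raw and linearized axes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .models import ModelFit
from .screen import CorrelationMatrixSet, Thresholds, TRANSFORM_PAIRS

__all__ = ["plot_correlation_heatmap", "plot_fit"]

_TRANSFORM_TITLES = {
    "x.y": "(x, y)",
    "lnx.y": "(ln x, y)",
    "x.lny": "(x, ln y)",
    "lnx.lny": "(ln x, ln y)",
}


def plot_correlation_heatmap(
    cms: CorrelationMatrixSet,
    path: str | Path,
    thresholds: Thresholds | None = None,
) -> Path:
    """Four-panel heat map of the transform-pair matrices; entries outside
    the shading band (|r| <= shade threshold) are masked out, mimicking a
    shaded-matrix display."""
    th = thresholds if thresholds is not None else Thresholds()
    fig, axes = plt.subplots(2, 2, figsize=(14, 12))
    for ax, key in zip(axes.ravel(), TRANSFORM_PAIRS):
        r = cms.r[key]
        mask = r.abs() <= th.shade
        sns.heatmap(
            r,
            mask=mask,
            vmin=-1,
            vmax=1,
            cmap="RdBu_r",
            annot=True,
            fmt=".2f",
            cbar=False,
            ax=ax,
            linewidths=0.5,
            linecolor="lightgrey",
        )
        ax.set_title(f"{cms.cell_type}  {_TRANSFORM_TITLES[key]}")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_fit(
    x: np.ndarray,
    y: np.ndarray,
    fit: ModelFit,
    path: str | Path,
    x_label: str = "x",
    y_label: str = "y",
) -> Path:
    """Scatter with the fitted curve on raw axes and, for nonlinear forms,
    the linearized scatter with its regression line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_panels = 1 if fit.form == "linear" else 2
    fig, axes = plt.subplots(1, n_panels, figsize=(6 * n_panels, 5), squeeze=False)
    ax = axes[0, 0]
    ax.scatter(x, y, s=12, alpha=0.6)
    grid = np.linspace(x.min(), x.max(), 200)
    if fit.form in ("logarithmic", "power"):
        grid = grid[grid > 0]
    ax.plot(grid, fit.predict(grid), color="crimson")
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    ax.set_title(f"{fit.form}: r = {fit.r_linearized:.2f} (linearized)")
    if n_panels == 2:
        ax2 = axes[0, 1]
        u = np.log(x) if fit.form in ("logarithmic", "power") else x
        v = np.log(y) if fit.form in ("exponential", "power") else y
        ax2.scatter(u, v, s=12, alpha=0.6)
        coeff = np.polyfit(u, v, 1)
        ugrid = np.linspace(u.min(), u.max(), 2)
        ax2.plot(ugrid, np.polyval(coeff, ugrid), color="crimson")
        ax2.set_xlabel(f"ln {x_label}" if fit.form in ("logarithmic", "power") else x_label)
        ax2.set_ylabel(f"ln {y_label}" if fit.form in ("exponential", "power") else y_label)
        ax2.set_title("linearized coordinates")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
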