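"""Graphical diagnostics: distribution, density, scatter, and deviance plots.

Every plot function also returns the plain table behind the figure, so the
visual claims (which points are flagged, how the densities compare) can be
asserted without parsing images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .datasets import BINARY
from .ppc import ReplicateMatrix, ReplicateSummary, deviance_residuals


@dataclass
class PlotSpec:
    kind: str = "distribution"
    level: float = 0.95
    path: str | Path | None = None
    in_color: str = "tab:blue"
    out_color: str = "tab:red"
    bound_color: str = "0.6"
    fmt: str = "png"

    def resolve_path(self, default: str) -> Path:
        if self.path is not None:
            return Path(self.path)
        return Path(f"{default}.{self.fmt}")


def distribution_plot(summary: ReplicateSummary, spec: PlotSpec | None = None):
    """Observed points with their per-point predictive interval bounds, in
    ascending order of the replicate mean; points outside their interval are
    flagged in the alternate color.

    Returns ``(table, path)`` where the table carries the plotting order,
    bounds, and the flag for every point.
    """
    spec = spec or PlotSpec(kind="distribution")
    order = np.argsort(summary.center, kind="stable")
    table = pd.DataFrame(
        {
            "rank": np.arange(len(order)),
            "obs": summary.obs[order],
            "center": summary.center[order],
            "lower": summary.lower[order],
            "upper": summary.upper[order],
            "flagged": ~summary.covered[order],
        }
    )
    path = spec.resolve_path("distribution_plot")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(table["rank"], table["lower"], color=spec.bound_color, lw=0.8)
    ax.plot(table["rank"], table["upper"], color=spec.bound_color, lw=0.8)
    inside = ~table["flagged"].to_numpy()
    ax.scatter(
        table["rank"][inside], table["obs"][inside],
        s=6, color=spec.in_color, label="inside interval",
    )
    ax.scatter(
        table["rank"][~inside], table["obs"][~inside],
        s=10, color=spec.out_color, label="outside interval",
    )
    ax.set_xlabel("observed points, ordered by replicate mean")
    ax.set_ylabel("value")
    ax.set_title(f"{summary.level:.0%} posterior predictive intervals")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return table, path


def comparison_plots(
    rep: ReplicateMatrix,
    covariate: np.ndarray,
    spec: PlotSpec | None = None,
    max_panels: int = 5,
    grid_size: int = 256,
):
    """Density overlay and observed-vs-replicate scatter panels.

    The density table holds a shared evaluation grid with the observed
    kernel density and one column per replicate set; the scatter panels show
    the observed values against the covariate next to each of the first
    ``max_panels`` imputations.

    Returns ``(density_table, density_path, scatter_path)``.
    """
    spec = spec or PlotSpec(kind="density")
    covariate = np.asarray(covariate, dtype=float)
    if rep.m < 1:
        raise ValueError("need at least one replicate")
    pooled = np.concatenate([rep.obs, rep.draws.ravel()])
    lo, hi = pooled.min(), pooled.max()
    pad = 0.1 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)

    def _kde(sample):
        if np.ptp(sample) == 0:  # degenerate sample: a spike, no bandwidth
            return np.full_like(grid, np.nan)
        return gaussian_kde(sample, bw_method="silverman")(grid)

    dens = {"grid": grid, "observed": _kde(rep.obs)}
    n_panels = min(rep.m, max_panels)
    for i in range(n_panels):
        dens[f"imp_{i + 1}"] = _kde(rep.draws[:, i])
    table = pd.DataFrame(dens)

    density_path = spec.resolve_path("density_plot")
    if spec.path is not None:
        scatter_out = density_path.with_name(
            density_path.stem + "_scatter" + density_path.suffix
        )
    else:
        scatter_out = Path(f"scatter_plot.{spec.fmt}")
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    for i in range(n_panels):
        ax.plot(grid, table[f"imp_{i + 1}"], color=spec.out_color, lw=0.7, alpha=0.6)
    ax.plot(grid, table["observed"], color=spec.in_color, lw=1.8, label="observed")
    ax.set_xlabel("value")
    ax.set_ylabel("density")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(density_path)
    plt.close(fig)

    scatter_path = scatter_out
    fig, axes = plt.subplots(
        1, n_panels + 1, figsize=(2.2 * (n_panels + 1), 2.6),
        sharex=True, sharey=True,
    )
    axes = np.atleast_1d(axes)
    axes[0].scatter(covariate, rep.obs, s=4, color=spec.in_color)
    axes[0].set_title("0 (observed)", fontsize=8)
    for i in range(n_panels):
        axes[i + 1].scatter(covariate, rep.obs, s=4, color=spec.in_color, alpha=0.4)
        axes[i + 1].scatter(covariate, rep.draws[:, i], s=4, color=spec.out_color)
        axes[i + 1].set_title(str(i + 1), fontsize=8)
    fig.tight_layout()
    fig.savefig(scatter_path)
    plt.close(fig)
    return table, density_path, scatter_path


def deviance_plot(rep: ReplicateMatrix, spec: PlotSpec | None = None):
    """Signed deviance residuals of a binary target against the point index
    (ordered by replicate probability). Returns ``(table, path)``."""
    spec = spec or PlotSpec(kind="deviance")
    if rep.kind != BINARY:
        raise ValueError("deviance plot requires a binary replicate matrix")
    resid = deviance_residuals(rep)
    p = rep.draws.mean(axis=1)
    order = np.argsort(p, kind="stable")
    table = pd.DataFrame(
        {
            "rank": np.arange(len(order)),
            "obs": rep.obs[order],
            "p_replicate": p[order],
            "deviance_residual": resid[order],
        }
    )
    path = spec.resolve_path("deviance_plot")
    fig, ax = plt.subplots(figsize=(6.5, 4))
    colors = np.where(table["obs"] > 0.5, spec.in_color, spec.out_color)
    ax.scatter(table["rank"], table["deviance_residual"], s=6, c=colors)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("observed points, ordered by replicate probability")
    ax.set_ylabel("deviance residual")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return table, path
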