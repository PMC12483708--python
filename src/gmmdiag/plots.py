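"""Plot renderers for draws, diagnostics and trajectories.

All functions return a matplotlib Figure; callers decide how to save.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import (DiagnosticsConfig, di_series, moving_average,
                          moving_sd)
from .summaries import midrange_band


def traceplot_pi(draws, figsize=(9, 3)):
    """Traceplot of the class probabilities, one panel per chain."""
    pi = draws.pi_draws()
    n_chains, n_iter, K = pi.shape
    fig, axes = plt.subplots(1, n_chains, figsize=figsize, sharey=True,
                             squeeze=False)
    for c in range(n_chains):
        ax = axes[0, c]
        for k in range(K):
            ax.plot(pi[c, :, k], lw=0.6, label=f"$\\pi_{{{k + 1}}}$")
        ax.set_title(f"chain {c + 1}", fontsize=8)
        ax.set_ylim(0, 1)
    axes[0, 0].set_ylabel("class probability")
    axes[0, -1].legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    return fig


def moving_stats_panel(pi_min, h: int = 10, ax=None):
    """Moving average and moving SD of the smallest class probability."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2))
    x = np.arange(h - 1, len(pi_min))
    ax.plot(x, moving_average(pi_min, h=h), lw=0.8, label="moving mean")
    ax.plot(x, moving_sd(pi_min, h=h), lw=0.8, label="moving SD")
    ax.set_ylabel(r"$\pi_{\min}$ moving stats")
    ax.legend(fontsize=7)
    return ax.figure


def di_panel(di, chain: int = 0, ax=None):
    """Distinguishability index traces for all class pairs of one chain."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2))
    for p, (k, l) in enumerate(di.pairs):
        ax.plot(di.values[chain, p], lw=0.6, label=f"DI({k + 1},{l + 1})")
    ax.set_ylim(0, 100)
    ax.set_ylabel("DI")
    ax.legend(fontsize=7, ncol=3)
    return ax.figure


def aligned_diagnostic_figure(draws, data, config: DiagnosticsConfig | None = None,
                              chain: int = 0, di=None):
    """Vertically aligned traceplot / moving statistics / DI panels."""
    cfg = config or DiagnosticsConfig()
    pi = draws.pi_draws()[chain]
    pi_min = pi.min(axis=1)
    if di is None:
        di = di_series(draws, data)
    fig, axes = plt.subplots(3, 1, figsize=(9, 6), sharex=True)
    for k in range(pi.shape[1]):
        axes[0].plot(pi[:, k], lw=0.6, label=f"$\\pi_{{{k + 1}}}$")
    axes[0].set_ylabel("class probability")
    axes[0].set_ylim(0, 1)
    axes[0].legend(fontsize=7)
    moving_stats_panel(pi_min, h=cfg.window, ax=axes[1])
    di_panel(di, chain=chain, ax=axes[2])
    axes[2].set_xlabel("iteration")
    fig.tight_layout()
    return fig


def trajectory_plot(params, data, coverage: float = 0.5, grid=None):
    """Class mean trajectories with shaded mid-range bands and boxplots
    of the observed responses per occasion."""
    df = data.to_frame()
    times = np.sort(df["time"].unique())
    if grid is None:
        grid = np.linspace(times.min(), times.max(), 50)
    fig, ax = plt.subplots(figsize=(7, 5))
    # observed-score boxplots at each occasion
    groups = [df.loc[df["time"] == t, "y"].to_numpy() for t in times]
    width = 0.08 * (times.max() - times.min() + 1)
    ax.boxplot(groups, positions=times, widths=width, manage_ticks=False,
               medianprops={"color": "gray"},
               boxprops={"color": "gray"}, whiskerprops={"color": "gray"},
               capprops={"color": "gray"}, flierprops={"markersize": 2})
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for k, cp in enumerate(params.classes):
        mean = cp.mean(grid)
        band = np.array([midrange_band(cp, t, coverage) for t in grid])
        col = colors[k % len(colors)]
        ax.plot(grid, mean, color=col,
                label=f"class {k + 1} ($\\pi$={params.pi[k]:.2f})")
        ax.fill_between(grid, band[:, 0], band[:, 1], color=col, alpha=0.2)
    ax.set_xlabel("time")
    ax.set_ylabel("response")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
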