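"""Figure rendering for diagnostics and effect summaries.

All figures are views over CSV tables written alongside them; nothing is
computed here that is not also available as data.  The Agg backend is forced
so rendering works headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .panel import STAGES  # noqa: E402

__all__ = ["plot_ppc_monthly", "plot_pit_hist", "plot_zero_heatmaps",
           "plot_seasonal_curves", "plot_year_effect"]


def plot_ppc_monthly(ppc: pd.DataFrame, path) -> None:
    """Observed vs posterior-predictive monthly means, one panel per stage."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, stage in zip(axes, STAGES):
        sub = ppc[ppc["stage"] == stage].sort_values("month")
        ax.fill_between(sub["month"], sub["lo"], sub["hi"], alpha=0.3,
                        color="tab:blue", label="95% predictive band")
        ax.plot(sub["month"], sub["predicted_mean"], color="tab:blue",
                label="predictive mean")
        ax.plot(sub["month"], sub["observed_mean"], color="black",
                marker="o", ms=3, label="observed mean")
        ax.set_title(stage)
        ax.set_xlabel("month")
    axes[0].set_ylabel("mean monthly count")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pit_hist(pit, path) -> None:
    """Histogram of randomised PIT values with the uniform reference line."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = 0.5 * (pit.hist_edges[:-1] + pit.hist_edges[1:])
    width = pit.hist_edges[1] - pit.hist_edges[0]
    density = pit.hist_counts / (pit.pit_values.size * width)
    ax.bar(centers, density, width=width * 0.95, color="tab:blue")
    ax.axhline(1.0, color="black", ls="--", lw=1)
    ax.set_xlabel("PIT value")
    ax.set_ylabel("density")
    ax.set_title(f"randomised PIT (KS p = {pit.ks_p:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_zero_heatmaps(profile, path) -> None:
    """Habitat x month zero-proportion heatmaps, one panel per stage."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.2))
    for ax, stage in zip(axes, STAGES):
        tab = profile.by_habitat_month[stage]
        im = ax.imshow(tab.to_numpy(), vmin=0, vmax=1, aspect="auto",
                       cmap="viridis")
        ax.set_xticks(range(len(tab.columns)), tab.columns)
        ax.set_yticks(range(len(tab.index)), tab.index)
        ax.set_title(f"{stage}: zero proportion")
        ax.set_xlabel("month")
    fig.colorbar(im, ax=axes, fraction=0.02)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_seasonal_curves(curves, path) -> None:
    """Harmonic seasonal effects on the log scale, peaks marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        line, = ax.plot(c.months, c.values, marker="o", ms=3, label=c.stage)
        ax.axvline(c.peak_month, color=line.get_color(), ls=":", lw=1)
    ax.set_xlabel("month")
    ax.set_ylabel("seasonal effect (log scale)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_year_effect(series: pd.DataFrame, path) -> None:
    """Shared year-effect trajectory with credible band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(series["year"], series["ci_low"], series["ci_high"],
                    alpha=0.3, color="tab:blue")
    ax.plot(series["year"], series["mean"], color="tab:blue", marker="o")
    ax.axhline(0.0, color="black", lw=1, ls="--")
    flagged = series[series["excludes_zero"]]
    if len(flagged):
        ax.scatter(flagged["year"], flagged["mean"], color="tab:red",
                   zorder=3, label="CI excludes 0")
        ax.legend()
    ax.set_xlabel("year")
    ax.set_ylabel("shared year effect")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
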