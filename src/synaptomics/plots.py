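"""Plotting helpers for quadrant maps and density comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .translation import kde_density


def quadrant_scatter(matched: pd.DataFrame, ax=None, highlight: dict | None = None,
                     xlabel: str = "transcript log2 FC", ylabel: str = "protein log2 FC"):
    """Scatter of transcript vs protein log2 fold changes with quadrant axes.

    ``highlight`` maps a label to a list of gene IDs drawn in color on top
    of the grey background cloud.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(matched["rna_log2fc"], matched["prot_log2fc"], s=6, c="0.7",
               linewidths=0, label=None, rasterized=True)
    if highlight:
        for (label, genes), color in zip(highlight.items(),
                                         ("crimson", "royalblue", "seagreen", "orange")):
            sub = matched.loc[matched.index.intersection(pd.Index(genes))]
            ax.scatter(sub["rna_log2fc"], sub["prot_log2fc"], s=10, c=color,
                       linewidths=0, label=label)
        ax.legend(frameon=False, fontsize=8)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    lim = max(np.abs(ax.get_xlim()).max(), np.abs(ax.get_ylim()).max())
    for q, (x, y) in {"Q1": (1, 1), "Q2": (1, -1), "Q3": (-1, -1), "Q4": (-1, 1)}.items():
        ax.annotate(q, (0.92 * lim * x, 0.92 * lim * y), ha="center", va="center",
                    fontsize=9, color="0.4")
    return ax


def density_plot(values_by_group: dict, ax=None, log_transform: bool = True,
                 xlabel: str = "log2 TE"):
    """Overlaid Gaussian kernel density curves, one per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for label, values in values_by_group.items():
        grid, heights = kde_density(values, log_transform=log_transform)
        ax.plot(grid, heights, label=label)
        ax.fill_between(grid, heights, alpha=0.15)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    return ax
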