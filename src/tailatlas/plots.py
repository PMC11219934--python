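"""Figure helpers (matplotlib, non-interactive backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .quantify import TailHistogram


def plot_tail_histograms(
    histograms: dict[str, TailHistogram], path: str | Path, title: str = ""
) -> None:
    """Overlayed per-sample tail-length histograms (1 nt bins)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, h in histograms.items():
        ax.plot(h.bins, h.heights, lw=0.8, label=label)
    ax.set_xlabel("poly(A) tail length (nt)")
    ax.set_ylabel(f"transcripts / {next(iter(histograms.values())).mode} normalizer")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_expression_scatter(
    normalized: pd.DataFrame,
    sample_x: str,
    sample_y: str,
    de: pd.DataFrame,
    path: str | Path,
) -> None:
    """log-log scatter of normalized counts with up/down genes highlighted."""
    fig, ax = plt.subplots(figsize=(5, 5))
    x = normalized[sample_x] + 0.5
    y = normalized[sample_y] + 0.5
    colors = de.set_index("gene").direction.reindex(normalized.index).fillna("unchanged")
    palette = {"up": "tab:red", "down": "tab:blue", "unchanged": "0.6"}
    for direction, color in palette.items():
        sel = colors == direction
        ax.scatter(x[sel], y[sel], s=8, c=color, label=f"{direction} ({int(sel.sum())})")
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lims, lims, "k--", lw=0.5)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"{sample_x} (normalized + 0.5)")
    ax.set_ylabel(f"{sample_y} (normalized + 0.5)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_te_groups(grouping, path: str | Path) -> None:
    """Box plot of log2 TE by tail-length group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = sorted(grouping.groups["bin"].unique())
    data = [grouping.groups.loc[grouping.groups["bin"] == b, "log2_te"] for b in bins]
    labels = [
        f"{grouping.edges[b]:.0f}-{grouping.edges[b + 1]:.0f} nt\n(n={len(d)})"
        for b, d in zip(bins, data)
    ]
    ax.boxplot(data, labels=labels)
    ax.set_ylabel("log2 TE")
    ax.set_xlabel("gene group by geometric-mean tail length")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
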