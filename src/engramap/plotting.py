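"""PNG heat maps for density, CV and q-value matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .binstats import CODE_ALL_LOWER, CODE_NONE, CODE_OTHER, BinStatResult


def heatmap(
    values: np.ndarray,
    path: str | Path,
    title: str = "",
    mask: np.ndarray | None = None,
    cmap: str = "viridis",
) -> None:
    """Write a per-bin heat map; masked / NaN bins are drawn light gray."""
    data = np.array(values, dtype=float)
    if mask is not None:
        data = np.where(mask, data, np.nan)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.9")
    im = ax.imshow(np.ma.masked_invalid(data), cmap=cm, origin="lower")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("bin column")
    ax.set_ylabel("bin row")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def q_matrix_plot(result: BinStatResult, path: str | Path, title: str = "q-value matrix") -> None:
    """q matrix with significant bins colored by their classification code.

    Red = all treatments below the reference; blue/yellow/... = single-
    treatment-specific bins (one color per treatment label); purple = other
    significant pattern; grayscale elsewhere shows the q value itself.
    """
    specific = sorted(
        {c for c in result.codes.ravel() if c not in (CODE_NONE, CODE_ALL_LOWER, CODE_OTHER)}
    )
    palette = {CODE_ALL_LOWER: "#d62728", CODE_OTHER: "#9467bd"}
    cycle = ["#1f77b4", "#ffd92f", "#2ca02c", "#e377c2", "#17becf"]
    for i, code in enumerate(specific):
        palette[code] = cycle[i % len(cycle)]

    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    cm = plt.get_cmap("Greys").copy()
    cm.set_bad("1.0")
    im = ax.imshow(
        np.ma.masked_invalid(1.0 - result.q), cmap=cm, origin="lower", vmin=0, vmax=1
    )
    fig.colorbar(im, ax=ax, shrink=0.8, label="1 - q")
    for r, c in zip(*np.nonzero(result.sig_mask)):
        color = palette.get(result.codes[r, c], "#d62728")
        ax.add_patch(
            plt.Rectangle((c - 0.5, r - 0.5), 1, 1, facecolor=color, edgecolor="k", lw=0.5)
        )
    handles = [
        plt.Rectangle((0, 0), 1, 1, facecolor=col, edgecolor="k", label=code)
        for code, col in palette.items()
        if code == CODE_ALL_LOWER or code in specific or code == CODE_OTHER
    ]
    if handles:
        ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.25, 1), fontsize=8)
    ax.set_title(f"{title} (q < {result.q_threshold:g} colored)")
    ax.set_xlabel("bin column")
    ax.set_ylabel("bin row")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
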