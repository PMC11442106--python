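"""Per-chromosome diagnostic panels for a fitted scan.

Six stacked panels per chromosome: SNP-index of the low bulk, SNP-index of
the high bulk, the two superimposed, the ΔSNP-index with 95/99% null bands,
the window mean −log10 P, and the directional QTL variant count (positive-Δ
counts upward, negative-Δ counts downward, with the calling threshold).
Variants whose SNP-index is exactly 0 are drawn in a distinct colour in the
index panels, since their clustering in one bulk is half of the region-
calling rule.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_MB = 1e6
ZERO_LOW_COLOR = "darkgreen"
ZERO_HIGH_COLOR = "darkorange"


def _index_panel(ax, pos, idx, zero_mask, wpos, wmean, color, zero_color, label):
    ax.scatter(pos[~zero_mask], idx[~zero_mask], s=2, color="0.6", rasterized=True)
    ax.scatter(pos[zero_mask], idx[zero_mask], s=4, color=zero_color, rasterized=True)
    ax.plot(wpos, wmean, color=color, lw=1.2)
    ax.set_ylabel(label)
    ax.set_ylim(-0.02, max(0.5, np.nanmax(idx) if idx.size else 0.5) + 0.02)


def plot_chromosome(
    windows: pd.DataFrame,
    scored: pd.DataFrame,
    thresholds: Mapping[float, tuple[float, float]],
    chrom: str,
    out_path: str | Path | None = None,
    count_threshold: int = 20,
):
    """Render the six-panel figure for one chromosome; returns the Figure."""
    wsub = windows.loc[windows["chrom"] == chrom]
    ssub = scored.loc[scored["chrom"] == chrom] if len(scored) else scored
    fig, axes = plt.subplots(6, 1, figsize=(10, 12), sharex=True)
    pos = ssub["pos"].to_numpy() / _MB if len(ssub) else np.array([])
    wpos = (wsub["start"].to_numpy() + wsub["end"].to_numpy()) / 2 / _MB

    if len(ssub):
        idx_low = ssub["idx_low"].to_numpy()
        idx_high = ssub["idx_high"].to_numpy()
        zlow = ssub["zero_in_low"].to_numpy().astype(bool)
        zhigh = ssub["zero_in_high"].to_numpy().astype(bool)
        delta = ssub["delta"].to_numpy()
    else:
        idx_low = idx_high = delta = np.array([])
        zlow = zhigh = np.array([], dtype=bool)

    _index_panel(axes[0], pos, idx_low, zlow, wpos,
                 wsub["mean_idx_low"].to_numpy(), "green", ZERO_LOW_COLOR,
                 "SNP-index\nlow bulk")
    _index_panel(axes[1], pos, idx_high, zhigh, wpos,
                 wsub["mean_idx_high"].to_numpy(), "red", ZERO_HIGH_COLOR,
                 "SNP-index\nhigh bulk")
    axes[2].plot(wpos, wsub["mean_idx_low"].to_numpy(), color="green", lw=1.2,
                 label="low bulk")
    axes[2].plot(wpos, wsub["mean_idx_high"].to_numpy(), color="red", lw=1.2,
                 label="high bulk")
    axes[2].set_ylabel("SNP-index\nsuperimposed")
    axes[2].legend(loc="upper right", fontsize=7)

    ax = axes[3]
    ax.scatter(pos, delta, s=2, color="0.6", rasterized=True)
    ax.plot(wpos, wsub["mean_delta"].to_numpy(), color="blue", lw=1.2)
    for level, color in ((0.95, "orange"), (0.99, "red")):
        if level in thresholds:
            lo, hi = thresholds[level]
            ax.axhline(lo, color=color, lw=0.8)
            ax.axhline(hi, color=color, lw=0.8)
    ax.axhline(0, color="0.3", lw=0.5)
    ax.set_ylabel("ΔSNP-index")

    axes[4].plot(wpos, wsub["mean_neglog10p"].to_numpy(), color="blue", lw=1.2)
    axes[4].set_ylabel("window\n$-\\log_{10}P$")

    ax = axes[5]
    width = (wsub["end"].to_numpy() - wsub["start"].to_numpy() + 1) / _MB * 0.2
    ax.bar(wpos, wsub["count95_up"].to_numpy(), width=width, color="orange")
    ax.bar(wpos, -wsub["count95_down"].to_numpy(), width=width, color="orange")
    ax.scatter(wpos, wsub["count99_up"].to_numpy(), s=3, color="red")
    ax.scatter(wpos, -wsub["count99_down"].to_numpy(), s=3, color="red")
    ax.axhline(count_threshold, color="red", lw=0.8)
    ax.axhline(-count_threshold, color="red", lw=0.8)
    ax.axhline(0, color="0.3", lw=0.5)
    ax.set_ylabel("QTL variant\ncount")
    ax.set_xlabel(f"{chrom} position (Mb)")

    fig.suptitle(chrom)
    fig.align_ylabels(axes)
    fig.tight_layout(rect=(0, 0, 1, 0.98))
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
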