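"""Karyotype and index plots.

Numeric reports are the contract; these figures are conveniences mirroring
the standard presentation: per-chromosome Ratio × expected-ploidy scatter
with a stepped integer copy-number line, and a per-site index scatter with
the windowed mean line and horizontal guides at the 0.2/0.8 classification
thresholds.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _panel_grid(n: int):
    ncols = min(4, max(1, n))
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows),
                             squeeze=False, sharey=True)
    return fig, [ax for row in axes for ax in row]


def plot_karyotype(result, layout, path: str | Path) -> Path:
    """One panel per chromosome: ratio × ploidy scatter + stepped CN line."""
    chroms = [k.chrom for k in result.chromosomes]
    fig, axes = _panel_grid(len(chroms))
    by_chrom = {k.chrom: k for k in result.chromosomes}
    bins = result.track.bins
    for ax, chrom in zip(axes, chroms):
        k = by_chrom[chrom]
        sub = bins[(bins["chrom"] == chrom) & ~bins["masked"] & ~bins["ratio"].isna()]
        ax.plot(sub["start"] / 1e6, sub["ratio"] * k.ploidy,
                ".", ms=2, color="tab:gray", alpha=0.6)
        for seg in k.segments:
            if seg.copy_number is None:
                continue
            ax.plot([seg.start / 1e6, seg.end / 1e6],
                    [seg.copy_number, seg.copy_number], "k-", lw=2)
        ax.set_title(f"{chrom} (CN {k.copy_number})", fontsize=9)
        ax.set_ylim(bottom=0)
    for ax in axes[len(chroms):]:
        ax.set_visible(False)
    fig.supxlabel("position (Mb)")
    fig.supylabel("Ratio × expected ploidy")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_index(sites: pd.DataFrame, windows: pd.DataFrame, path: str | Path,
               low: float = 0.2, high: float = 0.8) -> Path:
    """Per-chromosome index scatter, windowed mean line, 0.2/0.8 guides."""
    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = _panel_grid(len(chroms))
    for ax, chrom in zip(axes, chroms):
        s = sites[sites["chrom"] == chrom]
        w = windows[windows["chrom"] == chrom]
        ax.plot(s["pos"] / 1e6, s["index"], ".", ms=1.5, color="tab:gray", alpha=0.4)
        ax.plot(w["mid"] / 1e6, w["mean_index"], "k-", lw=1.2)
        for y in (low, high):
            ax.axhline(y, color="red", ls=":", lw=1)
        ax.set_ylim(-0.05, 1.05)
        ax.set_title(chrom, fontsize=9)
    for ax in axes[len(chroms):]:
        ax.set_visible(False)
    fig.supxlabel("position (Mb)")
    fig.supylabel("index")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
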