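"""Per-chromosome z-score profile plots.

One panel per chromosome; each vertical bar is one analysis bin. Bins
inside a called duplication are green, deletions red, everything else
grey. The +/-threshold reference interval is drawn as dashed lines.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import BinGrid
from .cna_calling import AberrationCall, DEFAULT_Z_THRESHOLD

__all__ = ["plot_zprofile", "plot_zprofile_tsv"]

_COL_NEUTRAL = "#9a9a9a"
_COL_DUP = "#2e8b57"
_COL_DEL = "#c0392b"


def plot_zprofile(
    z: np.ndarray,
    grid: BinGrid,
    calls: list[AberrationCall] = (),
    path: str | Path = "zprofile.png",
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if z.size == 0:
        raise ValueError("empty z profile")
    colors = np.full(grid.n_bins, _COL_NEUTRAL, dtype=object)
    for c in calls:
        colors[c.bin_indices] = _COL_DUP if c.direction > 0 else _COL_DEL

    names = grid.genome.names
    fig, axes = plt.subplots(len(names), 1,
                             figsize=(10, 2.2 * len(names)), squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        sl = grid.bins_of_chrom(name)
        x = (grid.start[sl] + grid.end[sl]) / 2e6
        zz = np.nan_to_num(z[sl])
        ax.bar(x, zz, width=grid.width / 1e6 * 0.9, color=colors[sl])
        ax.axhline(threshold, ls="--", lw=0.8, color="k")
        ax.axhline(-threshold, ls="--", lw=0.8, color="k")
        ax.set_ylabel("z")
        ax.set_title(name, fontsize=9, loc="left")
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_zprofile_tsv(tsv_path: str | Path, out_path: str | Path,
                      threshold: float = DEFAULT_Z_THRESHOLD) -> None:
    """Plot directly from a zscores.tsv written by the pipeline."""
    from .genome_model import Genome, build_bins
    from .cna_calling import call_aberrations

    df = pd.read_csv(tsv_path, sep="\t")
    if df.empty:
        raise ValueError("empty z profile table")
    genome = Genome.from_dict(
        df.groupby("chrom", sort=False)["end"].max().to_dict())
    width = int((df["end"] - df["start"]).max())
    grid = build_bins(genome, width)
    z = df["z"].to_numpy(float)
    mask = df["usable"].to_numpy(bool)
    calls = call_aberrations(z, grid, mask, threshold)
    plot_zprofile(z, grid, calls, out_path, threshold)
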