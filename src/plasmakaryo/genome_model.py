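"""Genome coordinates, fixed-width bin grids and per-bin GC content.

The analysis unit throughout the package is a fixed-width genomic bin.
GC correction operates on a fine grid (100 kb by default) which is later
merged into coarse analysis bins (1 Mb by default). Coordinates are
0-based, half-open everywhere, matching BED conventions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "BinGrid",
    "GCTrack",
    "build_bins",
    "compute_gc_track",
]

#: bins whose fraction of N/ambiguous bases exceeds this are masked by default
DEFAULT_MAX_N_FRACTION = 0.34


@dataclass(frozen=True)
class Genome:
    """An ordered set of chromosomes with lengths in bp.

    Order is significant: it defines the global bin ordering of every
    grid derived from the genome.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in count")
        if len(self.names) == 0:
            raise ValueError("genome has no chromosomes")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "Genome":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    @classmethod
    def from_fai(cls, path: str | Path) -> "Genome":
        """Read chromosome lengths from a samtools/pyfaidx .fai index."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["name", "length"], dtype={"name": str})
        return cls(tuple(df["name"]), tuple(int(v) for v in df["length"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Genome":
        """Read a two-column (name, length) TSV; same layout as .fai cols 1-2."""
        return cls.from_fai(path)

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in genome") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    @property
    def total_length(self) -> int:
        return sum(self.lengths)


@dataclass
class BinGrid:
    """Fixed-width bins tiling a genome.

    Within each chromosome bins are contiguous, sorted and non-overlapping;
    the last bin of a chromosome may be shorter than ``width``. Global bin
    indices run 0..n_bins-1 in genome order.
    """

    genome: Genome
    width: int
    chrom_idx: np.ndarray  # per-bin chromosome index into genome.names
    start: np.ndarray
    end: np.ndarray
    #: first global bin index of each chromosome (len = n_chroms + 1)
    chrom_offsets: np.ndarray = field(repr=False, default=None)

    @property
    def n_bins(self) -> int:
        return self.start.size

    @property
    def partial(self) -> np.ndarray:
        """Boolean mask of trailing bins shorter than the grid width."""
        return (self.end - self.start) < self.width

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def chrom_names(self) -> np.ndarray:
        return np.asarray(self.genome.names, dtype=object)[self.chrom_idx]

    def bins_of_chrom(self, name: str) -> slice:
        ci = self.genome.names.index(name)
        return slice(int(self.chrom_offsets[ci]), int(self.chrom_offsets[ci + 1]))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos`` on ``chrom``."""
        ci = self.genome.names.index(chrom)
        if not (0 <= pos < self.genome.lengths[ci]):
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.chrom_offsets[ci]) + pos // self.width

    def coarsen(self, factor: int) -> tuple["BinGrid", np.ndarray]:
        """Build the grid of ``factor``-times wider bins plus the fine->coarse map.

        Returns (coarse_grid, fine_to_coarse) where fine_to_coarse[i] is the
        global coarse-bin index containing fine bin i.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        coarse = build_bins(self.genome, self.width * factor)
        # fine bin's ordinal within its chromosome // factor + coarse chrom offset
        fine_ord = np.arange(self.n_bins) - self.chrom_offsets[self.chrom_idx]
        fine_to_coarse = coarse.chrom_offsets[self.chrom_idx] + fine_ord // factor
        return coarse, fine_to_coarse.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom_names(),
            "start": self.start,
            "end": self.end,
        })


def build_bins(genome: Genome, bin_width: int) -> BinGrid:
    """Tile every chromosome with ``bin_width``-bp bins.

    Every base belongs to exactly one bin; the final bin of a chromosome
    keeps the remainder and is flagged partial.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    chrom_idx, starts, ends = [], [], []
    offsets = [0]
    for ci, length in enumerate(genome.lengths):
        n = -(-length // bin_width)  # ceil division
        s = np.arange(n, dtype=np.int64) * bin_width
        e = np.minimum(s + bin_width, length)
        chrom_idx.append(np.full(n, ci, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        offsets.append(offsets[-1] + n)
    return BinGrid(
        genome=genome,
        width=bin_width,
        chrom_idx=np.concatenate(chrom_idx),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        chrom_offsets=np.asarray(offsets, dtype=np.int64),
    )


@dataclass
class GCTrack:
    """Per-bin GC fraction (over non-N bases) and N-base fraction."""

    grid: BinGrid
    gc: np.ndarray          # NaN where a bin has no A/C/G/T bases
    n_fraction: np.ndarray

    def usable_mask(self, max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
                    mask_partial: bool = True) -> np.ndarray:
        """Bins fit for depth analysis.

        N-heavy bins are excluded because their effective mappable length is
        unknown; trailing partial bins are excluded by default because their
        counts are not comparable to full-width bins.
        """
        ok = (self.n_fraction <= max_n_fraction) & np.isfinite(self.gc)
        if mask_partial:
            ok &= ~self.grid.partial
        return ok

    def to_tsv(self, path: str | Path) -> None:
        df = self.grid.to_frame()
        df["gc_fraction"] = self.gc
        df["n_fraction"] = self.n_fraction
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, grid: BinGrid) -> "GCTrack":
        df = pd.read_csv(path, sep="\t")
        if len(df) != grid.n_bins:
            raise ValueError("GC table row count does not match grid")
        return cls(grid, df["gc_fraction"].to_numpy(float),
                   df["n_fraction"].to_numpy(float))


def compute_gc_track(sequences, grid: BinGrid) -> GCTrack:
    """Count GC content per bin from a sequence source.

    ``sequences`` is anything mapping chromosome name -> sliceable sequence
    (a ``pyfaidx.Fasta``, or a plain dict of strings). GC fraction is taken
    over A/C/G/T bases only; ambiguous bases count toward ``n_fraction``.
    """
    gc = np.full(grid.n_bins, np.nan)
    nfrac = np.zeros(grid.n_bins)
    for ci, name in enumerate(grid.genome.names):
        try:
            seq_entry = sequences[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} missing from sequence source")
        sl = grid.bins_of_chrom(name)
        for i in range(sl.start, sl.stop):
            s = str(seq_entry[grid.start[i]:grid.end[i]]).upper()
            length = len(s)
            if length != grid.end[i] - grid.start[i]:
                raise ValueError(
                    f"sequence for {name} shorter than expected at bin {i}")
            g = s.count("G") + s.count("C")
            at = s.count("A") + s.count("T")
            acgt = g + at
            nfrac[i] = (length - acgt) / length
            if acgt > 0:
                gc[i] = g / acgt
    return GCTrack(grid, gc, nfrac)
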