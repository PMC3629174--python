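"""Turn paired-end alignments into filtered, deduplicated plasma fragments.

Plasma cfDNA is sequenced paired-end; each properly oriented read pair
delimits one original plasma DNA molecule (a *fragment*). Downstream
analysis counts fragments, not reads, so a pair passing the filters
contributes exactly one count.

Filters applied, in order:

1. both mates aligned, primary, on the same chromosome;
2. inward-facing FR orientation (forward mate leftmost);
3. insert size (fragment length) <= ``max_insert`` (600 bp default —
   plasma molecules are short and longer "pairs" are artefactual);
4. optionally, per-read mismatch count <= ``max_mismatches`` when an NM
   tag (or TSV column) is present;
5. PCR-duplicate removal: fragments sharing (chrom, start, end) keep one
   representative.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

from .genome_model import BinGrid

__all__ = [
    "Fragment",
    "FilterStats",
    "BinCounts",
    "filter_fragments",
    "fragments_from_sam",
    "read_fragment_tsv",
    "write_fragment_tsv",
    "deduplicate",
    "count_fragments",
]

DEFAULT_MAX_INSERT = 600
DEFAULT_MAX_MISMATCHES = 2


class Fragment(NamedTuple):
    chrom: str
    start: int  # 0-based leftmost
    end: int    # half-open rightmost
    nm1: Optional[int] = None
    nm2: Optional[int] = None

    @property
    def insert_size(self) -> int:
        return self.end - self.start


class MatePair(NamedTuple):
    """Minimal alignment facts about a read pair, independent of SAM."""
    chrom1: str
    start1: int
    end1: int
    reverse1: bool
    chrom2: str
    start2: int
    end2: int
    reverse2: bool
    nm1: Optional[int] = None
    nm2: Optional[int] = None


@dataclass
class FilterStats:
    total_pairs: int = 0
    retained: int = 0
    rejections: dict = field(default_factory=dict)
    unpaired: int = 0
    duplicates: int = 0

    def reject(self, reason: str) -> None:
        self.rejections[reason] = self.rejections.get(reason, 0) + 1

    def to_json(self) -> str:
        return json.dumps({
            "total_pairs": self.total_pairs,
            "retained": self.retained,
            "rejections": self.rejections,
            "unpaired": self.unpaired,
            "duplicates": self.duplicates,
        }, indent=2)


@dataclass
class BinCounts:
    """Per-bin fragment counts on a grid."""

    grid: BinGrid
    counts: np.ndarray  # int, len == grid.n_bins

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path) -> None:
        df = self.grid.to_frame()
        df["count"] = self.counts
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, grid: BinGrid) -> "BinCounts":
        df = pd.read_csv(path, sep="\t")
        if len(df) != grid.n_bins:
            raise ValueError("counts table does not match grid")
        return cls(grid, df["count"].to_numpy(np.int64))


def filter_fragments(
    pairs: Iterable[MatePair],
    max_insert: int = DEFAULT_MAX_INSERT,
    max_mismatches: Optional[int] = DEFAULT_MAX_MISMATCHES,
    stats: Optional[FilterStats] = None,
) -> tuple[list[Fragment], FilterStats]:
    """Apply pairing/orientation/insert/mismatch filters to mate pairs.

    Returns the surviving fragments (one per retained pair) together with
    per-reason rejection counts. ``max_mismatches=None`` disables the
    mismatch filter; pairs lacking mismatch info are never rejected on it.
    """
    if stats is None:
        stats = FilterStats()
    kept: list[Fragment] = []
    for p in pairs:
        stats.total_pairs += 1
        if p.chrom1 != p.chrom2:
            stats.reject("different_chromosomes")
            continue
        if p.reverse1 == p.reverse2:
            stats.reject("orientation")
            continue
        fwd_start = p.start1 if not p.reverse1 else p.start2
        rev_start = p.start2 if not p.reverse1 else p.start1
        # inward-facing (FR): the forward mate must be the leftmost
        if fwd_start > rev_start:
            stats.reject("orientation")
            continue
        start = min(p.start1, p.start2)
        end = max(p.end1, p.end2)
        if end - start > max_insert:
            stats.reject("insert_size")
            continue
        if max_mismatches is not None:
            nms = [v for v in (p.nm1, p.nm2) if v is not None]
            if any(v > max_mismatches for v in nms):
                stats.reject("mismatches")
                continue
        kept.append(Fragment(p.chrom1, start, end, p.nm1, p.nm2))
        stats.retained += 1
    return kept, stats


def fragments_from_sam(
    path: str | Path,
    max_insert: int = DEFAULT_MAX_INSERT,
    max_mismatches: Optional[int] = DEFAULT_MAX_MISMATCHES,
) -> tuple[list[Fragment], FilterStats]:
    """Read a SAM/BAM file and return filtered fragments.

    Mates are paired by query name, so any sort order works. Secondary and
    supplementary alignments are ignored; reads whose mate never appears
    are counted as unpaired and skipped.
    """
    import pysam

    stats = FilterStats()
    pending: dict[str, object] = {}
    pairs: list[MatePair] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for read in fh:
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            if not read.is_paired:
                stats.unpaired += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (mate, read)
            nm1 = r1.get_tag("NM") if r1.has_tag("NM") else None
            nm2 = r2.get_tag("NM") if r2.has_tag("NM") else None
            pairs.append(MatePair(
                r1.reference_name, r1.reference_start, r1.reference_end,
                r1.is_reverse,
                r2.reference_name, r2.reference_start, r2.reference_end,
                r2.is_reverse, nm1, nm2))
    stats.unpaired += len(pending)
    return filter_fragments(pairs, max_insert, max_mismatches, stats)


def read_fragment_tsv(path: str | Path) -> list[Fragment]:
    """Read the plain fragment dialect: chrom, start, end[, nm1, nm2]; no header."""
    frags: list[Fragment] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed fragment line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            nm1 = int(parts[3]) if len(parts) > 3 else None
            nm2 = int(parts[4]) if len(parts) > 4 else None
            if end <= start:
                raise ValueError(f"fragment end <= start: {line!r}")
            frags.append(Fragment(chrom, start, end, nm1, nm2))
    return frags


def write_fragment_tsv(fragments: Iterable[Fragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            cols = [f.chrom, str(f.start), str(f.end)]
            if f.nm1 is not None or f.nm2 is not None:
                cols += [str(f.nm1 or 0), str(f.nm2 or 0)]
            fh.write("\t".join(cols) + "\n")


def deduplicate(fragments: Iterable[Fragment]) -> tuple[list[Fragment], int]:
    """Drop PCR duplicates: fragments with identical (chrom, start, end).

    Keeps the first occurrence; survivor order is stable.
    """
    seen: set[tuple[str, int, int]] = set()
    kept: list[Fragment] = []
    dups = 0
    for f in fragments:
        key = (f.chrom, f.start, f.end)
        if key in seen:
            dups += 1
        else:
            seen.add(key)
            kept.append(f)
    return kept, dups


def count_fragments(
    fragments: Iterable[Fragment],
    grid: BinGrid,
    on_unknown_chrom: str = "skip",
) -> tuple[BinCounts, int]:
    """Count each fragment in the bin containing its leftmost start.

    A fragment straddling a bin boundary is counted once, in the bin of its
    start coordinate. Returns (BinCounts, n_skipped_unknown_chrom).
    """
    if on_unknown_chrom not in ("skip", "error"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'error'")
    names = grid.genome.names
    name_to_ci = {n: i for i, n in enumerate(names)}
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    skipped = 0
    offsets = grid.chrom_offsets
    width = grid.width
    lengths = grid.genome.lengths
    for f in fragments:
        ci = name_to_ci.get(f.chrom)
        if ci is None:
            if on_unknown_chrom == "error":
                raise KeyError(f"fragment on unknown chromosome {f.chrom!r}")
            skipped += 1
            continue
        if not (0 <= f.start < lengths[ci]):
            raise ValueError(f"fragment start {f.start} outside {f.chrom}")
        counts[offsets[ci] + f.start // width] += 1
    return BinCounts(grid, counts), skipped


def count_fragment_frame(df: pd.DataFrame, grid: BinGrid,
                         on_unknown_chrom: str = "skip") -> tuple[BinCounts, int]:
    """Vectorized ``count_fragments`` for a (chrom, start, ...) DataFrame."""
    name_to_ci = {n: i for i, n in enumerate(grid.genome.names)}
    ci = df["chrom"].map(name_to_ci)
    known = ci.notna()
    skipped = int((~known).sum())
    if skipped and on_unknown_chrom == "error":
        raise KeyError("fragments on unknown chromosomes present")
    ci_arr = ci[known].to_numpy(np.int64)
    starts = df.loc[known, "start"].to_numpy(np.int64)
    idx = grid.chrom_offsets[ci_arr] + starts // grid.width
    counts = np.bincount(idx, minlength=grid.n_bins).astype(np.int64)
    return BinCounts(grid, counts), skipped
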