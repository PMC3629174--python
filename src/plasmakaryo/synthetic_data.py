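"""Seeded synthetic plasma fragment datasets for end-to-end testing.

The generator emulates the statistical structure the pipeline assumes:

* a toy genome tiled by fine bins, each with a GC value drawn once per
  genome from a Beta-shaped spread (so panel and test samples share the
  same GC landscape, as real samples share a reference genome);
* a smooth multiplicative GC sampling bias, with small per-sample jitter
  of its strength to mimic library-to-library variation;
* maternal + fetal admixture at fetal fraction f: an implanted
  aberration of direction d multiplies the expected share of the bins it
  covers by a dosage factor depending on who carries it —
  fetal 1 + f*d/2, maternal 1 + (1-f)*d/2, both 1 + d/2;
* fragments of bounded length (<= 600 bp) placed uniformly within bins,
  with per-bin totals drawn from a multinomial over the biased shares.

It does not emulate nucleosome footprints, size-selection biology,
sequencing errors or mappability holes; tests passing on this generator
demonstrate the pipeline's statistical behaviour, not robustness to
those artefacts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import Genome, BinGrid, GCTrack, build_bins

__all__ = ["Implant", "SyntheticSpec", "generate_sample", "generate_panel",
           "synthetic_gc_track", "write_fasta"]

FINE_BIN_WIDTH = 100_000


@dataclass(frozen=True)
class Implant:
    chrom: str
    start: int
    end: int
    direction: int                              # -1 deletion, +1 duplication
    carrier: Literal["fetal", "maternal", "both"] = "fetal"

    def dosage(self, f: float) -> float:
        """Expected copy-dosage multiplier of a fully covered bin."""
        half = self.direction / 2.0
        if self.carrier == "fetal":
            return 1.0 + f * half
        if self.carrier == "maternal":
            return 1.0 + (1.0 - f) * half
        return 1.0 + half  # both


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Defaults model a down-scaled plasma sequencing experiment: a 90.3-Mb
    three-chromosome toy genome (large relative to Mb-scale implants, so
    an aberration stays a small fraction of the genome, as in real data)
    and 1.3 million fragments per sample — about 14,000 per 1-Mb analysis
    bin, sized so a fetus-only single-copy change at f = 10% shifts an
    affected bin by ~5-6 null SDs and is therefore reliably beyond the
    z = 3 interval. Reference panel of eight normals; plasma-like
    fragment lengths (mean 166 bp, SD 40, hard cap 600).
    """

    genome: Genome = field(default_factory=lambda: Genome.from_dict(
        {"chr1": 35_000_000, "chr2": 30_000_000, "chr3": 25_300_000}))
    n_fragments: int = 1_300_000
    fetal_fraction: float = 0.10
    implants: tuple[Implant, ...] = ()
    gc_bias_coef: float = 1.0       # slope of the linear GC bias around GC 0.45
    gc_bias_jitter: float = 0.05    # per-sample relative SD of the slope
    frag_len_mean: float = 166.0
    frag_len_sd: float = 40.0
    frag_len_max: int = 600
    fine_bin_width: int = FINE_BIN_WIDTH
    panel_size: int = 8
    gc_seed: int = 7                # fixes the genome's GC landscape
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fetal_fraction <= 1.0):
            raise ValueError("fetal_fraction must be in [0, 1]")
        for im in self.implants:
            if im.chrom not in self.genome:
                raise ValueError(f"implant on unknown chromosome {im.chrom!r}")
            if not (0 <= im.start < im.end <= self.genome.length_of(im.chrom)):
                raise ValueError("implant outside genome bounds")
        if not (0 < self.frag_len_max <= 600):
            raise ValueError("fragment lengths must lie in (0, 600]")

    def grid(self) -> BinGrid:
        return build_bins(self.genome, self.fine_bin_width)


def synthetic_gc_track(spec: SyntheticSpec) -> GCTrack:
    """Per-fine-bin GC drawn once per genome from a Beta(2, 2) spread on [0.3, 0.6].

    Deterministic in ``gc_seed`` alone, so every sample of a cohort sees the
    same GC landscape.
    """
    grid = spec.grid()
    rng = np.random.default_rng(spec.gc_seed)
    gc = 0.3 + 0.3 * rng.beta(2.0, 2.0, size=grid.n_bins)
    return GCTrack(grid, gc, np.zeros(grid.n_bins))


def _gc_bias(gc: np.ndarray, coef: float) -> np.ndarray:
    return np.clip(1.0 + coef * (gc - 0.45), 0.1, None)


def _dosage_per_bin(spec: SyntheticSpec, grid: BinGrid) -> np.ndarray:
    """Expected dosage multiplier per fine bin, overlap-weighted at edges."""
    dosage = np.ones(grid.n_bins)
    for im in spec.implants:
        sl = grid.bins_of_chrom(im.chrom)
        overlap = (np.minimum(grid.end[sl], im.end)
                   - np.maximum(grid.start[sl], im.start))
        frac = np.clip(overlap, 0, None) / grid.lengths[sl]
        dosage[sl] += frac * (im.dosage(spec.fetal_fraction) - 1.0)
    return dosage


def generate_sample(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    with_implants: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Draw one synthetic plasma sample.

    Returns a fragment table (chrom, start, end) sorted in genome order and
    a truth record (fetal fraction, implants, per-bin expected dosage and
    sampling shares).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    gc = synthetic_gc_track(spec)
    coef = spec.gc_bias_coef * (1.0 + spec.gc_bias_jitter * rng.standard_normal())
    dosage = _dosage_per_bin(spec, grid) if with_implants else np.ones(grid.n_bins)
    weights = grid.lengths * _gc_bias(gc.gc, coef) * dosage
    shares = weights / weights.sum()
    counts = rng.multinomial(spec.n_fragments, shares)

    bin_idx = np.repeat(np.arange(grid.n_bins), counts)
    lengths = np.clip(
        np.rint(rng.normal(spec.frag_len_mean, spec.frag_len_sd, size=bin_idx.size)),
        20, spec.frag_len_max).astype(np.int64)
    starts = (grid.start[bin_idx]
              + np.floor(rng.random(bin_idx.size) * grid.lengths[bin_idx]).astype(np.int64))
    chrom_len = np.asarray(spec.genome.lengths, dtype=np.int64)[grid.chrom_idx[bin_idx]]
    ends = np.minimum(starts + lengths, chrom_len)
    frame = pd.DataFrame({
        "chrom": grid.chrom_names()[bin_idx],
        "start": starts,
        "end": ends,
    })
    truth = {
        "fetal_fraction": spec.fetal_fraction,
        "n_fragments": spec.n_fragments,
        "gc_bias_coef_sample": coef,
        "implants": [
            {"chrom": im.chrom, "start": im.start, "end": im.end,
             "direction": im.direction, "carrier": im.carrier,
             "dosage": im.dosage(spec.fetal_fraction)}
            for im in (spec.implants if with_implants else ())
        ],
        "expected_dosage_per_fine_bin": dosage.tolist(),
        "version": 1,
    }
    return frame, truth


def generate_panel(
    spec: SyntheticSpec,
    n_samples: Optional[int] = None,
) -> list[pd.DataFrame]:
    """Independent karyotypically normal samples sharing the GC landscape.

    Samples are seeded from the spec's master seed, so the same spec always
    yields the identical panel. Implants are never applied to panel samples.
    """
    n = spec.panel_size if n_samples is None else n_samples
    if n < 2:
        raise ValueError("panel needs at least 2 samples")
    master = np.random.default_rng(spec.seed)
    out = []
    for _ in range(n):
        child = np.random.default_rng(master.integers(0, 2**31 - 1))
        frame, _ = generate_sample(spec, rng=child, with_implants=False)
        out.append(frame)
    return out


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


def write_fasta(spec: SyntheticSpec, path: str | Path,
                line_width: int = 70) -> None:
    """Emit a synthetic FASTA whose per-bin GC matches ``synthetic_gc_track``.

    Each fine bin is filled with a deterministic repeat pattern achieving its
    target GC to within 1/bin-length, so ``compute_gc_track`` on this file
    reproduces the synthetic track (useful for exercising the FASTA path).
    """
    grid = spec.grid()
    gc = synthetic_gc_track(spec)
    with open(path, "w") as fh:
        for name in spec.genome.names:
            fh.write(f">{name}\n")
            sl = grid.bins_of_chrom(name)
            buf = []
            for i in range(sl.start, sl.stop):
                n = int(grid.lengths[i])
                n_gc = int(round(gc.gc[i] * n))
                seq = ("GC" * ((n_gc + 1) // 2))[:n_gc] + \
                      ("AT" * ((n - n_gc + 1) // 2))[:n - n_gc]
                buf.append(seq)
            seq = "".join(buf)
            for j in range(0, len(seq), line_width):
                fh.write(seq[j:j + line_width] + "\n")
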