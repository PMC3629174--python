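"""Genomic representation, reference panel statistics and z-scores.

The genomic representation (GR) of a bin is the fraction of all counted
fragments that fall in it. A reference panel of karyotypically normal
plasma samples supplies, per bin, the mean and standard deviation of GR
against which a test sample is standardized:

    z_i = (dev_test,i - mean_ref,i) / sd_ref,i

where ``dev`` is the GR after per-chromosome median correction: for each
chromosome the median GR over its usable bins is subtracted from every
bin on that chromosome. This removes systematic inter-sample shifts in
whole-chromosome representation that would otherwise inflate every z on
a chromosome. Median correction is applied identically to the test
sample and to every panel sample, so numerator and denominator are on
the same scale.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import BinGrid, Genome, build_bins
from .fragment_ingest import BinCounts
from .gc_correction import CorrectedCounts

__all__ = [
    "GRProfile",
    "ReferencePanel",
    "merge_bins",
    "genomic_representation",
    "median_correct",
    "build_reference",
    "zscores",
]


@dataclass
class GRProfile:
    """Per-bin genomic representation with a usability mask.

    GR sums to 1 over usable bins; masked bins are NaN.
    """

    grid: BinGrid
    gr: np.ndarray
    mask: np.ndarray

    def deviations(self) -> np.ndarray:
        return median_correct(self.gr, self.grid, self.mask)


@dataclass
class ReferencePanel:
    """Per-bin mean/SD of median-corrected GR deviations across normals.

    Also keeps the panel mean of raw (non-median-corrected) GR, used by
    the fetal-fraction estimator which works on representation ratios.
    Bins masked in any panel sample, or with zero SD, are masked.
    """

    grid: BinGrid
    n_samples: int
    mean_dev: np.ndarray
    sd_dev: np.ndarray
    mean_gr: np.ndarray
    mask: np.ndarray

    def to_tsv(self, path: str | Path, genome_id: str = "custom",
               version: str = "0") -> None:
        header = json.dumps({
            "panel_size": self.n_samples,
            "bin_width": self.grid.width,
            "genome_id": genome_id,
            "software_version": version,
        })
        df = self.grid.to_frame()
        df["mean_dev"] = self.mean_dev
        df["sd_dev"] = self.sd_dev
        df["mean_gr"] = self.mean_gr
        df["usable"] = self.mask.astype(int)
        with open(path, "w") as fh:
            fh.write(f"#{header}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferencePanel":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("panel file missing JSON header line")
            meta = json.loads(first[1:])
            df = pd.read_csv(fh, sep="\t")
        genome = Genome.from_dict(
            df.groupby("chrom", sort=False)["end"].max().to_dict())
        grid = build_bins(genome, int(meta["bin_width"]))
        if grid.n_bins != len(df):
            raise ValueError("panel bins do not tile the genome consistently")
        return cls(
            grid=grid,
            n_samples=int(meta["panel_size"]),
            mean_dev=df["mean_dev"].to_numpy(float),
            sd_dev=df["sd_dev"].to_numpy(float),
            mean_gr=df["mean_gr"].to_numpy(float),
            mask=df["usable"].to_numpy(bool),
        )


def merge_bins(
    corrected: CorrectedCounts,
    factor: int,
    mask_policy: str | float = "any",
    mask_partial: bool = True,
) -> tuple[BinCounts, np.ndarray, np.ndarray]:
    """Sum fine-bin corrected counts into ``factor``-times wider bins.

    ``mask_policy`` — ``"any"`` masks a coarse bin when any member fine bin
    is masked; a float in (0, 1] masks when the masked-member fraction
    exceeds that threshold. Trailing coarse bins shorter than the full
    width are masked by default: their counts are not comparable to
    full-width bins.

    Returns (coarse BinCounts with float-summed values, coarse mask,
    fine_to_coarse index map).
    """
    coarse_grid, f2c = corrected.grid.coarsen(factor)
    vals = np.where(corrected.mask, np.nan_to_num(corrected.values), 0.0)
    sums = np.bincount(f2c, weights=vals, minlength=coarse_grid.n_bins)
    n_members = np.bincount(f2c, minlength=coarse_grid.n_bins)
    n_masked = np.bincount(f2c, weights=(~corrected.mask).astype(float),
                           minlength=coarse_grid.n_bins)
    if mask_policy == "any":
        coarse_mask = (n_masked == 0) & (n_members > 0)
    else:
        thr = float(mask_policy)
        if not (0 < thr <= 1):
            raise ValueError("mask_policy fraction must be in (0, 1]")
        with np.errstate(invalid="ignore"):
            coarse_mask = (n_masked / np.maximum(n_members, 1)) <= thr
        coarse_mask &= n_members > 0
    if mask_partial:
        coarse_mask &= ~coarse_grid.partial
    counts = BinCounts(coarse_grid, sums)
    return counts, coarse_mask, f2c


def genomic_representation(counts: BinCounts, mask: np.ndarray) -> GRProfile:
    """GR_i = count_i / total count over usable bins."""
    vals = np.asarray(counts.counts, dtype=float)
    total = vals[mask].sum()
    if total <= 0:
        raise ValueError("total count over usable bins is zero")
    gr = np.full(vals.shape, np.nan)
    gr[mask] = vals[mask] / total
    return GRProfile(counts.grid, gr, mask.copy())


def median_correct(gr: np.ndarray, grid: BinGrid, mask: np.ndarray) -> np.ndarray:
    """Subtract each chromosome's median usable-bin GR from its bins.

    Chromosomes with no usable bins have all their bins returned as NaN.
    """
    dev = np.full(gr.shape, np.nan)
    for name in grid.genome.names:
        sl = grid.bins_of_chrom(name)
        m = mask[sl]
        if not m.any():
            continue
        baseline = np.median(gr[sl][m])
        dev_sl = dev[sl]
        dev_sl[m] = gr[sl][m] - baseline
        dev[sl] = dev_sl
    return dev


def build_reference(profiles: list[GRProfile]) -> ReferencePanel:
    """Per-bin mean and sample SD (n-1) of median-corrected deviations.

    Masks are intersected across samples (conservative); bins where the
    panel SD is zero are additionally masked — a zero SD would make any
    test deviation infinitely significant.
    """
    if len(profiles) < 2:
        raise ValueError("reference panel needs at least 2 samples")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid.n_bins != grid.n_bins or p.grid.width != grid.width:
            raise ValueError("panel samples are on different grids")
    mask = np.logical_and.reduce([p.mask for p in profiles])
    devs = np.vstack([p.deviations() for p in profiles])
    grs = np.vstack([p.gr for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_dev = np.nanmean(devs, axis=0)
        sd_dev = np.nanstd(devs, axis=0, ddof=1)
        mean_gr = np.nanmean(grs, axis=0)
    degenerate = mask & ~(sd_dev > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} bins have zero panel SD and were masked")
    mask = mask & (sd_dev > 0)
    return ReferencePanel(grid, len(profiles), mean_dev, sd_dev, mean_gr, mask)


def zscores(test: GRProfile, panel: ReferencePanel) -> tuple[np.ndarray, np.ndarray]:
    """Standardize a test sample's deviations against the panel.

    Returns (z, mask); z is NaN outside the joint mask.
    """
    if test.grid.n_bins != panel.grid.n_bins:
        raise ValueError("test sample and panel are on different grids")
    mask = test.mask & panel.mask
    dev = test.deviations()
    z = np.full(dev.shape, np.nan)
    z[mask] = (dev[mask] - panel.mean_dev[mask]) / panel.sd_dev[mask]
    return z, mask
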