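"""Copy-number aberration calling from a per-bin z-score profile.

A single bin outside the +/-3 reference interval is expected ~0.3% of
the time by chance, so genome-wide scans would produce several false
positive bins per sample. The caller therefore requires at least three
consecutive bins on one chromosome, all beyond the threshold in the
same direction, before reporting an aberration. Overlapping qualifying
windows are merged: each call is a *maximal* run.

Masked bins terminate runs (they are not skipped over), so two distant
short runs cannot merge across an unusable gap.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .genome_model import BinGrid

__all__ = [
    "AberrationCall",
    "call_aberrations",
    "expected_false_positive_bins",
    "calls_to_bed",
]

DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_MIN_RUN = 3


@dataclass
class AberrationCall:
    chrom: str
    start: int
    end: int
    first_bin: int          # global index of the first member bin
    n_bins: int
    direction: int          # -1 deletion, +1 duplication
    z_min: float
    z_max: float
    z_mean: float

    @property
    def bin_indices(self) -> np.ndarray:
        return np.arange(self.first_bin, self.first_bin + self.n_bins)

    @property
    def kind(self) -> str:
        return "DEL" if self.direction < 0 else "DUP"

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom, "start": int(self.start), "end": int(self.end),
            "type": self.kind, "direction": self.direction,
            "n_bins": self.n_bins, "z_min": self.z_min, "z_max": self.z_max,
            "z_mean": self.z_mean,
        }


def call_aberrations(
    z: np.ndarray,
    grid: BinGrid,
    mask: Optional[np.ndarray] = None,
    threshold: float = DEFAULT_Z_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[AberrationCall]:
    """Report maximal runs of >= ``min_run`` same-direction outlier bins.

    A bin qualifies when its z is strictly beyond +/-``threshold``
    (z exactly at the boundary lies inside the reference interval).
    Runs never cross chromosome boundaries or masked bins.
    """
    if mask is None:
        mask = np.isfinite(z)
    state = np.zeros(grid.n_bins, dtype=np.int8)
    usable = mask & np.isfinite(z)
    state[usable & (z > threshold)] = 1
    state[usable & (z < -threshold)] = -1
    state[~usable] = 0

    calls: list[AberrationCall] = []
    for name in grid.genome.names:
        sl = grid.bins_of_chrom(name)
        s = state[sl]
        i = 0
        n = s.size
        while i < n:
            if s[i] == 0:
                i += 1
                continue
            j = i
            while j < n and s[j] == s[i]:
                j += 1
            if j - i >= min_run:
                gi, gj = sl.start + i, sl.start + j
                zz = z[gi:gj]
                calls.append(AberrationCall(
                    chrom=name,
                    start=int(grid.start[gi]),
                    end=int(grid.end[gj - 1]),
                    first_bin=gi,
                    n_bins=j - i,
                    direction=int(s[i]),
                    z_min=float(zz.min()),
                    z_max=float(zz.max()),
                    z_mean=float(zz.mean()),
                ))
            i = j
    return calls


def expected_false_positive_bins(T: int, threshold: float = DEFAULT_Z_THRESHOLD) -> float:
    """Expected number of usable bins outside +/-threshold by chance alone.

    Under the null the per-bin z is standard normal, so the expectation is
    T times the two-sided tail probability (~0.0027 at threshold 3).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    return float(T * 2.0 * norm.sf(threshold))


def calls_to_bed(calls: list[AberrationCall]) -> str:
    """BED6+3: chrom, start, end, DEL/DUP, |mean z|, '.', nbins, min_z, max_z."""
    lines = []
    for c in calls:
        lines.append("\t".join([
            c.chrom, str(c.start), str(c.end), c.kind,
            f"{abs(c.z_mean):.3f}", ".",
            str(c.n_bins), f"{c.z_min:.3f}", f"{c.z_max:.3f}",
        ]))
    return "\n".join(lines) + ("\n" if lines else "")
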