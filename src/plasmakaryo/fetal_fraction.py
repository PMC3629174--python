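"""Fetal DNA fraction from the dosage shift of a called aberration.

Plasma cfDNA is a maternal/fetal mixture. When only the fetus carries a
single-copy deletion or duplication, the affected bins' representation
shifts by half the fetal fraction: the fetus contributes f of the
molecules and its aberrant allele changes the local dosage by one copy
out of two, so

    GR_test / GR_ref = 1 + d * f / 2      (d = -1 deletion, +1 duplication)

Inverting gives the estimator  f = 2 * d * (mean ratio - 1), reported as
a percentage. Because GR is a fraction of the sample total, an
aberration also perturbs the denominator by its own genomic share
s = sum of reference GR over the region; solving the admixture balance
exactly gives

    f = 2 * d * (mean ratio - 1) / (1 - mean ratio * s),

which the implementation uses. For real genomes s is a few parts per
thousand and the correction is negligible; it matters only when the
region is a visible fraction of the genome analyzed. Ratios are
averaged per bin (not summed as counts) over the bins fully covered by
the aberration. An estimate far above the
plausible fetal range (~50% shift, ratio ~1.5) indicates the mother
carries the aberration herself, in which case f reflects the maternal
genotype rather than the fetal fraction.

Ratios are taken on GC-corrected but *non*-median-corrected GR: for a
large aberration the chromosome median itself shifts, and subtracting
it would bias the dosage signal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cna_calling import AberrationCall
from .genome_model import BinGrid
from .representation import GRProfile, ReferencePanel

__all__ = ["FetalFractionEstimate", "estimate_fetal_fraction", "bins_fully_covered"]


@dataclass
class FetalFractionEstimate:
    percent: float          # 0-100; may exceed the fetal range for maternal CNVs
    n_bins: int
    direction: int
    ratios: np.ndarray      # per-bin GR_test / mean GR_ref
    consistent: bool        # sign of (mean ratio - 1) matches the call direction

    def to_dict(self) -> dict:
        return {
            "fetal_percent": self.percent,
            "n_bins": self.n_bins,
            "direction": self.direction,
            "consistent": self.consistent,
            "ratios": [float(r) for r in self.ratios],
            "chry_fetal_percent": None,  # hook for an external chrY-based estimate
        }


def bins_fully_covered(grid: BinGrid, chrom: str, start: int, end: int) -> np.ndarray:
    """Global indices of bins lying entirely within [start, end) on chrom."""
    sl = grid.bins_of_chrom(chrom)
    idx = np.arange(sl.start, sl.stop)
    inside = (grid.start[sl] >= start) & (grid.end[sl] <= end)
    return idx[inside]


def estimate_fetal_fraction(
    test: GRProfile,
    panel: ReferencePanel,
    call: AberrationCall,
) -> FetalFractionEstimate:
    """Estimate fetal percentage from one called aberration.

    Uses only the call's member bins (each fully covered by construction,
    since calls are made in whole-bin units), restricted to bins usable in
    both the test sample and the panel with positive reference mean GR.
    """
    idx = call.bin_indices
    usable = test.mask[idx] & panel.mask[idx] & (panel.mean_gr[idx] > 0)
    idx = idx[usable]
    if idx.size == 0:
        raise ValueError("no usable fully-covered bins in the called region")
    ratios = test.gr[idx] / panel.mean_gr[idx]
    mean_ratio = float(ratios.mean())
    share = float(panel.mean_gr[idx].sum())  # region's share of the genome
    f = 2.0 * call.direction * (mean_ratio - 1.0) / (1.0 - mean_ratio * share) * 100.0
    consistent = np.sign(mean_ratio - 1.0) == np.sign(call.direction)
    return FetalFractionEstimate(
        percent=max(f, 0.0) if consistent else f,
        n_bins=int(idx.size),
        direction=call.direction,
        ratios=ratios,
        consistent=bool(consistent),
    )
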