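"""LOESS correction of GC-associated coverage bias on fine-bin counts.

Library preparation and sequencing over- or under-sample genomic windows
as a smooth function of their GC content. The correction fits expected
count versus GC by locally weighted regression (LOWESS) across usable
bins and recentres residuals on the genome-wide median raw count:

    corrected_i = raw_i - fit(gc_i) + median(raw)

The additive, median-recentred form approximately preserves the total
count, so downstream per-bin fractions are comparable before and after
correction. All depth statistics downstream of this module operate on
corrected counts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fragment_ingest import BinCounts
from .genome_model import BinGrid, GCTrack

__all__ = ["CorrectedCounts", "loess_gc_correct"]

DEFAULT_SPAN = 0.3
MIN_FIT_BINS = 30


@dataclass
class CorrectedCounts:
    """Real-valued GC-corrected per-bin counts with a usability mask."""

    grid: BinGrid
    values: np.ndarray      # NaN on masked bins
    mask: np.ndarray        # True = usable
    diagnostics: dict = field(default_factory=dict)


def loess_gc_correct(
    counts: BinCounts,
    gc: GCTrack,
    mask: np.ndarray | None = None,
    span: float = DEFAULT_SPAN,
) -> CorrectedCounts:
    """Remove GC bias from bin counts by LOWESS regression on GC.

    Parameters
    ----------
    counts, gc
        Raw counts and GC content on the same grid.
    mask
        Usable-bin mask; defaults to ``gc.usable_mask()``.
    span
        LOWESS smoothing fraction.

    Zero-count bins are excluded from the fit (they are typically
    unmappable, and would drag the smooth toward zero) but still receive
    a correction. Bins whose GC lies outside the fitted range get the
    nearest fitted value. Corrected counts are clamped at zero.
    """
    if counts.grid is not gc.grid and counts.grid.n_bins != gc.grid.n_bins:
        raise ValueError("counts and GC track are on different grids")
    if mask is None:
        mask = gc.usable_mask()
    raw = counts.counts.astype(float)
    gcv = gc.gc
    fit_bins = mask & (raw > 0) & np.isfinite(gcv)
    n_fit = int(fit_bins.sum())
    if n_fit < MIN_FIT_BINS:
        raise ValueError(
            f"only {n_fit} usable non-zero bins; need >= {MIN_FIT_BINS} for the GC fit")

    values = np.full(raw.shape, np.nan)
    diagnostics = {"span": span, "n_fit_bins": n_fit,
                   "n_excluded_from_fit": int(mask.sum()) - n_fit}

    if np.ptp(gcv[fit_bins]) == 0.0:
        warnings.warn("all usable bins share one GC value; GC correction is a no-op")
        values[mask] = raw[mask]
        diagnostics["degenerate_gc"] = True
        return CorrectedCounts(counts.grid, values, mask.copy(), diagnostics)

    sm = lowess(raw[fit_bins], gcv[fit_bins], frac=span, it=2)
    xs, ys = sm[:, 0], sm[:, 1]
    xs, uniq = np.unique(xs, return_index=True)
    ys = ys[uniq]
    fitted = np.interp(gcv[mask], xs, ys)  # clamps to edge fit outside range
    med = np.median(raw[fit_bins])
    values[mask] = np.clip(raw[mask] - fitted + med, 0.0, None)
    return CorrectedCounts(counts.grid, values, mask.copy(), diagnostics)
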