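"""End-to-end orchestration: fragments -> GC correction -> z-scores -> calls.

The stage order is fixed: count fragments on the fine grid, LOESS-correct
for GC, merge to the coarse analysis grid, normalize to genomic
representation, median-correct per chromosome, standardize against the
reference panel, call aberrations, and estimate the fetal fraction from
each call.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genome_model import (Genome, BinGrid, GCTrack, build_bins,
                           DEFAULT_MAX_N_FRACTION)
from .fragment_ingest import (BinCounts, Fragment, count_fragments,
                              count_fragment_frame, deduplicate,
                              fragments_from_sam, read_fragment_tsv)
from .gc_correction import loess_gc_correct, DEFAULT_SPAN
from .representation import (GRProfile, ReferencePanel, build_reference,
                             genomic_representation, merge_bins, zscores)
from .cna_calling import (call_aberrations, calls_to_bed,
                          DEFAULT_MIN_RUN, DEFAULT_Z_THRESHOLD)
from .fetal_fraction import estimate_fetal_fraction

logger = logging.getLogger("plasmakaryo")

__all__ = ["PipelineParams", "RunConfig", "sample_gr_profile",
           "build_panel_from_frames", "analyze_sample", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    fine_bin_width: int = 100_000
    coarse_bin_width: int = 1_000_000
    max_insert: int = 600
    max_mismatches: Optional[int] = 2
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION
    loess_span: float = DEFAULT_SPAN
    z_threshold: float = DEFAULT_Z_THRESHOLD
    min_run: int = DEFAULT_MIN_RUN

    def __post_init__(self) -> None:
        if self.coarse_bin_width % self.fine_bin_width != 0:
            raise ValueError("fine bin width must divide coarse bin width")

    @property
    def merge_factor(self) -> int:
        return self.coarse_bin_width // self.fine_bin_width


@dataclass
class RunConfig:
    """Paths plus parameters for a command-line run."""

    sample: str                 # fragment TSV or SAM/BAM
    gc_table: str               # per-fine-bin GC TSV
    genome: str                 # .fai or two-column TSV of chromosome lengths
    panel: Optional[str] = None             # serialized ReferencePanel TSV
    panel_samples: Sequence[str] = ()       # or raw samples to build one from
    out_dir: str = "."
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        p = PipelineParams(**raw.pop("params", {}))
        return cls(params=p, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in self.__dict__.items() if k != "params"},
             "params": asdict(self.params)},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_fragments(path: str | Path, params: PipelineParams):
    """Fragments + filter stats from a SAM/BAM or plain TSV path."""
    s = str(path)
    if s.endswith((".sam", ".bam")):
        frags, stats = fragments_from_sam(s, params.max_insert,
                                          params.max_mismatches)
    else:
        frags = read_fragment_tsv(s)
        frags = [f for f in frags if f.insert_size <= params.max_insert]
        stats = None
    frags, dups = deduplicate(frags)
    if stats is not None:
        stats.duplicates = dups
    logger.info("loaded %d fragments from %s (%d duplicates removed)",
                len(frags), path, dups)
    return frags, stats


def sample_gr_profile(
    fragments,
    grid: BinGrid,
    gc: GCTrack,
    params: PipelineParams = PipelineParams(),
) -> GRProfile:
    """Fine counts -> GC correction -> coarse merge -> GR for one sample.

    ``fragments`` may be a list of Fragment tuples or a (chrom, start, ...)
    DataFrame.
    """
    if isinstance(fragments, pd.DataFrame):
        counts, skipped = count_fragment_frame(fragments, grid)
    else:
        counts, skipped = count_fragments(fragments, grid)
    if skipped:
        logger.warning("%d fragments on chromosomes absent from the grid", skipped)
    fine_mask = gc.usable_mask(params.max_n_fraction)
    corrected = loess_gc_correct(counts, gc, fine_mask, params.loess_span)
    coarse_counts, coarse_mask, _ = merge_bins(corrected, params.merge_factor)
    return genomic_representation(coarse_counts, coarse_mask)


def build_panel_from_frames(
    samples,
    grid: BinGrid,
    gc: GCTrack,
    params: PipelineParams = PipelineParams(),
) -> ReferencePanel:
    profiles = [sample_gr_profile(s, grid, gc, params) for s in samples]
    return build_reference(profiles)


def analyze_sample(
    test_profile: GRProfile,
    panel: ReferencePanel,
    params: PipelineParams = PipelineParams(),
) -> dict:
    """z-scores, aberration calls and per-call fetal fractions for one sample."""
    z, mask = zscores(test_profile, panel)
    calls = call_aberrations(z, test_profile.grid, mask,
                             params.z_threshold, params.min_run)
    report_calls = []
    for c in calls:
        entry = c.to_dict()
        try:
            ff = estimate_fetal_fraction(test_profile, panel, c)
            entry["fetal_fraction"] = ff.to_dict()
        except ValueError as exc:
            entry["fetal_fraction"] = {"error": str(exc)}
        report_calls.append(entry)
    return {
        "n_usable_bins": int(mask.sum()),
        "calls": report_calls,
        "z": z,
        "mask": mask,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline for one sample and write standard outputs.

    Writes <out>/zscores.tsv, <out>/calls.bed, <out>/report.json. Raises
    ``PipelineError`` with a stage-tagged message on failure.
    """
    params = config.params
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise PipelineError(f"[{name}] {exc}") from exc

    genome = stage("genome", Genome.from_fai, config.genome)
    grid = stage("bins", build_bins, genome, params.fine_bin_width)
    gc = stage("gc", GCTrack.from_tsv, config.gc_table, grid)

    if config.panel:
        panel = stage("panel", ReferencePanel.from_tsv, config.panel)
    elif config.panel_samples:
        frames = [stage("panel", _load_fragments, p, params)[0]
                  for p in config.panel_samples]
        panel = stage("panel", build_panel_from_frames, frames, grid, gc, params)
    else:
        raise PipelineError("[panel] no reference panel provided")

    frags, stats = stage("ingest", _load_fragments, config.sample, params)
    profile = stage("represent", sample_gr_profile, frags, grid, gc, params)
    result = stage("call", analyze_sample, profile, panel, params)

    coarse = profile.grid
    zdf = coarse.to_frame()
    zdf["gr"] = profile.gr
    zdf["dev"] = profile.deviations()
    zdf["z"] = result["z"]
    zdf["usable"] = result["mask"].astype(int)
    zdf.to_csv(out / "zscores.tsv", sep="\t", index=False,
               float_format="%.6g")
    calls = call_aberrations(result["z"], coarse, result["mask"],
                             params.z_threshold, params.min_run)
    (out / "calls.bed").write_text(calls_to_bed(calls))

    report = {
        "sample": str(config.sample),
        "n_fragments": len(frags),
        "filter_stats": json.loads(stats.to_json()) if stats else None,
        "n_usable_bins": result["n_usable_bins"],
        "calls": result["calls"],
        "provenance": {
            "software": "plasmakaryo",
            "version": __version__,
            "config_hash": config.config_hash(),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""
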