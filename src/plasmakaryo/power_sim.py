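"""Binomial power simulation for depth requirements of cfDNA CNV detection.

The genome (3,000 Mb by convention) is divided into T equal bins; the
diagnostic resolution is three bin widths because a call requires three
consecutive outlier bins. With N total plasma molecules, an unaffected
bin receives a Binomial(N, 1/T) count. A bin inside an aberration of
direction d (-1 deletion, +1 duplication) carried only by the fetus at
fetal fraction f receives Binomial(N, E) with

    E = (1 + f * d / 2) / T

(the maternal compartment contributes (1-f)/T, the fetal one
f*(2+d)/(2T)). Each bin count is standardized against the null mean N/T
and the exact null binomial SD sqrt(N * (1/T) * (1 - 1/T)); an affected
case is detected when all three affected bins exceed the z threshold in
direction d, and a normal case is a false positive when any three
consecutive same-direction outlier bins occur genome-wide.

This is the idealized model — no GC bias, mappability structure or
panel noise — so results are upper bounds on real-data performance.
A normal-approximation closed form,

    sensitivity ~= Phi((f/2) * sqrt(n_per_bin) - threshold) ** k,

serves as an independent cross-check of the Monte-Carlo estimates and as
the tie-breaker in the depth search when a candidate depth lands within
Monte-Carlo noise of the target.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "RequiredDepth",
    "expected_bin_proportion",
    "simulate_sensitivity",
    "simulate_specificity",
    "analytic_sensitivity",
    "required_molecules",
]

GENOME_MB = 3000  # conventional whole-genome span for T


@dataclass(frozen=True)
class SimulationConfig:
    n_molecules: float          # N, total molecules sequenced and aligned
    fetal_fraction: float       # f, as a proportion in [0, 1]
    direction: int = -1         # d: -1 microdeletion, +1 microduplication
    n_bins: int = 3000          # T
    affected_bins: int = 3      # k, consecutive bins covered by the aberration
    threshold: float = 3.0      # z threshold
    replicates: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if not (0.0 <= self.fetal_fraction <= 1.0):
            raise ValueError("fetal_fraction must be in [0, 1]")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")
        if not (1 <= self.affected_bins <= self.n_bins):
            raise ValueError("need n_bins >= affected_bins >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SimulationResult:
    expected_proportion: float
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    se: float = 0.0
    replicates: int = 0


@dataclass
class RequiredDepth:
    per_bin: int
    total: float
    n_bins: int
    sensitivity: float          # simulated sensitivity at the accepted depth


def expected_bin_proportion(f: float, d: int, T: int) -> float:
    """Expected share of molecules falling in one affected bin."""
    if T <= 0:
        raise ValueError("T must be positive")
    return (1.0 + f * d / 2.0) / T


def _null_moments(N: float, T: int) -> tuple[float, float]:
    p0 = 1.0 / T
    return N * p0, np.sqrt(N * p0 * (1.0 - p0))


def simulate_sensitivity(config: SimulationConfig) -> SimulationResult:
    """Fraction of affected replicates in which all k affected bins are called.

    Each replicate draws the k affected-bin counts independently from
    Binomial(N, E); detection requires every standardized count beyond the
    threshold in the aberration's direction.
    """
    E = expected_bin_proportion(config.fetal_fraction, config.direction,
                                config.n_bins)
    rng = np.random.default_rng(config.seed)
    mu0, sd0 = _null_moments(config.n_molecules, config.n_bins)
    counts = rng.binomial(int(config.n_molecules), E,
                          size=(config.replicates, config.affected_bins))
    z = (counts - mu0) / sd0
    detected = np.all(config.direction * z > config.threshold, axis=1)
    sens = float(detected.mean())
    se = float(np.sqrt(sens * (1.0 - sens) / config.replicates))
    return SimulationResult(E, sensitivity=sens, se=se,
                            replicates=config.replicates)


def _has_run(flags: np.ndarray, k: int) -> np.ndarray:
    """Row-wise: does a run of >= k consecutive True occur?"""
    cs = np.cumsum(flags, axis=1)
    csp = np.concatenate([np.zeros((flags.shape[0], 1), dtype=cs.dtype), cs], axis=1)
    windows = csp[:, k:] - csp[:, :-k]
    return (windows == k).any(axis=1)


def simulate_specificity(config: SimulationConfig) -> SimulationResult:
    """Fraction of genome-wide null replicates with zero aberration calls.

    Every replicate draws all T bin counts from the null binomial and the
    k-consecutive same-direction criterion is scanned across the genome.
    """
    rng = np.random.default_rng(config.seed)
    mu0, sd0 = _null_moments(config.n_molecules, config.n_bins)
    p0 = 1.0 / config.n_bins
    false_pos = np.zeros(config.replicates, dtype=bool)
    # draw in chunks to bound memory at large T x replicates
    chunk = max(1, int(2e7) // config.n_bins)
    for lo in range(0, config.replicates, chunk):
        hi = min(lo + chunk, config.replicates)
        counts = rng.binomial(int(config.n_molecules), p0,
                              size=(hi - lo, config.n_bins))
        z = (counts - mu0) / sd0
        hit = _has_run(z > config.threshold, config.affected_bins)
        hit |= _has_run(z < -config.threshold, config.affected_bins)
        false_pos[lo:hi] = hit
    spec = float(1.0 - false_pos.mean())
    se = float(np.sqrt(spec * (1.0 - spec) / config.replicates))
    E = expected_bin_proportion(config.fetal_fraction, config.direction,
                                config.n_bins)
    return SimulationResult(E, specificity=spec, se=se,
                            replicates=config.replicates)


def analytic_sensitivity(n_per_bin: float, f: float, k: int = 3,
                         threshold: float = 3.0) -> float:
    """Normal-approximation closed form for the k-bin detection probability."""
    if n_per_bin <= 0:
        raise ValueError("n_per_bin must be positive")
    return float(norm.cdf((f / 2.0) * np.sqrt(n_per_bin) - threshold) ** k)


def required_molecules(
    f: float,
    target_sensitivity: float,
    resolution_mb: float,
    d: int = -1,
    granularity: int = 1000,
    threshold: float = 3.0,
    k: int = 3,
    replicates: int = 10000,
    seed: Optional[int] = None,
    genome_mb: float = GENOME_MB,
    max_per_bin: int = 10_000_000,
) -> RequiredDepth:
    """Smallest per-bin depth (multiple of ``granularity``) meeting a target.

    The bin size is one third of the desired diagnostic resolution, so
    T = genome_mb / (resolution_mb / 3). Candidate depths are scanned
    upward; at each, sensitivity is estimated by simulation. When the
    estimate lies within 3 Monte-Carlo SEs of the target the decision
    defers to the analytic closed form, which is deterministic.
    """
    if not (0.0 < target_sensitivity < 1.0):
        raise ValueError("target_sensitivity must be in (0, 1)")
    if resolution_mb <= 0:
        raise ValueError("resolution_mb must be positive")
    T = int(round(genome_mb / (resolution_mb / 3.0)))
    rng = np.random.default_rng(seed)
    n = granularity
    while n <= max_per_bin:
        cfg = SimulationConfig(
            n_molecules=float(n) * T, fetal_fraction=f, direction=d,
            n_bins=T, affected_bins=k, threshold=threshold,
            replicates=replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        res = simulate_sensitivity(cfg)
        analytic = analytic_sensitivity(n, f, k, threshold)
        if abs(res.sensitivity - target_sensitivity) <= 3.0 * max(res.se, 1e-12):
            ok = analytic >= target_sensitivity
        else:
            ok = res.sensitivity >= target_sensitivity
        if ok:
            return RequiredDepth(per_bin=n, total=float(n) * T, n_bins=T,
                                 sensitivity=res.sensitivity)
        n += granularity
    raise RuntimeError("target sensitivity unreachable below max_per_bin")
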