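# Methods

## Model

Plasma cfDNA from a pregnant woman is modelled as an admixture: a
fraction 1 − f of molecules from the maternal genome and f from the
fetal (placental) genome. For a genomic region where the fetus carries a
single-copy aberration of direction d (−1 deletion, +1 duplication) and
the mother is diploid, the expected share of sequenced molecules
mapping to a bin of that region is

    E = (1 − f)/T + f·(2 + d)/(2T) = (1 + f·d/2)/T,

with T bins tiling the genome. Everything in the package follows from
this dosage relation: the z-score pipeline detects the (f/2)-sized
depth shift, the fetal-fraction estimator inverts it, and the power
simulation asks how many molecules are needed before the shift clears a
noise threshold.

## Pipeline stages and the choices behind them

**Fragment filters.** Same-chromosome, inward-facing (FR) read pairs
with insert ≤ 600 bp; optional per-read mismatch cap (default 2) when an
NM tag or TSV column is present; duplicates are pairs with identical
(chromosome, start, end). Counting is once per fragment (pair), not per
read, in the bin containing the leftmost coordinate — a single,
deterministic assignment rule; the alternative (midpoint) differs only
for the ~0.2% of fragments straddling a 100-kb boundary. No
mapping-quality filter is applied by default; a flag exists.

**Bin grids.** 0-based half-open coordinates. Fine bins of 100 kb for GC
correction, merged by summation into 1-Mb analysis bins. Trailing
partial bins (fine and coarse) are kept in the data structures but
masked from analysis: their counts are not comparable to full-width
bins. Bins whose N-base fraction exceeds 0.34 are masked as well; on a
real genome this removes centromeric/telomeric gaps and makes the
usable-bin count data-driven rather than hard-coded. A coarse bin is
masked when any member fine bin is masked (a fractional threshold is
available).

**GC correction.** LOWESS of raw count on GC over usable non-zero bins
(span 0.3, 2 robustness iterations), applied additively and recentred on
the genome-wide median raw count; negative values clamp to zero. The
additive median-recentred form approximately preserves the total count
(to well under 1% at realistic per-bin depths), so downstream GR values
are comparable before/after correction; the median (not the mean) is
used so that a real CNV region cannot drag the recentring level. Bins
with GC outside the fitted range take the nearest fitted value. Span
and form are configurable; neither is sharply determined — any smooth
monotone-flexible fit of count vs GC behaves equivalently here.

**Genomic representation and z-scores.** GR_i = count_i / total over
*usable* bins, so ΣGR = 1 on the analyzed set. Per-chromosome median
correction (subtract the median GR of each chromosome's usable bins) is
applied identically to the test sample and to every reference sample
before panel statistics are formed — applying it to one side only would
put numerator and denominator of the z-score on different scales. Panel
SD uses the n−1 denominator (panels are small; 8 by default). Bins
masked in any panel sample, or with zero panel SD, are masked. z-scores
are not re-standardized genome-wide: the ±3 interval is used at face
value, implying a ~0.3% per-bin chance rate (2·Φ(−3) ≈ 0.0027).

**Calling.** Maximal runs of ≥ 3 consecutive usable bins with z strictly
beyond ±3, all in one direction, within one chromosome. z exactly at the
boundary is inside the reference interval. Masked bins terminate runs
rather than being skipped — skipping would let two distant sub-threshold
runs merge into a spurious call. Overlapping qualifying windows merge
into a single maximal call, so a 31-bin event is one 31-Mb call, not 29
overlapping 3-bin calls.

**Fetal fraction.** For the bins fully covered by a call,
r_i = GR_test,i / meanGR_ref,i and r̄ = mean(r_i) (per-bin ratios, not a
ratio of sums — robust to unequal bin usability). GR is taken
GC-corrected but *not* median-corrected: a large aberration shifts its
own chromosome's median, and subtracting that would eat part of the
signal. The linear admixture model gives r̄ = (1 + d·f/2)/(1 + d·f·s/2),
where s = Σ meanGR_ref over the region is the region's share of the
genome — the denominator arises because GR is normalized by the sample
total, which the aberration itself perturbs. The estimator inverts this
exactly:

    f = 2·d·(r̄ − 1) / (1 − r̄·s),

reported as a percentage. For a real genome s is ~10⁻³ and the formula
coincides with the plain f = 2·d·(r̄ − 1) to ~0.2%; on the compact
synthetic genomes used for testing (where a 5-Mb implant is several
percent of the genome) the correction removes an otherwise visible
shrinkage of the estimate. An estimate near 100% (ratio ≈ 1.5) means
the *mother* carries the aberration; the estimate is then a genotype
signature, not a fetal fraction. A consistency flag records whether the
sign of r̄ − 1 matches the call direction.

## Power simulation

Idealized by construction: no GC bias, mappability structure or panel
noise, so its sensitivities are upper bounds for real data. Per-bin
counts are independent Binomial(N, E) draws (independence error vs a
joint multinomial is O(1/T)); each is standardized by the *exact* null
moments N/T and √(N·(1/T)(1 − 1/T)), not an empirical SD — at 1,000
replicates the empirical alternative converges to the same values while
adding noise. An affected replicate is detected when all k = 3 affected
bins clear the threshold in the aberration's direction; a null replicate
is a false positive when any ≥ 3-run of same-direction outliers occurs
among its T bins.

A normal-approximation closed form,
sensitivity ≈ Φ((f/2)·√n_bin − 3)³ with n_bin molecules per bin, serves
as an independent oracle. The depth search ascends in steps of 1,000
molecules per bin (matching the precision at which such depth
requirements are usefully quoted) and simulates each candidate at
10,000 replicates; when the simulated estimate falls within 3
Monte-Carlo SEs of the target, the decision defers to the closed form,
which is deterministic — without this, a candidate whose true
sensitivity sits within noise of the target (as 42,000/bin does at the
95% target) would be accepted or rejected by luck. Diagnostic
resolution maps to bin count via bin size = resolution/3 over a
3,000-Mb genome: T = 3,000, 4,500, 9,000 bins at 3, 2, 1 Mb.

At 150 million molecules and f = 5% the simulated sensitivity is ~98–99%,
slightly above the ~96% sometimes quoted for this regime; the package
treats published operating points as lower bounds for the idealized
model, which its own simulations clear.

## Synthetic data generator

Emulates exactly the structure the pipeline assumes: per-fine-bin GC
drawn once per genome from a Beta(2,2) spread on [0.30, 0.60] (shared
across all samples of a cohort, as a reference genome is); a linear
multiplicative GC sampling bias 1 + c·(gc − 0.45) with c = 1 by default
and 5% relative per-sample jitter (library-to-library variation); bin
dosages from implants — fetal carrier 1 + f·d/2, maternal 1 + (1−f)·d/2,
both 1 + d/2 — overlap-weighted at implant edges; per-bin totals
multinomial over the biased shares; fragment starts uniform within
bins; lengths ~N(166, 40²) clipped to (20, 600].

Default study conditions, fixed once: a 90.3-Mb three-chromosome toy
genome (35 + 30 + 25.3 Mb — large relative to Mb-scale implants, so a
region's genomic share stays small, while keeping runtimes at seconds);
1.3 million fragments per sample, i.e. ~14,000 per 1-Mb bin, chosen by
a power argument: at f = 10% a fetus-only deletion shifts an affected
bin by 0.05·√14,000 ≈ 5.9 null SDs, putting per-bin detection near
99.7% and making end-to-end recovery tests informative about
correctness rather than about marginal power. A reference panel of 8
normals mirrors common practice for small NIPT panels.

What the generator does **not** model: nucleosome-driven coverage
waves, fragment-size selection biology, sequencing error, mappability
holes, maternal CNVs outside explicit implants. Tests passing on this
generator demonstrate the statistical correctness of the pipeline, not
robustness to those artefacts.

## Numerical details

- LOWESS evaluated via sorted-fit + linear interpolation; outside the
  fitted GC range the nearest fitted value is used.
- GR totals, medians and panel moments use float64 throughout; GR sums
  reproduce 1.0 to ~1e-15.
- Degenerate inputs: all-identical GC → correction no-op with warning;
  identical panel profiles → all bins masked (zero SD) with warning;
  chromosome with no usable bins → its bins masked; zero usable total →
  error.
- Determinism: every stochastic component takes a NumPy Generator or
  integer seed; same seed + config gives byte-identical TSV/JSON
  outputs.

## Known limitations

- The caller is a run detector, not a segmenter: events separated by a
  single masked or sub-threshold bin are reported as two calls.
- Fetal-fraction estimates assume the reference panel mean GR is an
  unbiased diploid baseline for the called region; a common CNV present
  in the panel biases the estimate.
- The chrY-based fetal-fraction comparator is out of scope; the report
  schema leaves a `chry_fetal_percent` hook for an external value.
- Whole-chromosome aneuploidy scoring is intentionally absent; the
  per-chromosome median correction in fact suppresses whole-chromosome
  signals by design.
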