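import numpy as np
import pytest

from plasmakaryo.cna_calling import AberrationCall
from plasmakaryo.fetal_fraction import (bins_fully_covered,
                                        estimate_fetal_fraction)
from plasmakaryo.genome_model import Genome, build_bins
from plasmakaryo.representation import GRProfile, ReferencePanel

MB = 1_000_000


def make_setup(ratios, direction, n_total=600):
    """A toy profile/panel pair whose per-bin GR ratios equal ``ratios``.

    With ``n_total`` bins the aberration's genomic share is
    len(ratios)/n_total; large n_total approximates the genome-scale
    regime where the estimator reduces to f = 2 d (ratio - 1).
    """
    k = len(ratios)
    grid = build_bins(Genome.from_dict({"chr1": n_total * MB}), MB)
    mask = np.ones(n_total, bool)
    ref_gr = np.full(n_total, 1.0 / n_total)
    test_gr = ref_gr.copy()
    test_gr[1:1 + k] = ref_gr[1:1 + k] * np.asarray(ratios)
    panel = ReferencePanel(grid, 8, np.zeros(n_total), np.full(n_total, 1e-5),
                           ref_gr, mask)
    profile = GRProfile(grid, test_gr, mask)
    call = AberrationCall("chr1", MB, (1 + k) * MB, 1, k,
                          direction, 0.0, 0.0, 0.0)
    return profile, panel, call


class TestEstimator:
    def test_no_deviation_gives_zero(self):
        profile, panel, call = make_setup([1.0, 1.0, 1.0], -1)
        est = estimate_fetal_fraction(profile, panel, call)
        assert est.percent == pytest.approx(0.0)

    def test_deletion_ratio_095_gives_ten_percent(self):
        # fetus-only single-copy loss: GR ratio = 1 - f/2
        profile, panel, call = make_setup([0.95] * 4, -1)
        est = estimate_fetal_fraction(profile, panel, call)
        assert est.percent == pytest.approx(10.0, abs=0.1)
        assert est.consistent and est.n_bins == 4

    def test_duplication_ratio_105_gives_ten_percent(self):
        profile, panel, call = make_setup([1.05] * 3, +1)
        est = estimate_fetal_fraction(profile, panel, call)
        assert est.percent == pytest.approx(10.0, abs=0.1)

    @pytest.mark.parametrize("f,d,share_bins,n_total", [
        (0.10, -1, 5, 100), (0.10, +1, 5, 100),
        (0.20, -1, 5, 50), (0.05, +1, 3, 1000),
    ])
    def test_exact_inversion_of_the_admixture_balance(self, f, d,
                                                      share_bins, n_total):
        # forward model: ratio = (1 + d f/2) / (1 + d f s / 2) with
        # s the region's genomic share; the estimator must invert it exactly
        s = share_bins / n_total
        ratio = (1 + d * f / 2) / (1 + d * f * s / 2)
        profile, panel, call = make_setup([ratio] * share_bins, d, n_total)
        est = estimate_fetal_fraction(profile, panel, call)
        assert est.percent == pytest.approx(100 * f, abs=1e-9)

    def test_maternal_carrier_signature_large_estimate(self):
        # ratio ~1.5 would mean f ~100%: a maternal, not fetal, aberration
        profile, panel, call = make_setup([1.48] * 3, +1)
        est = estimate_fetal_fraction(profile, panel, call)
        assert est.percent == pytest.approx(96.0, abs=1.0)
        assert est.consistent

    def test_inconsistent_direction_flagged(self):
        profile, panel, call = make_setup([1.05] * 3, -1)
        est = estimate_fetal_fraction(profile, panel, call)
        assert not est.consistent

    def test_ratios_averaged_per_bin(self):
        profile, panel, call = make_setup([0.94, 0.95, 0.96], -1)
        est = estimate_fetal_fraction(profile, panel, call)
        assert est.percent == pytest.approx(10.0, abs=0.1)

    def test_unusable_region_raises(self):
        profile, panel, call = make_setup([0.95] * 3, -1)
        panel.mask[:] = False
        with pytest.raises(ValueError):
            estimate_fetal_fraction(profile, panel, call)


class TestFullyCoveredBins:
    def test_partial_overlap_bins_excluded(self):
        grid = build_bins(Genome.from_dict({"chr1": 10 * MB}), MB)
        idx = bins_fully_covered(grid, "chr1", int(1.5 * MB), int(5.5 * MB))
        assert idx.tolist() == [2, 3, 4]

    def test_exact_bin_span(self):
        grid = build_bins(Genome.from_dict({"chr1": 10 * MB}), MB)
        idx = bins_fully_covered(grid, "chr1", 2 * MB, 5 * MB)
        assert idx.tolist() == [2, 3, 4]


def region_call(grid, chrom, start, end, direction):
    """An AberrationCall covering a known region (for estimator-only tests)."""
    idx = bins_fully_covered(grid, chrom, start, end)
    return AberrationCall(chrom, start, end, int(idx[0]), idx.size,
                          direction, 0.0, 0.0, 0.0)


class TestRoundTrip:
    @pytest.mark.parametrize("f0", [0.05, 0.10, 0.20])
    def test_recovers_generating_fetal_fraction(self, f0, cohort, params):
        """Average estimate over 20 replicates is within 1.5 points of truth.

        Synthetic samples carry a 5-bin fetal deletion at fetal fraction f0;
        the estimator is evaluated on the implanted region against the
        shared normal panel.
        """
        from plasmakaryo.pipeline import sample_gr_profile
        from plasmakaryo.synthetic_data import Implant, generate_sample
        import dataclasses
        spec = dataclasses.replace(
            cohort["spec"], fetal_fraction=f0,
            implants=(Implant("chr1", 10 * MB, 15 * MB, -1, "fetal"),))
        rng = np.random.default_rng(200 + int(f0 * 100))
        coarse = cohort["panel"].grid
        call = region_call(coarse, "chr1", 10 * MB, 15 * MB, -1)
        estimates = []
        for _ in range(20):
            frame, _ = generate_sample(spec, rng=rng)
            profile = sample_gr_profile(frame, cohort["grid"], cohort["gc"],
                                        params)
            est = estimate_fetal_fraction(profile, cohort["panel"], call)
            estimates.append(est.percent)
        assert np.mean(estimates) == pytest.approx(100 * f0, abs=1.5)

    def test_deletion_and_duplication_estimates_agree(self, cohort, params):
        """Dual aberrations in one sample give concordant f estimates."""
        from plasmakaryo.pipeline import sample_gr_profile
        from plasmakaryo.synthetic_data import Implant, generate_sample
        import dataclasses
        spec = dataclasses.replace(
            cohort["spec"], fetal_fraction=0.12,
            implants=(Implant("chr1", 5 * MB, 10 * MB, -1, "fetal"),
                      Implant("chr2", 8 * MB, 13 * MB, +1, "fetal")))
        rng = np.random.default_rng(77)
        coarse = cohort["panel"].grid
        del_call = region_call(coarse, "chr1", 5 * MB, 10 * MB, -1)
        dup_call = region_call(coarse, "chr2", 8 * MB, 13 * MB, +1)
        diffs = []
        for _ in range(5):
            frame, _ = generate_sample(spec, rng=rng)
            profile = sample_gr_profile(frame, cohort["grid"], cohort["gc"],
                                        params)
            f_del = estimate_fetal_fraction(profile, cohort["panel"], del_call)
            f_dup = estimate_fetal_fraction(profile, cohort["panel"], dup_call)
            diffs.append(f_dup.percent - f_del.percent)
        assert abs(np.mean(diffs)) < 2.0
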