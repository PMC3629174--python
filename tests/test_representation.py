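import numpy as np
import pytest

from plasmakaryo.fragment_ingest import BinCounts
from plasmakaryo.gc_correction import CorrectedCounts
from plasmakaryo.genome_model import Genome, build_bins
from plasmakaryo.representation import (GRProfile, build_reference,
                                        genomic_representation,
                                        median_correct, merge_bins, zscores)


def grid_for(lengths, width):
    return build_bins(Genome.from_dict(lengths), width)


def corrected(grid, values, mask=None):
    m = np.ones(grid.n_bins, bool) if mask is None else np.asarray(mask, bool)
    vals = np.where(m, np.asarray(values, float), np.nan)
    return CorrectedCounts(grid, vals, m)


class TestMergeBins:
    def test_sums_members(self):
        grid = grid_for({"chrA": 1_000_000}, 100_000)
        counts, mask, _ = merge_bins(corrected(grid, np.full(10, 500)), 10)
        assert counts.counts.tolist() == [5000.0]
        assert mask.tolist() == [True]

    def test_factor_one_identity(self):
        grid = grid_for({"chrA": 500_000}, 100_000)
        vals = np.array([1.0, 2, 3, 4, 5])
        counts, mask, f2c = merge_bins(corrected(grid, vals), 1)
        assert np.array_equal(counts.counts, vals)
        assert np.array_equal(f2c, np.arange(5))

    def test_any_masked_member_masks_coarse_bin(self):
        grid = grid_for({"chrA": 2_000_000}, 100_000)
        m = np.ones(20, bool)
        m[3] = False
        _, mask, _ = merge_bins(corrected(grid, np.full(20, 10.0), m), 10)
        assert mask.tolist() == [False, True]

    def test_fraction_mask_policy(self):
        grid = grid_for({"chrA": 2_000_000}, 100_000)
        m = np.ones(20, bool)
        m[3] = False
        _, mask, _ = merge_bins(corrected(grid, np.full(20, 10.0), m), 10,
                                mask_policy=0.2)
        assert mask.tolist() == [True, True]

    def test_partial_coarse_bin_masked_by_default(self):
        grid = grid_for({"chrA": 1_300_000}, 100_000)
        _, mask, _ = merge_bins(corrected(grid, np.full(13, 10.0)), 10)
        assert mask.tolist() == [True, False]
        _, mask, _ = merge_bins(corrected(grid, np.full(13, 10.0)), 10,
                                mask_partial=False)
        assert mask.tolist() == [True, True]


class TestGenomicRepresentation:
    def test_direct_division(self):
        grid = grid_for({"chrA": 3_000_000}, 1_000_000)
        prof = genomic_representation(BinCounts(grid, np.array([30, 50, 20])),
                                      np.ones(3, bool))
        assert np.allclose(prof.gr, [0.30, 0.50, 0.20])

    def test_uniform_counts_give_one_over_T(self):
        grid = grid_for({"chrA": 8_000_000}, 1_000_000)
        prof = genomic_representation(BinCounts(grid, np.full(8, 123)),
                                      np.ones(8, bool))
        assert np.allclose(prof.gr, 1 / 8)

    def test_sums_to_one_over_usable_bins(self):
        grid = grid_for({"chrA": 10_000_000}, 1_000_000)
        rng = np.random.default_rng(0)
        mask = np.ones(10, bool)
        mask[[2, 7]] = False
        prof = genomic_representation(
            BinCounts(grid, rng.integers(100, 1000, 10)), mask)
        assert np.nansum(prof.gr) == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(prof.gr[2])

    def test_zero_total_raises(self):
        grid = grid_for({"chrA": 2_000_000}, 1_000_000)
        with pytest.raises(ValueError):
            genomic_representation(BinCounts(grid, np.zeros(2, int)),
                                   np.ones(2, bool))


class TestMedianCorrect:
    def test_equal_bins_zero_deviation(self):
        grid = grid_for({"chrA": 4_000_000}, 1_000_000)
        dev = median_correct(np.full(4, 2e-4), grid, np.ones(4, bool))
        assert np.allclose(dev, 0.0)

    def test_odd_length_median(self):
        grid = grid_for({"chrA": 5_000_000}, 1_000_000)
        gr = np.array([1, 2, 3, 4, 5]) * 1e-4
        dev = median_correct(gr, grid, np.ones(5, bool))
        assert np.allclose(dev, np.array([-2, -1, 0, 1, 2]) * 1e-4)

    def test_no_crosstalk_between_chromosomes(self):
        grid = grid_for({"chrA": 3_000_000, "chrB": 3_000_000}, 1_000_000)
        gr = np.array([1, 2, 3, 10, 20, 30], float)
        mask = np.ones(6, bool)
        dev = median_correct(gr, grid, mask)
        # brute-force per-chromosome medians: 2 and 20
        assert np.allclose(dev, [1 - 2, 0, 1, -10, 0, 10])
        # per-chromosome median deviation is exactly zero
        assert np.median(dev[:3]) == 0.0 and np.median(dev[3:]) == 0.0

    def test_chromosome_without_usable_bins_stays_masked(self):
        grid = grid_for({"chrA": 2_000_000, "chrB": 2_000_000}, 1_000_000)
        mask = np.array([True, True, False, False])
        dev = median_correct(np.array([1.0, 2, 3, 4]), grid, mask)
        assert np.isnan(dev[2]) and np.isnan(dev[3])


class TestReferencePanel:
    def test_hand_computed_mean_and_sd(self):
        # two-bin chromosomes so median correction leaves +/- deviations
        grid2 = grid_for({"chrA": 2_000_000, "chrB": 2_000_000}, 1_000_000)
        mask2 = np.ones(4, bool)
        # bin 0 deviations across the two samples: 0.001 and 0.003
        p1 = GRProfile(grid2, np.array([0.251, 0.249, 0.25, 0.25]), mask2)
        p2 = GRProfile(grid2, np.array([0.253, 0.247, 0.25, 0.25]), mask2)
        panel = build_reference([p1, p2])
        assert panel.mean_dev[0] == pytest.approx(0.002)
        assert panel.sd_dev[0] == pytest.approx(0.0014142, abs=1e-6)

    def test_identical_profiles_mask_everything(self):
        grid = grid_for({"chrA": 3_000_000}, 1_000_000)
        prof = GRProfile(grid, np.array([0.3, 0.4, 0.3]), np.ones(3, bool))
        with pytest.warns(UserWarning, match="zero panel SD"):
            panel = build_reference([prof, prof])
        assert not panel.mask.any()

    def test_requires_two_samples_and_matching_grids(self):
        grid = grid_for({"chrA": 3_000_000}, 1_000_000)
        prof = GRProfile(grid, np.array([0.3, 0.4, 0.3]), np.ones(3, bool))
        with pytest.raises(ValueError):
            build_reference([prof])
        other = GRProfile(grid_for({"chrA": 2_000_000}, 1_000_000),
                          np.array([0.5, 0.5]), np.ones(2, bool))
        with pytest.raises(ValueError):
            build_reference([prof, other])

    def test_synthetic_panel_has_few_masked_bins(self, cohort):
        panel = cohort["panel"]
        frac_masked = 1 - panel.mask.mean()
        assert frac_masked < 0.05

    def test_roundtrip_tsv(self, cohort, tmp_path):
        panel = cohort["panel"]
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        back = type(panel).from_tsv(path)
        assert back.n_samples == panel.n_samples
        assert np.allclose(back.mean_dev, panel.mean_dev, equal_nan=True)
        assert np.allclose(back.sd_dev, panel.sd_dev, equal_nan=True)
        assert np.array_equal(back.mask, panel.mask)


class TestZscores:
    def test_direct_formula(self):
        grid = grid_for({"chrA": 2_000_000, "chrB": 2_000_000}, 1_000_000)
        mask = np.ones(4, bool)
        # test deviations on chrA: +/-0.0004 around the median
        test = GRProfile(grid, np.array([0.2504, 0.2496, 0.25, 0.25]), mask)
        panel = build_reference([
            GRProfile(grid, np.array([0.2501, 0.2499, 0.2501, 0.2499]), mask),
            GRProfile(grid, np.array([0.2503, 0.2497, 0.2503, 0.2497]), mask),
        ])
        # panel bin-0 deviations {0.0001, 0.0003}: mean 0.0002, sd ~0.00014142
        z, zmask = zscores(test, panel)
        dev0 = 0.0004  # test deviation in bin 0
        expected = (dev0 - 0.0002) / panel.sd_dev[0]
        assert z[0] == pytest.approx(expected)
        assert zmask.all()

    def test_zero_when_test_matches_panel_mean(self):
        grid = grid_for({"chrA": 2_000_000}, 1_000_000)
        mask = np.ones(2, bool)
        p1 = GRProfile(grid, np.array([0.52, 0.48]), mask)
        p2 = GRProfile(grid, np.array([0.56, 0.44]), mask)
        test = GRProfile(grid, np.array([0.54, 0.46]), mask)
        z, _ = zscores(test, build_reference([p1, p2]))
        assert np.allclose(z, 0.0)

    def test_leave_one_out_null_calibration(self, cohort, params):
        """A panel member scored against the remaining panel looks null."""
        from plasmakaryo.pipeline import (build_panel_from_frames,
                                          sample_gr_profile)
        frames = cohort["panel_frames"]
        held_out = sample_gr_profile(frames[0], cohort["grid"], cohort["gc"],
                                     params)
        rest = build_panel_from_frames(frames[1:], cohort["grid"], cohort["gc"],
                                       params)
        z, mask = zscores(held_out, rest)
        zz = z[mask]
        assert abs(zz.mean()) < 0.3
        assert 0.5 < zz.std() < 2.0
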