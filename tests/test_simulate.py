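import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shallowcna.grid import build_grid, hg19_grid
from shallowcna.noise import first_order_variance
from shallowcna.preprocess import bin_reads
from shallowcna.simulate import (
    BiasModel,
    TruthCNA,
    get_preset,
    loucy_truth,
    sigma_for_target_variance,
    simulate_counts,
    simulate_gc_track,
    simulate_mappability_track,
    simulate_reads,
    truth_copy_number,
)


class TestLoucyTruth:
    def test_seven_aberrations_with_expected_sizes(self):
        truth = loucy_truth(hg19_grid())
        assert len(truth) == 7
        by_key = {(t.chrom, t.copy_number): t for t in truth}
        assert by_key[("chr5", 1)].length == 72_000_000
        assert by_key[("chr6", 1)].length == 45_000_000
        assert by_key[("chr9", 1)].length == 2_500_000
        assert by_key[("chr13", 3)].copy_number == 3
        assert by_key[("chr13", 3)].length == 3_000_000
        chr16 = sorted((t for t in truth if t.chrom == "chr16"), key=lambda t: t.start)
        assert [t.length for t in chr16] == [13_000_000, 3_000_000]
        x = by_key[("chrX", 1)]
        assert (x.start, x.end) == (0, 155_270_560)  # whole-chromosome monosomy

    def test_missing_chromosome_rejected(self):
        grid = build_grid([("chr5", 180_000_000)])
        with pytest.raises(ValueError, match="chr6"):
            loucy_truth(grid)


class TestTruthCNA:
    @pytest.mark.parametrize("start,end,cn", [(5, 5, 1), (10, 5, 1), (0, 10, 2), (0, 10, -1)])
    def test_invalid_records_rejected(self, start, end, cn):
        with pytest.raises(ValueError):
            TruthCNA("chr1", start, end, cn)

    def test_overlapping_truth_rejected(self, two_chrom_grid):
        truth = [TruthCNA("chrA", 0, 3_000_000, 1), TruthCNA("chrA", 2_000_000, 5_000_000, 3)]
        with pytest.raises(ValueError, match="overlap"):
            truth_copy_number(two_chrom_grid, truth)

    def test_partial_overlap_is_area_weighted(self, two_chrom_grid):
        truth = [TruthCNA("chrA", 250_000, 2_750_000, 1)]  # 0.75 / 1.0 / 0.75 bin coverage
        cn = truth_copy_number(two_chrom_grid, truth)
        assert cn[:3] == pytest.approx([1.25, 1.0, 1.25])
        assert np.all(cn[3:] == 2.0)


class TestSimulateCounts:
    def test_poisson_only_matches_counting_floor(self):
        grid = build_grid([("chr1", 2000_000_000)])  # 2000 bins
        bias = BiasModel(mean_depth=4000, sigma_log=0.0, seed=3)
        counts = simulate_counts(grid, [], bias)
        assert counts.mean() == pytest.approx(4000, rel=0.01)
        v = first_order_variance(counts).v
        # 1/N with sampling tolerance ~ sqrt(2/n)/N
        assert v == pytest.approx(1 / 4000, rel=0.15)

    def test_copy_number_linearity(self):
        grid = build_grid([("chr1", 400_000_000)])
        truth = [TruthCNA("chr1", 100_000_000, 200_000_000, 1),
                 TruthCNA("chr1", 200_000_000, 300_000_000, 3)]
        counts = simulate_counts(grid, truth, BiasModel(mean_depth=4000, seed=4))
        # regional means scale as cn/2 within 3 standard errors (SE = sqrt(N/n))
        se = math.sqrt(4000 / 100)
        assert abs(counts[:100].mean() - 4000) < 3 * se
        assert abs(counts[100:200].mean() - 2000) < 3 * se
        assert abs(counts[200:300].mean() - 6000) < 3 * se

    def test_calibrated_sigma_reproduces_target_variance(self):
        """sigma_for_target_variance inverts the first-order estimator."""
        grid = build_grid([("chr1", 2878_000_000)])
        sigma = sigma_for_target_variance(0.077, 4000)
        assert sigma == pytest.approx(0.272, abs=0.001)
        vs = [
            first_order_variance(
                simulate_counts(grid, [], BiasModel(4000, sigma, seed=10 + r))
            ).v
            for r in range(8)
        ]
        assert np.mean(vs) == pytest.approx(0.077, rel=0.05)

    def test_variance_increases_with_sigma(self):
        """Expected first-order variance is strictly monotone in sigma_log."""
        grid = build_grid([("chr1", 1500_000_000)])
        means = []
        for sigma in (0.1, 0.25, 0.4):
            vs = [
                first_order_variance(
                    simulate_counts(grid, [], BiasModel(4000, sigma, seed=50 + r))
                ).v
                for r in range(25)
            ]
            means.append(np.mean(vs))
        assert means[0] < means[1] < means[2]

    def test_reproducible_given_seed(self, two_chrom_grid):
        bias = BiasModel(mean_depth=100, sigma_log=0.3, rho=0.5, seed=9)
        a = simulate_counts(two_chrom_grid, [], bias)
        b = simulate_counts(two_chrom_grid, [], bias)
        assert np.array_equal(a, b)

    def test_gc_slope_requires_track(self, two_chrom_grid):
        with pytest.raises(ValueError, match="gc_track"):
            simulate_counts(two_chrom_grid, [], BiasModel(100, gc_slope=0.5))


class TestSimulateReads:
    def test_all_zero_counts_give_empty_bed(self, two_chrom_grid):
        reads = simulate_reads(two_chrom_grid, np.zeros(two_chrom_grid.n_bins, dtype=int))
        assert len(reads) == 0

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=18, max_size=18))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rebinning_recovers_counts_exactly(self, counts):
        grid = build_grid([("chrA", 10_000_000), ("chrB", 8_500_000)])
        counts = np.asarray(counts)
        reads = simulate_reads(grid, counts, seed=2)
        track, skipped = bin_reads(grid, reads)
        assert skipped == 0
        assert np.array_equal(track.values, counts)

    def test_negative_counts_rejected(self, two_chrom_grid):
        bad = np.zeros(two_chrom_grid.n_bins, dtype=int)
        bad[0] = -1
        with pytest.raises(ValueError, match="negative"):
            simulate_reads(two_chrom_grid, bad)


class TestTracksAndPresets:
    def test_track_ranges(self, two_chrom_grid):
        gc = simulate_gc_track(two_chrom_grid, seed=0)
        mp = simulate_mappability_track(two_chrom_grid, seed=0)
        assert np.all((gc >= 0) & (gc <= 1))
        assert np.all((mp >= 0) & (mp <= 1))

    def test_known_presets_calibrated(self):
        assert get_preset("sureplex-3cell").sigma_log == pytest.approx(0.272, abs=0.001)
        assert get_preset("malbac-3cell").sigma_log == pytest.approx(0.359, abs=0.001)
        assert get_preset("flat").sigma_log == 0.0

    def test_unknown_preset_lists_options(self):
        with pytest.raises(KeyError, match="sureplex-3cell"):
            get_preset("nope")
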