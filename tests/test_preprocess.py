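import numpy as np
import pandas as pd
import pytest

from shallowcna.grid import build_grid
from shallowcna.noise import first_order_variance
from shallowcna.preprocess import (
    BinTrack,
    bin_reads,
    correct_mappability,
    gc_correct,
    median_normalize,
    preprocess_counts,
)
from shallowcna.simulate import BiasModel, simulate_counts, simulate_gc_track


class TestBinReads:
    def test_empty_input_gives_zero_track(self, two_chrom_grid):
        track, skipped = bin_reads(two_chrom_grid, [])
        assert np.all(track.values == 0) and skipped == 0

    def test_half_open_convention(self, two_chrom_grid):
        """A read starting at 1,500,000 belongs to the second bin; one at
        exactly 1,000,000 also does (bin intervals are half-open)."""
        track, _ = bin_reads(two_chrom_grid, [("chrA", 1_500_000), ("chrA", 1_000_000)])
        assert track.values[1] == 2
        assert track.values.sum() == 2

    def test_conservation_and_skip_tally(self, two_chrom_grid, rng):
        starts = rng.integers(0, 10_000_000, size=1000)
        reads = pd.DataFrame({"chrom": "chrA", "start": starts})
        unknown = pd.DataFrame({"chrom": ["chrZ"], "start": [5]})
        beyond = pd.DataFrame({"chrom": ["chrB"], "start": [8_400_000]})  # past last full bin
        track, skipped = bin_reads(two_chrom_grid, pd.concat([reads, unknown, beyond]))
        assert track.values.sum() == 1000
        assert skipped == 2


class TestMappability:
    def test_identity_when_mappability_one(self, two_chrom_grid):
        track = BinTrack.from_values(two_chrom_grid, np.arange(18.0))
        out = correct_mappability(track, np.ones(18))
        assert np.array_equal(out.values, track.values)
        assert out.mask.all()

    def test_division_and_masking(self, two_chrom_grid):
        values = np.full(18, 50.0)
        m = np.ones(18)
        m[2] = 0.5   # corrected
        m[3] = 0.1   # below threshold -> masked
        out = correct_mappability(BinTrack.from_values(two_chrom_grid, values), m, 0.5)
        assert out.values[2] == 100.0
        assert not out.mask[3]
        # masked bin is excluded from the downstream median
        prof = median_normalize(out)
        assert np.median(prof.ratios[prof.mask]) == 1.0

    def test_out_of_range_mappability_rejected(self, two_chrom_grid):
        track = BinTrack.from_values(two_chrom_grid, np.ones(18))
        with pytest.raises(ValueError):
            correct_mappability(track, np.full(18, 1.5))


class TestGCCorrect:
    @pytest.fixture
    def big_grid(self):
        return build_grid([("chr1", 1000_000_000)])

    def test_constant_gc_is_identity(self, big_grid, rng):
        values = rng.poisson(1000, big_grid.n_bins).astype(float)
        out = gc_correct(BinTrack.from_values(big_grid, values), np.full(big_grid.n_bins, 0.4123))
        assert out.values == pytest.approx(values, rel=1e-9)

    def test_removes_exponential_gc_tilt(self, big_grid):
        gc = simulate_gc_track(big_grid, seed=7)
        bias = BiasModel(mean_depth=4000, gc_slope=0.5, seed=7)
        counts = simulate_counts(big_grid, [], bias, gc_track=gc).astype(float)
        before = np.corrcoef(counts, gc)[0, 1]
        out = gc_correct(BinTrack.from_values(big_grid, counts), gc)
        after = np.corrcoef(out.values, gc)[0, 1]
        assert abs(before) > 0.3          # the tilt was real
        assert abs(after) < 0.05          # and the LOESS removed it

    def test_total_count_neutral(self, big_grid, rng):
        gc = simulate_gc_track(big_grid, seed=8)
        counts = rng.poisson(np.exp(0.8 * (gc - gc.mean())) * 2000).astype(float)
        mask = rng.random(big_grid.n_bins) > 0.05
        track = BinTrack(grid=big_grid, values=counts, mask=mask)
        out = gc_correct(track, gc)
        assert out.values[mask].sum() == pytest.approx(counts[mask].sum(), rel=1e-6)

    def test_skipped_below_min_bins(self, two_chrom_grid, rng):
        values = rng.poisson(100, 18).astype(float)
        track = BinTrack.from_values(two_chrom_grid, values)
        out = gc_correct(track, np.linspace(0.3, 0.6, 18))  # 18 < 100 usable bins
        assert np.array_equal(out.values, values)


class TestMedianNormalize:
    def test_constant_profile(self, two_chrom_grid):
        prof = median_normalize(BinTrack.from_values(two_chrom_grid, np.full(18, 7.0)))
        assert np.all(prof.ratios == 1.0)
        assert prof.N == 7.0

    def test_direct_median(self):
        grid = build_grid([("c", 3_000_000)])
        prof = median_normalize(BinTrack.from_values(grid, [1.0, 2.0, 3.0]))
        assert prof.ratios == pytest.approx([0.5, 1.0, 1.5])
        assert prof.N == 2.0

    def test_poisson_profile_median_one_mean_near_one(self, rng):
        grid = build_grid([("c", 2000_000_000)])
        counts = rng.poisson(4000, grid.n_bins).astype(float)
        prof = median_normalize(BinTrack.from_values(grid, counts))
        assert np.median(prof.ratios) == 1.0
        assert prof.ratios.mean() == pytest.approx(1.0, abs=0.01)

    def test_zero_median_is_error(self, two_chrom_grid):
        with pytest.raises(ValueError, match="median"):
            median_normalize(BinTrack.from_values(two_chrom_grid, np.zeros(18)))


class TestComposedPreprocess:
    def test_mask_is_hereditary(self, two_chrom_grid, rng):
        counts = rng.poisson(500, 18).astype(float)
        m = np.ones(18)
        m[[1, 7]] = 0.2
        prof = preprocess_counts(two_chrom_grid, counts, map_track=m)
        assert not prof.mask[1] and not prof.mask[7]

    def test_no_bias_pipeline_hits_counting_floor(self):
        """Composed preprocess of a no-CNA, no-bias simulation: mean-scaled
        variance matches 1/N within 3 SE over 25 replicates."""
        grid = build_grid([("chr1", 800_000_000)])
        gc = simulate_gc_track(grid, seed=11)
        vs = []
        for r in range(25):
            counts = simulate_counts(grid, [], BiasModel(mean_depth=1000, seed=600 + r), gc)
            prof = preprocess_counts(grid, counts, gc_track=gc, map_track=np.ones(grid.n_bins))
            vs.append(first_order_variance(prof).v)
        se = np.std(vs, ddof=1) / np.sqrt(len(vs))
        assert abs(np.mean(vs) - 1 / 1000) < 3 * se + 1e-5
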