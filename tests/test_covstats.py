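import numpy as np
import pytest

from ladpipe.core import GenomeLayout, Interval
from ladpipe.covstats import (
    average_profile,
    profile_matrix,
    site_flank_coverage,
    windowed_sum_comparison,
)
from ladpipe.tags import CoverageVector


def coverage_from_array(layout, chrom_arrays, bin_width):
    data = {c: np.asarray(a, dtype=float) for c, a in chrom_arrays.items()}
    return CoverageVector(data, bin_width, layout, normalized=True, scale=1.0)


@pytest.fixture
def small_layout():
    return GenomeLayout({"chr1": 10_000})


class TestProfileMatrix:
    def test_delta_coverage_hits_center_column(self, small_layout):
        arr = np.zeros(100)
        site = Interval("chr1", 4_000, 4_200)  # midpoint 4100, bin 41
        arr[41] = 7.0
        cov = coverage_from_array(small_layout, {"chr1": arr}, 100)
        mat = profile_matrix([site], cov, flank=1_000, nbins=20)  # 100bp profile bins
        nz = np.flatnonzero(mat.values[0])
        assert nz.tolist() == [10]  # [4100, 4200) is the 11th of 20 bins
        assert mat.values[0, 10] == pytest.approx(7.0 / 100)

    def test_constant_coverage_fills_matrix(self, small_layout):
        cov = coverage_from_array(small_layout, {"chr1": np.full(100, 5.0)}, 100)
        sites = [Interval("chr1", 4_000, 4_200), Interval("chr1", 6_000, 6_100)]
        mat = profile_matrix(sites, cov, flank=500, nbins=10)
        np.testing.assert_allclose(mat.values, 5.0 / 100)

    def test_rows_match_per_site_extraction(self, small_layout):
        rng = np.random.default_rng(5)
        arr = rng.random(100) * 10
        cov = coverage_from_array(small_layout, {"chr1": arr}, 100)
        sites = [Interval("chr1", int(s), int(s) + 100) for s in rng.integers(1_000, 9_000, 5)]
        mat = profile_matrix(sites, cov, flank=500, nbins=10)
        for i, site in enumerate(sites):
            left = site.midpoint - 500
            expected = [
                cov.window_sum("chr1", left + j * 100, left + (j + 1) * 100) / 100
                for j in range(10)
            ]
            np.testing.assert_allclose(mat.values[i], expected)

    def test_chromosome_edge_pads_with_zeros(self, small_layout):
        cov = coverage_from_array(small_layout, {"chr1": np.full(100, 3.0)}, 100)
        mat = profile_matrix([Interval("chr1", 0, 200)], cov, flank=1_000, nbins=20)
        # midpoint 100: bins left of the chromosome origin are zero
        assert mat.values[0, :9].sum() == 0
        assert mat.values[0, -1] == pytest.approx(3.0 / 100)

    def test_indivisible_window_rejected(self, small_layout):
        cov = coverage_from_array(small_layout, {"chr1": np.zeros(100)}, 100)
        with pytest.raises(ValueError, match="divide"):
            profile_matrix([Interval("chr1", 0, 100)], cov, flank=500, nbins=7)

    def test_row_sum_times_bin_width_equals_window_sum(self, small_layout):
        rng = np.random.default_rng(6)
        arr = rng.random(100) * 4
        cov = coverage_from_array(small_layout, {"chr1": arr}, 100)
        sites = [Interval("chr1", int(s), int(s) + 50) for s in rng.integers(2_000, 8_000, 8)]
        mat = profile_matrix(sites, cov, flank=1_000, nbins=40)
        _, frac = windowed_sum_comparison(sites, cov, cov, window=2_000)
        for i, site in enumerate(sites):
            direct = cov.window_sum("chr1", site.midpoint - 1_000, site.midpoint + 1_000)
            assert mat.values[i].sum() * mat.bin_width == pytest.approx(direct, rel=1e-6)


class TestAverageProfile:
    def test_single_row_identity(self, small_layout):
        cov = coverage_from_array(small_layout, {"chr1": np.arange(100.0)}, 100)
        mat = profile_matrix([Interval("chr1", 5_000, 5_100)], cov, flank=500, nbins=10)
        np.testing.assert_allclose(average_profile(mat), mat.values[0])

    def test_permutation_invariance(self, small_layout):
        rng = np.random.default_rng(7)
        cov = coverage_from_array(small_layout, {"chr1": rng.random(100)}, 100)
        sites = [Interval("chr1", int(s), int(s) + 100) for s in rng.integers(1_000, 9_000, 6)]
        m1 = profile_matrix(sites, cov, flank=500, nbins=10)
        m2 = profile_matrix(sites[::-1], cov, flank=500, nbins=10)
        np.testing.assert_allclose(average_profile(m1), average_profile(m2))

    def test_means_match_hand_computation(self, small_layout):
        rng = np.random.default_rng(8)
        cov = coverage_from_array(small_layout, {"chr1": rng.random(100)}, 100)
        sites = [Interval("chr1", int(s), int(s) + 100) for s in rng.integers(1_000, 9_000, 10)]
        mat = profile_matrix(sites, cov, flank=500, nbins=10)
        np.testing.assert_allclose(average_profile(mat), mat.values.sum(axis=0) / 10)

    def test_empty_matrix_rejected(self, small_layout):
        cov = coverage_from_array(small_layout, {"chr1": np.zeros(100)}, 100)
        mat = profile_matrix([], cov, flank=500, nbins=10)
        with pytest.raises(ValueError):
            average_profile(mat)

    def test_sorting_by_row_sum(self, small_layout):
        arr = np.zeros(100)
        arr[10] = 1.0
        arr[50] = 9.0
        cov = coverage_from_array(small_layout, {"chr1": arr}, 100)
        sites = [Interval("chr1", 1_000, 1_100), Interval("chr1", 5_000, 5_100)]
        mat = profile_matrix(sites, cov, flank=500, nbins=10).sorted_by_row_sum()
        assert mat.sites[0].start == 5_000


class TestWindowedComparison:
    def test_uniform_excess_in_A(self, small_layout):
        covA = coverage_from_array(small_layout, {"chr1": np.full(100, 2.0)}, 100)
        covB = coverage_from_array(small_layout, {"chr1": np.full(100, 1.0)}, 100)
        sites = [Interval("chr1", s, s + 100) for s in (2_000, 5_000, 8_000)]
        summaries, frac = windowed_sum_comparison(sites, covA, covB, window=2_000)
        assert frac == 1.0
        assert all(s.sum_young == pytest.approx(2 * s.sum_old) for s in summaries)

    def test_ties_count_as_not_higher(self, small_layout):
        cov = coverage_from_array(small_layout, {"chr1": np.full(100, 1.0)}, 100)
        sites = [Interval("chr1", 2_000, 2_100)]
        _, frac = windowed_sum_comparison(sites, cov, cov)
        assert frac == 0.0

    def test_swap_maps_to_strictly_higher_B(self, small_layout):
        rng = np.random.default_rng(9)
        covA = coverage_from_array(small_layout, {"chr1": rng.random(100)}, 100)
        covB = coverage_from_array(small_layout, {"chr1": rng.random(100)}, 100)
        sites = [Interval("chr1", int(s), int(s) + 100) for s in rng.integers(1_000, 9_000, 12)]
        sAB, fAB = windowed_sum_comparison(sites, covA, covB)
        sBA, fBA = windowed_sum_comparison(sites, covB, covA)
        strictly_b = sum(1 for s in sAB if s.sum_old > s.sum_young) / len(sites)
        assert fBA == pytest.approx(strictly_b)

    def test_empty_sites_rejected(self, small_layout):
        cov = coverage_from_array(small_layout, {"chr1": np.zeros(100)}, 100)
        with pytest.raises(ValueError):
            windowed_sum_comparison([], cov, cov)

    def test_planted_fraction_recovered(self, small_layout):
        """90% of sites get a 3-fold A excess; the statistic lands within
        3 binomial SEs of 0.9 (the remaining ties count as not-higher)."""
        rng = np.random.default_rng(10)
        base = rng.random(100) + 0.5
        arrA, arrB = base.copy(), base.copy()
        sites = []
        n, boosted = 50, 0
        for i in range(n):
            s = 100 + i * 190
            sites.append(Interval("chr1", s, s + 10))
        for i, site in enumerate(sites):
            if i < int(0.9 * n):
                b = site.midpoint // 100
                arrA[b] *= 3.0
                boosted += 1
        covA = coverage_from_array(small_layout, {"chr1": arrA}, 100)
        covB = coverage_from_array(small_layout, {"chr1": arrB}, 100)
        _, frac = windowed_sum_comparison(sites, covA, covB, window=200)
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(frac - boosted / n) <= 3 * se


class TestSiteFlankCoverage:
    def test_zero_coverage(self, small_layout):
        cov = coverage_from_array(small_layout, {"chr1": np.zeros(100)}, 100)
        vals = site_flank_coverage([Interval("chr1", 4_000, 4_100)], cov)
        assert vals.tolist() == [0.0]

    def test_uniform_coverage_scales_with_window(self, small_layout):
        # per-base density u = 2/100; a 5 kb window sums to u * 5000
        cov = coverage_from_array(small_layout, {"chr1": np.full(100, 2.0)}, 100)
        vals = site_flank_coverage([Interval("chr1", 5_000, 5_100)], cov, window=5_000)
        assert vals[0] == pytest.approx(2.0 * 50)

    def test_matches_direct_summation(self, small_layout):
        rng = np.random.default_rng(11)
        arr = rng.random(100)
        cov = coverage_from_array(small_layout, {"chr1": arr}, 100)
        site = Interval("chr1", 5_000, 5_100)
        got = site_flank_coverage([site], cov, window=5_000)[0]
        lo, hi = 5_050 - 2_500, 5_050 + 2_500
        expect = 0.0
        for b in range(100):
            ov = max(0, min(hi, (b + 1) * 100) - max(lo, b * 100))
            expect += arr[b] * ov / 100
        assert got == pytest.approx(expect, rel=1e-9)
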