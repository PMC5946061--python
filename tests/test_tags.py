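import numpy as np
import pandas as pd
import pytest

from _oracles import pearson_direct
from conftest import make_uniform_library
from ladpipe.core import GenomeLayout, Interval, TagRecord
from ladpipe.tags import (
    TagLibrary,
    binned_coverage,
    deduplicate,
    downsample,
    extend_tags,
    replicate_correlation,
)


def lib_from(records, layout, label="t"):
    return TagLibrary.from_records(records, layout, label)


class TestDeduplicate:
    def test_exact_duplicates_collapse(self, layout):
        lib = lib_from([TagRecord("chr1", 10, 85), TagRecord("chr1", 10, 85)], layout)
        assert deduplicate(lib).total_tags == 1

    def test_opposite_strands_both_kept(self, layout):
        lib = lib_from(
            [TagRecord("chr1", 10, 85, strand="+"), TagRecord("chr1", 10, 85, strand="-")],
            layout,
        )
        assert deduplicate(lib).total_tags == 2

    def test_distinct_library_unchanged_and_idempotent(self, uniform_library):
        once = deduplicate(uniform_library)
        twice = deduplicate(once)
        assert once.total_tags == twice.total_tags
        pd.testing.assert_frame_equal(once.frame, twice.frame)


class TestDownsample:
    def test_n_at_least_total_is_identity(self, uniform_library):
        out = downsample(uniform_library, uniform_library.total_tags + 10, seed=1)
        pd.testing.assert_frame_equal(out.frame, uniform_library.frame)

    def test_n_zero_empties(self, uniform_library):
        assert downsample(uniform_library, 0, seed=1).total_tags == 0

    def test_negative_n_rejected(self, uniform_library):
        with pytest.raises(ValueError):
            downsample(uniform_library, -1, seed=1)

    def test_seeds_give_distinct_subsets_of_right_size(self, big_layout):
        lib = make_uniform_library(big_layout, 10_000, seed=3)
        a = downsample(lib, 5_000, seed=1)
        b = downsample(lib, 5_000, seed=2)
        assert a.total_tags == b.total_tags == 5_000
        assert not a.frame.equals(b.frame)

    def test_reproducible_bit_exact(self, uniform_library):
        a = downsample(uniform_library, 500, seed=9)
        b = downsample(uniform_library, 500, seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_bin_coverage_expectation_scales(self, layout):
        """E[bin count after downsampling] = count * n/total, within 3 SDs
        of the mean of 100 seeded draws."""
        lib = make_uniform_library(layout, 2_000, seed=5)
        full = binned_coverage(lib, 10_000)
        bin_count = full.data["chr1"][2]
        q = 0.5
        draws = [
            binned_coverage(downsample(lib, 1_000, seed=s), 10_000).data["chr1"][2]
            for s in range(100)
        ]
        se_mean = np.sqrt(bin_count * q * (1 - q)) / np.sqrt(100)
        assert abs(np.mean(draws) - bin_count * q) <= 3 * se_mean


class TestExtend:
    def test_plus_strand_extends_right(self, layout):
        lib = lib_from([TagRecord("chr1", 100, 140, strand="+")], layout)
        out = extend_tags(lib, 150).frame.iloc[0]
        assert (out.start, out.end) == (100, 250)

    def test_minus_strand_extends_left_with_clip(self, layout):
        lib = lib_from([TagRecord("chr1", 100, 140, strand="-")], layout)
        out = extend_tags(lib, 150).frame.iloc[0]
        assert (out.start, out.end) == (0, 140)

    def test_extension_to_tag_length_is_identity(self, layout):
        lib = lib_from([TagRecord("chr1", 100, 140, strand="+")], layout)
        out = extend_tags(lib, 40)
        pd.testing.assert_frame_equal(out.frame, lib.frame)

    def test_right_end_clipped_to_chromosome(self, layout):
        lib = lib_from([TagRecord("chr2", 49_990, 49_999, strand="+")], layout)
        assert extend_tags(lib, 150).frame.iloc[0].end == 50_000

    def test_five_prime_positions_survive_extension(self, uniform_library):
        ext = extend_tags(uniform_library, 150)
        np.testing.assert_array_equal(
            np.where(
                uniform_library.frame["strand"] == "+",
                ext.frame["start"],
                ext.frame["end"] - 1,
            ),
            uniform_library.five_prime(),
        )


class TestBinnedCoverage:
    def test_tag_counted_in_bin_of_five_prime(self, layout):
        lib = lib_from([TagRecord("chr1", 5, 80)], layout)
        cov = binned_coverage(lib, 10)
        assert cov.data["chr1"][0] == 1
        assert cov.data["chr1"][1:].sum() == 0

    def test_minus_strand_anchors_at_right_end(self, layout):
        lib = lib_from([TagRecord("chr1", 5, 80, strand="-")], layout)
        cov = binned_coverage(lib, 10)
        assert cov.data["chr1"][7] == 1  # 5' = 79

    def test_normalization_scales_by_total(self, big_layout):
        lib = make_uniform_library(big_layout, 20_000, seed=2)
        raw = binned_coverage(lib, 1_000)
        cpm = binned_coverage(lib, 1_000, normalize=True)
        np.testing.assert_allclose(
            cpm.data["chr1"], raw.data["chr1"] * 1e6 / 20_000, rtol=1e-12
        )

    def test_unnormalized_sum_is_total_tags(self, uniform_library):
        cov = binned_coverage(uniform_library, 777)
        assert cov.total() == uniform_library.total_tags

    def test_window_sum_fractional_edges(self, layout):
        lib = lib_from([TagRecord("chr1", 5, 80)], layout)
        cov = binned_coverage(lib, 10)
        # the single count sits in bin [0,10); half the bin -> half the count
        assert cov.window_sum("chr1", 0, 5) == pytest.approx(0.5)
        assert cov.window_sum("chr1", 0, 10) == pytest.approx(1.0)
        assert cov.window_sum("chr1", -100, 200_000) == pytest.approx(1.0)


class TestReplicateCorrelation:
    def regions(self):
        return [Interval("chr1", i * 1_000, i * 1_000 + 600) for i in range(20)]

    def test_scaled_copy_gives_r_one(self, layout):
        lib = make_uniform_library(layout, 2_000, seed=8)
        cov = binned_coverage(lib, 100)
        doubled = binned_coverage(lib, 100)
        for c in doubled.data:
            doubled.data[c] = doubled.data[c] * 2.0
        assert replicate_correlation(cov, doubled, self.regions()) == pytest.approx(1.0)

    def test_reversed_sums_give_r_minus_one(self, layout):
        lib = make_uniform_library(layout, 2_000, seed=8)
        cov = binned_coverage(lib, 100)
        flipped = binned_coverage(lib, 100)
        # anti-correlate by reversing the per-bin values within chr1
        flipped.data["chr1"] = cov.data["chr1"].max() - cov.data["chr1"]
        r = replicate_correlation(cov, flipped, self.regions())
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, layout):
        a = make_uniform_library(layout, 3_000, seed=1)
        b = make_uniform_library(layout, 3_000, seed=2)
        cov_a, cov_b = binned_coverage(a, 100), binned_coverage(b, 100)
        regs = self.regions()
        r = replicate_correlation(cov_a, cov_b, regs)
        xs = [cov_a.window_sum(r_.chrom, r_.start, r_.end) for r_ in regs]
        ys = [cov_b.window_sum(r_.chrom, r_.start, r_.end) for r_ in regs]
        assert r == pytest.approx(pearson_direct(xs, ys), abs=1e-12)

    def test_short_regions_filtered_and_errors(self, layout):
        lib = make_uniform_library(layout, 2_000, seed=8)
        cov = binned_coverage(lib, 100)
        short = [Interval("chr1", 0, 49), Interval("chr1", 100, 149)]
        with pytest.raises(ValueError, match="2 regions"):
            replicate_correlation(cov, cov, short)
        flat = binned_coverage(make_uniform_library(layout, 0, seed=0), 100)
        with pytest.raises(ValueError, match="variance"):
            replicate_correlation(flat, flat, self.regions())
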