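import numpy as np
import pytest
from scipy import stats

from _oracles import fisher_two_sided_exact
from ladpipe.core import GenomeLayout, Interval, merge_intervals
from ladpipe.cooccupancy import (
    classify_shared_exclusive,
    fisher_two_sided,
    overlap_enrichment,
    random_background,
)


class TestVenn:
    def test_simple_overlap(self):
        v = classify_shared_exclusive(
            [Interval("chr1", 0, 100)], [Interval("chr1", 50, 150)]
        )
        assert (v.A_overlapping_B, v.B_overlapping_A, v.A_only) == (1, 1, 0)

    def test_disjoint_sets(self):
        v = classify_shared_exclusive(
            [Interval("chr1", 0, 100)], [Interval("chr1", 200, 300)]
        )
        assert (v.A_only, v.B_only) == (1, 1)

    def test_one_a_spanning_two_b_is_asymmetric(self):
        v = classify_shared_exclusive(
            [Interval("chr1", 0, 1_000)],
            [Interval("chr1", 100, 200), Interval("chr1", 500, 600)],
        )
        assert v.A_overlapping_B == 1
        assert v.B_overlapping_A == 2
        assert v.to_dict()["center_discrepancy"] == 1

    def test_unmerged_input_rejected_with_hint(self):
        with pytest.raises(ValueError, match="merge"):
            classify_shared_exclusive(
                [Interval("chr1", 0, 100), Interval("chr1", 50, 150)],
                [Interval("chr1", 0, 10)],
            )

    def test_counts_invariant_to_order(self):
        rng = np.random.default_rng(3)
        A = merge_intervals(
            [Interval("chr1", int(s), int(s) + 50) for s in rng.integers(0, 5_000, 30)]
        )
        B = merge_intervals(
            [Interval("chr1", int(s), int(s) + 80) for s in rng.integers(0, 5_000, 30)]
        )
        v1 = classify_shared_exclusive(A, B)
        v2 = classify_shared_exclusive(list(reversed(A)), list(reversed(B)))
        assert v1 == v2


class TestRandomBackground:
    def test_bounds_respected(self):
        layout = GenomeLayout({"chr1": 10_000})
        sites = [Interval("chr1", 2_000, 3_000)]
        for seed in range(50):
            bg = random_background(sites, layout, seed=seed)[0][0]
            assert bg.chrom == "chr1"
            assert 0 <= bg.start <= 9_000
            assert bg.length == 1_000

    def test_same_seed_identical_sets(self):
        layout = GenomeLayout({"chr1": 100_000, "chr2": 50_000})
        sites = [Interval("chr1", 0, 500), Interval("chr2", 100, 400)]
        assert random_background(sites, layout, seed=5, n_draws=3) == random_background(
            sites, layout, seed=5, n_draws=3
        )

    def test_start_positions_uniform_by_chi_square(self):
        layout = GenomeLayout({"chr1": 10_000})
        sites = [Interval("chr1", 0, 1_000)]
        starts = [
            random_background(sites, layout, seed=s)[0][0].start for s in range(10_000)
        ]
        # starts range over [0, 9000]; bin into 10 cells
        counts, _ = np.histogram(starts, bins=10, range=(0, 9_001))
        chi2 = ((counts - 1_000.0) ** 2 / 1_000.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=9)

    def test_exclusion_respected(self):
        layout = GenomeLayout({"chr1": 10_000})
        excl = [Interval("chr1", 0, 8_000)]
        sites = [Interval("chr1", 0, 500)]
        for seed in range(20):
            bg = random_background(sites, layout, seed=seed, exclusion=excl)[0][0]
            assert bg.start >= 8_000

    def test_oversized_site_rejected(self):
        layout = GenomeLayout({"chr1": 1_000, "chr2": 10_000})
        with pytest.raises(ValueError, match="length"):
            random_background([Interval("chr1", 0, 1_000 + 1)], layout, seed=0)


class TestFisher:
    def test_symmetric_table_is_null(self):
        assert fisher_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_example_table_matches_enumeration(self):
        # frozen from the exact-integer hypergeometric enumeration oracle
        want = fisher_two_sided_exact(10, 5, 4, 11)
        assert want == pytest.approx(0.0655955, abs=1e-7)
        assert fisher_two_sided([[10, 5], [4, 11]]) == pytest.approx(want, abs=1e-10)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            assert fisher_two_sided([[a, b], [c, d]]) == pytest.approx(
                fisher_two_sided_exact(a, b, c, d), abs=1e-10
            )


class TestOverlapEnrichment:
    def test_saturated_domains_give_p_one(self):
        layout = GenomeLayout({"chr1": 10_000})
        domains = [Interval("chr1", 0, 10_000)]
        sites = [Interval("chr1", i * 100, i * 100 + 50) for i in range(20)]
        r = overlap_enrichment(sites, domains, layout, seed=1)
        assert (r.k_observed, r.k_background) == (20, 20)
        assert r.fisher_p == pytest.approx(1.0)

    def test_no_sites_rejected(self):
        layout = GenomeLayout({"chr1": 10_000})
        with pytest.raises(ValueError, match="site"):
            overlap_enrichment([], [Interval("chr1", 0, 100)], layout, seed=1)

    def test_unmerged_domains_rejected(self):
        layout = GenomeLayout({"chr1": 10_000})
        with pytest.raises(ValueError, match="merged"):
            overlap_enrichment(
                [Interval("chr1", 0, 50)],
                [Interval("chr1", 0, 100), Interval("chr1", 50, 150)],
                layout,
                seed=1,
            )

    def test_concentrated_sites_detected(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        domains = [Interval("chr1", 0, 50_000)]
        rng = np.random.default_rng(2)
        sites = [
            Interval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 49_800, size=50)
        ]
        r = overlap_enrichment(sites, domains, layout, seed=3)
        assert r.k_observed == 50
        assert r.fisher_p < 1e-6
        assert r.odds_ratio > 1

    def test_zero_cell_odds_ratio_uses_continuity(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        domains = [Interval("chr1", 0, 10_000)]
        sites = [Interval("chr1", i * 10, i * 10 + 5) for i in range(10)]
        r = overlap_enrichment(sites, domains, layout, seed=4)
        assert np.isfinite(r.odds_ratio)
        assert r.odds_ratio > 0

    def test_table_shape_consistent(self):
        layout = GenomeLayout({"chr1": 100_000})
        domains = [Interval("chr1", 0, 30_000)]
        sites = [Interval("chr1", int(s), int(s) + 100) for s in range(0, 90_000, 9_000)]
        r = overlap_enrichment(sites, domains, layout, seed=5, n_draws=5)
        (a, b), (c, d) = r.table
        assert a + b == r.n_sites
        assert c + d == r.n_background
        assert 0 <= r.k_background <= r.n_background
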