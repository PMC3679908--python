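import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fourc.genome import BaitRegion, GenomeLayout, GenomicInterval
from fourc.enrichment import (
    PeakSet,
    compare_to_random,
    enrichment_factor,
    random_site_table,
    rank_sum_test,
    tag_density,
)


def sites_df(records):
    return pd.DataFrame(
        {"chrom": [c for c, _ in records], "rep_pos": [p for _, p in records]}
    )


def exact_wmw_p(x, y):
    """Oracle: enumerate every assignment of pooled ranks to group x.

    One-sided (x greater); assumes no ties. P(U_null >= U_obs).
    """
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - len(x) * (len(x) + 1) / 2
    n = len(pooled)
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), len(x)):
        u = sum(combo) - len(x) * (len(x) + 1) / 2
        total += 1
        if u >= u_obs:
            count += 1
    return count / total


class TestEnrichmentFactor:
    def test_saturated_peaks_give_ef_one(self, layout):
        # one peak covering all of chr3: every site and every random draw hits
        peaks = PeakSet.from_intervals("mark", [GenomicInterval("chr3", 0, 8_000_000)])
        sites = sites_df([("chr3", 10), ("chr3", 5_000_000)])
        ef, obs, exp = enrichment_factor(sites, peaks, layout, "chr3", n_random=100, seed=0)
        assert obs == 2 and exp == pytest.approx(2.0)
        assert ef == pytest.approx(1.0)

    def test_no_overlap_possible(self, layout):
        peaks = PeakSet.from_intervals("mark", [GenomicInterval("chr2", 0, 100)])
        sites = sites_df([("chr3", 5_000_000)])
        ef, obs, exp = enrichment_factor(sites, peaks, layout, "chr3", n_random=100, seed=0)
        assert obs == 0
        assert math.isnan(ef)  # expectation zero: no chr3 peaks at all

    def test_proximity_padding(self, layout):
        peaks = PeakSet.from_intervals("mark", [GenomicInterval("chr3", 100_000, 100_100)])
        near = sites_df([("chr3", 95_000)])  # 5 kb from the start base
        far = sites_df([("chr3", 94_999)])
        _, obs_near, _ = enrichment_factor(near, peaks, layout, "chr3", n_random=100, seed=0)
        _, obs_far, _ = enrichment_factor(far, peaks, layout, "chr3", n_random=100, seed=0)
        assert obs_near == 1 and obs_far == 0

    def test_expected_matches_analytic_coverage(self, layout):
        # padded-merged peaks cover an exactly known fraction of chr3
        peaks = PeakSet.from_intervals(
            "mark",
            [GenomicInterval("chr3", 1_000_000, 1_200_000),
             GenomicInterval("chr3", 4_000_000, 4_100_000)],
        )
        pad = 5_000
        covered = (200_000 + 2 * pad) + (100_000 + 2 * pad)
        phi = covered / 8_000_000
        n_sites, n_random = 50, 2_000
        rng_sites = np.random.default_rng(9)
        sites = sites_df([("chr3", int(p)) for p in rng_sites.integers(0, 8_000_000, n_sites)])
        _, _, expected = enrichment_factor(
            sites, peaks, layout, "chr3", proximity=pad, n_random=n_random, seed=1
        )
        analytic = n_sites * phi
        se = math.sqrt(n_sites * phi * (1 - phi) / n_random)
        assert abs(expected - analytic) <= 4 * se

    def test_n_random_floor(self, layout):
        peaks = PeakSet.from_intervals("mark", [GenomicInterval("chr3", 0, 10)])
        with pytest.raises(ValueError):
            enrichment_factor(sites_df([("chr3", 5)]), peaks, layout, "chr3", n_random=10)

    def test_reproducible(self, layout):
        peaks = PeakSet.from_intervals("mark", [GenomicInterval("chr3", 0, 500_000)])
        sites = sites_df([("chr3", 100), ("chr3", 7_000_000)])
        a = enrichment_factor(sites, peaks, layout, "chr3", n_random=200, seed=3)
        b = enrichment_factor(sites, peaks, layout, "chr3", n_random=200, seed=3)
        assert a == b


class TestPeakSetMerging:
    def test_padded_merge(self):
        peaks = PeakSet.from_intervals(
            "m", [GenomicInterval("c", 100, 200), GenomicInterval("c", 205, 300)]
        )
        merged = peaks.padded_merged(10)
        s, e = merged["c"]
        assert s.tolist() == [90] and e.tolist() == [310]

    def test_no_merge_when_separated(self):
        peaks = PeakSet.from_intervals(
            "m", [GenomicInterval("c", 100, 200), GenomicInterval("c", 500, 600)]
        )
        s, e = peaks.padded_merged(10)["c"]
        assert s.tolist() == [90, 490] and e.tolist() == [210, 610]


class TestTagDensity:
    def test_arithmetic(self):
        sites = sites_df([("chr3", 10_000)])
        treat = {"chr3": np.array([9_500, 10_200, 12_500])}  # 2 within +/-1 kb
        bg = {"chr3": np.array([10_100])}  # 1 within window
        out = tag_density(sites, treat, 10_000_000, bg, 5_000_000)
        row = out.iloc[0]
        assert row["obs_norm"] == pytest.approx(2.0)
        assert row["bg_norm"] == pytest.approx(2.0)
        assert row["net"] == pytest.approx(0.0)

    def test_window_boundary_inclusive(self):
        sites = sites_df([("chr3", 10_000)])
        treat = {"chr3": np.array([9_000, 11_000])}
        out = tag_density(sites, treat, 10_000_000, {"chr3": np.array([1])}, 10_000_000)
        assert out.iloc[0]["obs_norm"] == pytest.approx(2.0)

    def test_normalization_scale_invariance(self):
        sites = sites_df([("chr3", 10_000), ("chr3", 50_000)])
        treat = {"chr3": np.array([10_000, 10_100, 50_000])}
        a = tag_density(sites, treat, 1_000_000, treat, 1_000_000)
        b = tag_density(sites, treat, 1_000_000, treat, 2_000_000)
        assert np.allclose(a["net"], 0.0)
        assert (b["net"] > 0).all()

    def test_invalid_totals(self):
        with pytest.raises(ValueError):
            tag_density(sites_df([("chr3", 1)]), {}, 0, {}, 10)


class TestRankSumTest:
    def test_textbook_extreme_case(self):
        # {4,5,6} vs {1,2,3}: the most extreme of C(6,3)=20 assignments
        _, p = rank_sum_test(np.array([4, 5, 6]), np.array([1, 2, 3]))
        assert p == pytest.approx(0.05)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.permutation(100)[: nx + ny]  # distinct values, no ties
            x, y = list(pooled[:nx]), list(pooled[nx:])
            _, p = rank_sum_test(np.array(x, float), np.array(y, float))
            assert p == pytest.approx(exact_wmw_p(x, y), abs=1e-12)

    def test_degenerate_p_one(self):
        _, p = rank_sum_test(np.array([2.0, 2.0]), np.array([2.0, 2.0, 2.0]))
        assert p == 1.0

    def test_shifted_sample_small_p(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 1, 200)
        y = rng.normal(0, 1, 200)
        _, p = rank_sum_test(x, y)
        assert p < 1e-10

    def test_one_sided_direction(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0])
        _, p = rank_sum_test(x, y)  # x smaller -> no evidence x greater
        assert p > 0.9


class TestRandomSitesAndComparison:
    def test_random_sites_respect_scope_and_exclusion(self, layout, bait):
        rng = np.random.default_rng(2)
        tbl = random_site_table(layout, 500, rng, restrict_chrom="chr17", exclude=bait)
        assert (tbl["chrom"] == "chr17").all()
        assert not ((tbl["rep_pos"] >= bait.start) & (tbl["rep_pos"] < bait.end)).any()
        assert tbl["rep_pos"].between(0, 10_000_000 - 1).all()

    def test_compare_to_random_detects_planted_signal(self, layout):
        rng = np.random.default_rng(3)
        site_pos = rng.integers(0, 8_000_000, 40)
        sites = sites_df([("chr3", int(p)) for p in np.sort(site_pos)])
        # pile treatment tags onto the 4C sites, uniform background
        treat = np.sort(
            np.concatenate([rng.integers(p - 500, p + 500, 30) for p in site_pos])
        )
        bg = np.sort(rng.integers(0, 8_000_000, 5_000))
        records = tag_density(sites, {"chr3": treat}, 100_000, {"chr3": bg}, 100_000)
        _, _, p = compare_to_random(
            records, layout, {"chr3": treat}, 100_000, {"chr3": bg}, 100_000,
            seed=4, restrict_chrom="chr3",
        )
        assert p < 1e-6

    def test_compare_to_random_null_is_calm(self, layout):
        rng = np.random.default_rng(5)
        sites = sites_df([("chr3", int(p)) for p in np.sort(rng.integers(0, 8_000_000, 40))])
        treat = np.sort(rng.integers(0, 8_000_000, 5_000))
        bg = np.sort(rng.integers(0, 8_000_000, 5_000))
        records = tag_density(sites, {"chr3": treat}, 100_000, {"chr3": bg}, 100_000)
        _, _, p = compare_to_random(
            records, layout, {"chr3": treat}, 100_000, {"chr3": bg}, 100_000,
            seed=6, restrict_chrom="chr3",
        )
        assert p > 0.01
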