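import itertools
import math

import numpy as np
import pytest

import meichip as m
from meichip.coloc import block_edge_index, peak_distances

from conftest import make_profile


def brute_force_distance(pos, chrom, blocks):
    best = math.inf
    for b in blocks:
        if b.chrom != chrom:
            continue
        best = min(best, abs(pos - b.start), abs(pos - (b.end - 1)))
    return best


class TestNearestEdgeDistance:
    def test_peak_at_block_start_is_zero(self):
        b = m.HotspotBlock("chr1", 1000, 1180, 1.0)
        assert m.distance_to_nearest_block(1000, "chr1", [b]) == 0

    def test_peak_inside_block_gets_distance_to_nearer_edge(self):
        # center of [1000, 1180): nearer edge is 89 from 1179, 90 from 1000
        b = m.HotspotBlock("chr1", 1000, 1180, 1.0)
        assert m.distance_to_nearest_block(1090, "chr1", [b]) == 89
        assert m.distance_to_nearest_block(1089, "chr1", [b]) == 89

    def test_no_blocks_on_chromosome_is_infinite(self):
        b = m.HotspotBlock("chr1", 0, 10, 1.0)
        assert m.distance_to_nearest_block(5, "chr2", [b]) == math.inf

    def test_matches_brute_force_oracle(self, toy_blocks):
        rng = np.random.default_rng(17)
        for _ in range(50):
            chrom = rng.choice(["chr1", "chr2"])
            pos = int(rng.integers(0, 300_000))
            assert m.distance_to_nearest_block(
                pos, chrom, toy_blocks
            ) == brute_force_distance(pos, chrom, toy_blocks)


class TestCumulativeCurve:
    def test_all_peaks_at_edges(self, toy_blocks):
        peaks = [m.Peak(b.chrom, b.start, 1.0, i + 1) for i, b in enumerate(toy_blocks)]
        curve = m.cumulative_distance_curve(peaks, toy_blocks, grid=[0, 100])
        assert curve.tolist() == [1.0, 1.0]

    def test_counting_example(self):
        blocks = [m.HotspotBlock("chr1", 1000, 1001, 1.0)]
        peaks = [m.Peak("chr1", 1100, 1.0, 1), m.Peak("chr1", 1700, 0.9, 2)]
        curve = m.cumulative_distance_curve(peaks, blocks, grid=[0, 600, 1000])
        assert curve.tolist() == [0.0, 0.5, 1.0]

    def test_matches_counting_loop(self, toy_blocks):
        rng = np.random.default_rng(23)
        peaks = [
            m.Peak(rng.choice(["chr1", "chr2"]), int(rng.integers(0, 200_000)), 1.0, i)
            for i in range(40)
        ]
        grid = np.arange(0, 5001, 250)
        curve = m.cumulative_distance_curve(peaks, toy_blocks, grid)
        dists = [brute_force_distance(p.pos, p.chrom, toy_blocks) for p in peaks]
        expected = [sum(d <= g for d in dists) / len(dists) for g in grid]
        np.testing.assert_allclose(curve, expected)
        assert np.all(np.diff(curve) >= 0)
        assert curve.min() >= 0 and curve.max() <= 1

    def test_zero_peaks_rejected(self, toy_blocks):
        with pytest.raises(ValueError):
            m.cumulative_distance_curve([], toy_blocks)


class TestMatchedFraction:
    def test_all_inside_narrow_blocks(self, toy_blocks):
        peaks = [m.Peak(b.chrom, b.center, 1.0, i) for i, b in enumerate(toy_blocks)]
        frac, matched, unmatched = m.matched_fraction(peaks, toy_blocks, 600)
        assert frac == 1.0 and unmatched == 0

    def test_no_blocks_gives_zero(self):
        peaks = [m.Peak("chr1", 100, 1.0, 1)]
        frac, matched, unmatched = m.matched_fraction(peaks, [], 600)
        assert frac == 0.0 and matched == 0

    def test_consistency_with_curve(self, toy_blocks):
        rng = np.random.default_rng(29)
        peaks = [
            m.Peak("chr1", int(rng.integers(0, 300_000)), 1.0, i) for i in range(30)
        ]
        frac, _, _ = m.matched_fraction(peaks, toy_blocks, 600)
        curve = m.cumulative_distance_curve(peaks, toy_blocks, grid=[600])
        assert frac == pytest.approx(curve[0])


class TestRandomNull:
    def test_blocks_tiling_genome_give_fraction_one(self):
        g = m.make_genome([("chr1", 10_000)])
        blocks = [
            m.HotspotBlock("chr1", i * 1000, (i + 1) * 1000, 1.0) for i in range(10)
        ]
        null = m.random_null(
            50, blocks, g, m.ColocConfig(match_distance=600),
            m.NullModelConfig(repetitions=10, seed=0),
        )
        assert null.mean_fraction == 1.0

    def test_mean_matches_analytic_coverage_for_sparse_blocks(self):
        """For sparse non-overlapping blocks the chance of a uniform
        position landing within d of a block edge is sum(w_i + 2d)/G."""
        g = m.make_genome([("chr1", 2_000_000), ("chr2", 1_000_000)])
        rng = np.random.default_rng(13)
        blocks = []
        for i in range(30):
            chrom = "chr1" if i < 20 else "chr2"
            start = int(rng.integers(20_000, 900_000)) + (i % 20) * 45_000
            start = min(start, 1_900_000)
            width = int(rng.integers(100, 500))
            blocks.append(m.HotspotBlock(chrom, start, start + width, 1.0))
        d_star = 600.0
        expected = sum(b.width + 2 * d_star for b in blocks) / g.total_length
        reps = 200
        n_peaks = 400
        null = m.random_null(
            n_peaks, blocks, g, m.ColocConfig(match_distance=d_star),
            m.NullModelConfig(repetitions=reps, seed=5),
        )
        se = math.sqrt(expected * (1 - expected) / (reps * n_peaks))
        assert abs(null.mean_fraction - expected) <= 3 * se

    def test_same_seed_identical_envelopes(self, toy_blocks, toy_genome):
        cfg = m.NullModelConfig(repetitions=20, seed=8)
        a = m.random_null(100, toy_blocks, toy_genome, m.ColocConfig(), cfg)
        b = m.random_null(100, toy_blocks, toy_genome, m.ColocConfig(), cfg)
        assert np.array_equal(a.lower_curve, b.lower_curve)
        assert np.array_equal(a.upper_curve, b.upper_curve)
        assert np.all(a.lower_curve <= a.upper_curve)


def enumeration_fisher(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(r1 + r2, c1)
    s = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = math.comb(r1, x) * math.comb(r2, c1 - x)
        if num <= obs + obs * 1e-7:
            s += num
    return s / total


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert m.fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_small_table_closed_form(self):
        # margins 4/4/4: two-sided p = 34/70
        assert m.fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70, rel=1e-9)

    def test_printed_500_peak_comparison_is_below_1e40(self):
        # 310/500 observed matches vs 35/500 random-expected
        assert m.fisher_exact([[310, 190], [35, 465]]) <= 1e-40

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            m.fisher_exact([[-1, 2], [3, 4]])

    def test_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if a + b + c + d == 0:
                continue
            p = m.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(enumeration_fisher(a, b, c, d), rel=1e-8)


class TestCompareTopN:
    def test_random_peaks_are_null_consistent(self, toy_genome, toy_blocks):
        rng = np.random.default_rng(37)
        peaks = []
        for i in range(120):
            chrom = rng.choice(["chr1", "chr2"], p=[0.6, 0.4])
            pos = int(rng.integers(0, toy_genome.lengths[chrom]))
            peaks.append(m.Peak(chrom, pos, float(120 - i), i + 1))
        res = m.compare_top_n(
            peaks, toy_blocks, 100, 6,
            m.ColocConfig(), m.NullModelConfig(repetitions=100, seed=2),
            genome=toy_genome,
        )
        assert res.fisher_p > 0.01
        inside = np.mean(
            (res.curve >= res.null.lower_curve) & (res.curve <= res.null.upper_curve)
        )
        assert inside >= 0.9

    def test_fewer_peaks_than_requested_warns_and_uses_all(
        self, toy_genome, toy_blocks
    ):
        peaks = [m.Peak("chr1", 40_000, 2.0, 1), m.Peak("chr1", 90_100, 1.5, 2)]
        with pytest.warns(UserWarning, match="peaks available"):
            res = m.compare_top_n(
                peaks, toy_blocks, 10, 6,
                m.ColocConfig(), m.NullModelConfig(repetitions=5, seed=1),
                genome=toy_genome,
            )
        assert res.n_peaks == 2


class TestAxisDomainClassifier:
    def _ratio(self, toy_genome, values):
        p = make_profile(toy_genome, {"chr1": values})
        return p.with_values(p.data, smoothed=True, bandwidth=500.0, normalized=True)

    def test_threshold_rules(self, toy_genome):
        vals = np.full(100, 1.0)
        vals[10], vals[20], vals[30] = 0.4, 0.6, 0.5
        ratio = self._ratio(toy_genome, vals)
        sites = [m.AxisSite("chr1", 500, 1.0), m.AxisSite("chr1", 1000, 1.0),
                 m.AxisSite("chr1", 1500, 1.0)]
        labels = m.axis_domain_classifier(ratio, sites, threshold=0.5)
        # 0.4 -> 0; 0.6 -> 1; exactly 0.5 -> 0 (strict "exceeded")
        assert labels.tolist() == [0, 1, 0]

    def test_site_beyond_chromosome_rejected(self, toy_genome):
        ratio = self._ratio(toy_genome, np.full(100, 1.0))
        with pytest.raises(ValueError, match="beyond"):
            m.axis_domain_classifier(ratio, [("chr1", 10**7)])
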