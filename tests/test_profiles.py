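import numpy as np
import pytest

import meichip as m
from meichip.profiles import KSMOOTH_SD_PER_BANDWIDTH

from conftest import make_profile


def direct_nadaraya_watson(pos, val, bandwidth):
    """Independent per-point Nadaraya–Watson oracle (full kernel, no
    truncation, plain Python loop)."""
    sd = KSMOOTH_SD_PER_BANDWIDTH * bandwidth
    out = np.empty_like(val, dtype=float)
    for i, x in enumerate(pos):
        w = np.exp(-0.5 * ((pos - x) / sd) ** 2)
        out[i] = np.sum(w * val) / np.sum(w)
    return out


class TestSmoothing:
    def test_constant_profile_preserved(self, toy_genome):
        p = make_profile(toy_genome, {"chr1": np.full(200, 3.7)})
        sm = m.smooth(p, m.SmoothingParams(500))
        np.testing.assert_allclose(sm.data["chr1"][1], 3.7, rtol=1e-12)
        assert sm.smoothed and sm.bandwidth == 500

    @pytest.mark.parametrize("bandwidth", [250.0, 500.0, 1000.0])
    def test_matches_direct_convolution_oracle(self, toy_genome, bandwidth):
        rng = np.random.default_rng(8)
        vals = np.exp(rng.normal(0, 0.3, 300))
        vals[150] = 8.0  # single elevated probe among noisy background
        p = make_profile(toy_genome, {"chr1": vals})
        sm = m.smooth(p, m.SmoothingParams(bandwidth))
        expected = direct_nadaraya_watson(
            p.data["chr1"][0].astype(float), vals, bandwidth
        )
        np.testing.assert_allclose(sm.data["chr1"][1], expected, rtol=1e-9)

    def test_irregular_grid_matches_oracle(self, toy_genome):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(0, 100_000, 10), 200, replace=False))
        vals = np.exp(rng.normal(0, 0.2, 200))
        p = m.TilingProfile(toy_genome, {"chr1": (pos, vals)})
        sm = m.smooth(p, m.SmoothingParams(400))
        expected = direct_nadaraya_watson(pos.astype(float), vals, 400)
        np.testing.assert_allclose(sm.data["chr1"][1], expected, rtol=1e-9)

    def test_tiny_bandwidth_is_identity(self, toy_genome):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(0, 0.2, 100))
        p = make_profile(toy_genome, {"chr1": vals})
        sm = m.smooth(p, m.SmoothingParams(bandwidth=1.0))
        np.testing.assert_allclose(sm.data["chr1"][1], vals, rtol=1e-9)

    def test_linearity(self, toy_genome):
        rng = np.random.default_rng(5)
        f = np.exp(rng.normal(0, 0.3, 150))
        g = np.exp(rng.normal(0, 0.3, 150))
        a, b = 1.7, 0.4
        params = m.SmoothingParams(500)
        sf = m.smooth(make_profile(toy_genome, {"chr1": f}), params).data["chr1"][1]
        sg = m.smooth(make_profile(toy_genome, {"chr1": g}), params).data["chr1"][1]
        sfg = m.smooth(
            make_profile(toy_genome, {"chr1": a * f + b * g}), params
        ).data["chr1"][1]
        np.testing.assert_allclose(sfg, a * sf + b * sg, rtol=1e-9)

    def test_convex_combination_bounds(self, toy_genome):
        rng = np.random.default_rng(6)
        vals = np.exp(rng.normal(0, 0.5, 400))
        sm = m.smooth(make_profile(toy_genome, {"chr1": vals}), m.SmoothingParams(750))
        out = sm.data["chr1"][1]
        assert out.min() >= vals.min() - 1e-12
        assert out.max() <= vals.max() + 1e-12

    def test_no_smoothing_across_chromosomes(self, toy_genome):
        p = make_profile(
            toy_genome, {"chr1": np.full(50, 1.0), "chr2": np.full(50, 9.0)}
        )
        sm = m.smooth(p, m.SmoothingParams(1000))
        np.testing.assert_allclose(sm.data["chr1"][1], 1.0, rtol=1e-12)
        np.testing.assert_allclose(sm.data["chr2"][1], 9.0, rtol=1e-12)

    def test_resmoothing_rejected_unless_allowed(self, toy_genome):
        p = make_profile(toy_genome, {"chr1": np.full(20, 1.0)})
        sm = m.smooth(p)
        with pytest.raises(ValueError, match="smoothed"):
            m.smooth(sm)
        m.smooth(sm, allow_resmooth=True)


class TestDecileNormalize:
    def test_constant_profile(self, toy_genome):
        p = make_profile(toy_genome, {"chr1": np.full(50, 4.0)})
        out, nf = m.decile_normalize(p)
        assert nf.F == pytest.approx(0.25)
        np.testing.assert_allclose(out.data["chr1"][1], 1.0)

    def test_1_to_100_interpolated_quantile(self, toy_genome):
        # linear-interpolation 0.10 quantile of 1..100 is 10.9
        p = make_profile(toy_genome, {"chr1": np.arange(1.0, 101.0)})
        out, nf = m.decile_normalize(p)
        assert nf.F == pytest.approx(1.0 / 10.9, rel=1e-12)
        assert out.normalized and out.norm_factor == pytest.approx(nf.F)

    def test_post_normalization_decile_is_one(self, toy_genome):
        rng = np.random.default_rng(2)
        p = make_profile(toy_genome, {"chr1": np.exp(rng.normal(0, 0.4, 500))})
        out, _ = m.decile_normalize(p)
        assert np.quantile(out.all_values(), 0.10) == pytest.approx(1.0, rel=1e-9)

    def test_idempotent(self, toy_genome):
        rng = np.random.default_rng(4)
        p = make_profile(toy_genome, {"chr1": np.exp(rng.normal(0, 0.4, 500))})
        once, _ = m.decile_normalize(p)
        _, nf2 = m.decile_normalize(once)
        assert nf2.F == pytest.approx(1.0, rel=1e-9)

    def test_too_few_probes_rejected(self, toy_genome):
        p = make_profile(toy_genome, {"chr1": np.full(5, 1.0)})
        with pytest.raises(ValueError, match="at least 10"):
            m.decile_normalize(p)


class TestRatioAndInversion:
    @staticmethod
    def _prep(genome, values):
        p = make_profile(genome, {"chr1": values})
        return m.decile_normalize(m.smooth(p, m.SmoothingParams(1.0)))[0]

    def test_self_ratio_is_one(self, toy_genome):
        rng = np.random.default_rng(7)
        p = self._prep(toy_genome, np.exp(rng.normal(0.5, 0.2, 100)))
        r = m.ratio_profile(p, p)
        np.testing.assert_allclose(r.data["chr1"][1], 1.0, rtol=1e-12)
        assert r.label.count("/") == 1

    def test_floor_applies(self, toy_genome):
        num = self._prep(toy_genome, np.full(100, 2.0))
        den_vals = np.full(100, 2.0)
        den_vals[10] = 0.02  # far below the floor after normalization
        den = self._prep(toy_genome, den_vals)
        r = m.ratio_profile(num, den, floor=0.25)
        assert r.data["chr1"][1][10] == pytest.approx(
            num.data["chr1"][1][10] / 0.25
        )

    def test_elementwise_matches_scalar_loop(self, toy_genome):
        rng = np.random.default_rng(9)
        a = self._prep(toy_genome, np.exp(rng.normal(0, 0.4, 200)))
        b = self._prep(toy_genome, np.exp(rng.normal(0, 0.4, 200)))
        r = m.ratio_profile(a, b, floor=0.25)
        av, bv = a.data["chr1"][1], b.data["chr1"][1]
        expected = [x / max(y, 0.25) for x, y in zip(av, bv)]
        np.testing.assert_allclose(r.data["chr1"][1], expected, rtol=1e-12)

    def test_unprocessed_inputs_rejected(self, toy_genome):
        raw = make_profile(toy_genome, {"chr1": np.full(100, 1.0)})
        with pytest.raises(ValueError, match="smoothed and normalized"):
            m.ratio_profile(raw, raw)

    def test_mismatched_grids_rejected(self, toy_genome):
        a = self._prep(toy_genome, np.full(100, 1.0))
        b = self._prep(toy_genome, np.full(120, 1.0))
        with pytest.raises(ValueError, match="grids"):
            m.ratio_profile(a, b)

    def test_invert_basics_and_round_trip(self, toy_genome):
        rng = np.random.default_rng(10)
        vals = np.exp(rng.normal(0.6, 0.3, 150))
        p = self._prep(toy_genome, vals)
        inv = m.invert_profile(p, floor=0.25)
        pv = p.data["chr1"][1]
        np.testing.assert_allclose(
            inv.data["chr1"][1], 1.0 / np.maximum(pv, 0.25), rtol=1e-12
        )
        # invert twice = identity wherever both value and reciprocal clear the floor
        back = m.invert_profile(inv, floor=0.25)
        ok = (pv >= 0.25) & (1.0 / pv >= 0.25)
        np.testing.assert_allclose(
            back.data["chr1"][1][ok], pv[ok], rtol=1e-12
        )


class TestBedgraphIO:
    def test_round_trip(self, tmp_path, toy_genome):
        rng = np.random.default_rng(12)
        p = make_profile(
            toy_genome,
            {"chr1": np.exp(rng.normal(0, 0.3, 80)), "chr2": np.full(40, 2.0)},
            spacing=50,
            label="WT",
        )
        path = tmp_path / "p.bedgraph"
        m.write_bedgraph(p, path)
        q = m.read_bedgraph(path, toy_genome, label="WT")
        assert q.same_grid(p)
        for c in p.data:
            np.testing.assert_allclose(q.data[c][1], p.data[c][1], rtol=1e-7)

    def test_interval_collapses_to_start(self, tmp_path, toy_genome):
        path = tmp_path / "p.bedgraph"
        path.write_text("chr1\t0\t50\t1.5\n")
        q = m.read_bedgraph(path, toy_genome)
        assert q.data["chr1"][0].tolist() == [0]
        assert q.data["chr1"][1].tolist() == [1.5]

    def test_position_past_chromosome_end_rejected(self, tmp_path, toy_genome):
        path = tmp_path / "p.bedgraph"
        path.write_text("chr1\t299990\t300040\t1.0\n")
        with pytest.raises(ValueError, match=":1"):
            m.read_bedgraph(path, toy_genome)

    def test_unsorted_intervals_rejected_with_line(self, tmp_path, toy_genome):
        path = tmp_path / "p.bedgraph"
        path.write_text("chr1\t100\t150\t1.0\nchr1\t0\t50\t1.0\n")
        with pytest.raises(ValueError, match=":2"):
            m.read_bedgraph(path, toy_genome)
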