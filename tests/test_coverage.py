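"""Size factors, binning, metagene profiles and TSS dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcpakit import coverage as cov
from pcpakit.annotation import GeneModel


def bg(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def flat_track(value, L=1000, bin_size=100, strand="+", chrom="c"):
    return cov.bin_coverage(
        bg([(chrom, 0, L, value)]), {chrom: L}, bin_size, strand
    )


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 40], "b": [10, 20, 40]})
        f = cov.estimate_size_factors(m)
        assert f["a"] == pytest.approx(1.0)
        assert f["b"] == pytest.approx(1.0)

    def test_doubled_sample(self):
        m = pd.DataFrame({"a": [10, 20, 40], "b": [20, 40, 80]})
        f = cov.estimate_size_factors(m)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_hand_median_of_ratios(self):
        # ratios to the geometric-mean reference, per spike-in:
        # ref = sqrt(a*b) -> a/ref = sqrt(a/b) = {sqrt(1/2), sqrt(2), 1}
        m = pd.DataFrame({"a": [10, 20, 40], "b": [20, 10, 40]})
        f = cov.estimate_size_factors(m)
        assert f["a"] == pytest.approx(1.0)
        assert f["b"] == pytest.approx(1.0)
        assert f["b"] / f["a"] == pytest.approx(1.0)

    def test_no_positive_row_errors(self):
        m = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            cov.estimate_size_factors(m)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_scale_equivariance_of_factor_ratios(self, c):
        # factors are defined up to an overall scale; scaling one sample's
        # counts by c scales its factor relative to the others by c
        m = pd.DataFrame({"a": [10, 25, 40, 7], "b": [12, 30, 33, 9]})
        f0 = cov.estimate_size_factors(m)
        m2 = m.copy()
        m2["b"] = m["b"] * c
        f1 = cov.estimate_size_factors(m2)
        assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(
            c, rel=1e-9
        )


class TestBinCoverage:
    def test_constant_signal_constant_bins(self):
        t = flat_track(1.0)
        assert np.allclose(t.values["c"], 1.0)

    def test_partial_interval_weighted(self):
        t = cov.bin_coverage(bg([("c", 0, 50, 2.0)]), {"c": 100}, 100, "+")
        assert t.values["c"][0] == pytest.approx(1.0)

    def test_size_factor_divides(self):
        t1 = flat_track(1.0)
        t2 = cov.bin_coverage(
            bg([("c", 0, 1000, 1.0)]), {"c": 1000}, 100, "+", size_factor=2.0
        )
        assert np.allclose(t2.values["c"], t1.values["c"] / 2.0)

    def test_out_of_bounds_interval(self):
        with pytest.raises(ValueError, match="beyond"):
            cov.bin_coverage(bg([("c", 0, 2000, 1.0)]), {"c": 1000}, 100, "+")

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 9), st.floats(0, 5)),
            min_size=1, max_size=8, unique_by=lambda x: x[0],
        ),
        st.floats(0.5, 4.0),
    )
    def test_mass_conservation(self, intervals, factor):
        rows = [("c", i * 100, (i + 1) * 100, v) for i, v in intervals]
        t = cov.bin_coverage(bg(rows), {"c": 1000}, 300, "+", size_factor=factor)
        mass_in = sum(100 * v for _, v in intervals) / factor
        mass_out = float(np.sum(t.values["c"]) * 300)
        assert mass_out == pytest.approx(mass_in, rel=1e-9, abs=1e-9)


class TestRegionSum:
    def test_sum_matches_mass(self):
        t = flat_track(2.0)
        assert t.region_sum("c", 100, 400) == pytest.approx(600.0)

    def test_partial_bins(self):
        t = flat_track(1.0)
        assert t.region_sum("c", 150, 250) == pytest.approx(100.0)


class TestMetagene:
    def make_gene(self, gid, start, end, strand):
        return GeneModel(gid, "c", strand, start, end, [(start, end)])

    def test_uniform_coverage_flat_body(self):
        tracks = {"+": flat_track(1.0, L=10000), "-": flat_track(0.0, L=10000)}
        g = self.make_gene("g", 3000, 6000, "+")
        prof = cov.metagene_profile(tracks, [g])
        body = prof.sense[prof.n_flank_bins:prof.n_flank_bins + 50]
        assert np.allclose(body, 1.0)

    def test_minus_strand_orientation(self):
        # signal only near the minus-strand gene's TSS (genomic end)
        L = 10000
        plus = cov.bin_coverage(bg([("c", 0, L, 0.0)]), {"c": L}, 100, "+")
        minus = cov.bin_coverage(
            bg([("c", 5800, 6000, 4.0)]), {"c": L}, 100, "-"
        )
        g = self.make_gene("g", 2000, 6000, "-")
        prof = cov.metagene_profile({"+": plus, "-": minus}, [g])
        body = prof.sense[prof.n_flank_bins:prof.n_flank_bins + 50]
        assert np.argmax(body) <= 2
        assert body[-1] == pytest.approx(0.0)

    def test_two_gene_average(self):
        L = 20000
        t = cov.bin_coverage(
            bg([("c", 1000, 4000, 2.0), ("c", 10000, 13000, 4.0)]),
            {"c": L}, 100, "+",
        )
        zero = cov.bin_coverage(bg([("c", 0, L, 0.0)]), {"c": L}, 100, "-")
        genes = [
            self.make_gene("a", 1000, 4000, "+"),
            self.make_gene("b", 10000, 13000, "+"),
        ]
        prof = cov.metagene_profile({"+": t, "-": zero}, genes)
        body = prof.sense[prof.n_flank_bins:prof.n_flank_bins + 50]
        assert np.allclose(body, 3.0)

    def test_short_gene_excluded(self):
        tracks = {"+": flat_track(1.0, L=10000), "-": flat_track(0.0, L=10000)}
        genes = [self.make_gene("a", 3000, 6000, "+"),
                 self.make_gene("b", 7000, 7030, "+")]
        prof = cov.metagene_profile(tracks, genes)
        assert prof.n_genes == 1 and prof.n_excluded == 1

    def test_rescale_bounds(self):
        x = np.array([0.0, 5.0, 10.0])
        r = cov.MetageneProfile.rescale(x)
        assert r.min() == pytest.approx(1.0) and r.max() == pytest.approx(100.0)


class TestDynamics:
    def make_tracks(self, value_ctl, value_trt, L=40000):
        ctl = {
            "+": cov.bin_coverage(bg([("c", 0, L, value_ctl)]), {"c": L}, 50, "+"),
            "-": cov.bin_coverage(bg([("c", 0, L, value_ctl)]), {"c": L}, 50, "-"),
        }
        trt = {
            "+": cov.bin_coverage(bg([("c", 0, L, value_trt)]), {"c": L}, 50, "+"),
            "-": cov.bin_coverage(bg([("c", 0, L, value_trt)]), {"c": L}, 50, "-"),
        }
        return ctl, trt

    def test_null_change_and_rate(self):
        ctl, trt = self.make_tracks(1.0, 1.0)
        g = GeneModel("g", "c", "+", 2000, 30000, [(2000, 30000)])
        dyn = cov.tss_dynamics(ctl, trt, [g])
        assert np.allclose(dyn.change, 0.0)
        assert np.allclose(dyn.rate, 0.0)

    def test_linear_change_constant_rate(self):
        L = 40000
        rows = [("c", i * 50, (i + 1) * 50, float(i)) for i in range(L // 50)]
        trt = {
            "+": cov.bin_coverage(bg(rows), {"c": L}, 50, "+"),
            "-": cov.bin_coverage(bg(rows), {"c": L}, 50, "-"),
        }
        ctl, _ = self.make_tracks(0.0, 0.0, L)
        g = GeneModel("g", "c", "+", 2000, 30000, [(2000, 30000)])
        dyn = cov.tss_dynamics(ctl, trt, [g])
        assert np.allclose(dyn.rate, dyn.rate[0])

    def test_bin_mismatch_errors(self):
        ctl, _ = self.make_tracks(1.0, 1.0)
        trt100 = {
            "+": flat_track(1.0, L=40000), "-": flat_track(1.0, L=40000)
        }
        g = GeneModel("g", "c", "+", 2000, 30000, [(2000, 30000)])
        with pytest.raises(ValueError, match="bin size"):
            cov.tss_dynamics(ctl, trt100, [g])

    def test_rate_rescaled_spans_change_range(self):
        L = 40000
        rng = np.random.default_rng(0)
        rows = [("c", i * 50, (i + 1) * 50, float(v))
                for i, v in enumerate(rng.random(L // 50))]
        trt = {
            "+": cov.bin_coverage(bg(rows), {"c": L}, 50, "+"),
            "-": cov.bin_coverage(bg(rows), {"c": L}, 50, "-"),
        }
        ctl, _ = self.make_tracks(0.0, 0.0, L)
        g = GeneModel("g", "c", "+", 2000, 30000, [(2000, 30000)])
        dyn = cov.tss_dynamics(ctl, trt, [g])
        assert dyn.rate_rescaled.min() == pytest.approx(dyn.change.min())
        assert dyn.rate_rescaled.max() == pytest.approx(dyn.change.max())
        assert len(dyn.rate) == len(dyn.change) - 1


class TestReplicateCorrelation:
    def test_self_and_reverse(self):
        L = 1000
        rng = np.random.default_rng(1)
        vals = rng.random(10)
        rows = [("c", i * 100, (i + 1) * 100, float(v)) for i, v in enumerate(vals)]
        t1 = cov.bin_coverage(bg(rows), {"c": L}, 100, "+", sample_id="t1")
        rev = [("c", i * 100, (i + 1) * 100, float(v))
               for i, v in enumerate(sorted(vals, reverse=True))]
        fwd = [("c", i * 100, (i + 1) * 100, float(v))
               for i, v in enumerate(sorted(vals))]
        t2 = cov.bin_coverage(bg(fwd), {"c": L}, 100, "+", sample_id="t2")
        t3 = cov.bin_coverage(bg(rev), {"c": L}, 100, "+", sample_id="t3")
        m = cov.replicate_correlation([t1, t2, t3])
        assert m.loc["t1", "t1"] == pytest.approx(1.0)
        assert m.loc["t2", "t3"] == pytest.approx(-1.0)

    def test_constant_track_missing(self):
        t1 = flat_track(1.0)
        t1.sample_id = "flat"
        rows = [("c", i * 100, (i + 1) * 100, float(i)) for i in range(10)]
        t2 = cov.bin_coverage(bg(rows), {"c": 1000}, 100, "+", sample_id="ramp")
        m = cov.replicate_correlation([t1, t2])
        assert np.isnan(m.loc["flat", "ramp"])
        assert m.loc["flat", "flat"] == pytest.approx(1.0)

    def test_independent_replicates_agree(self, null_run):
        from pcpakit.simulate import simulate_tt_coverage

        sim = null_run["sim"]
        paths, _ = simulate_tt_coverage(sim, null_run["outdir"] / "reps")
        tracks = [
            cov.bin_coverage(
                cov.read_bedgraph(paths[s]["+"]), sim.seq_lengths, 100, "+",
                sample_id=s,
            )
            for s in ("control_rep1", "control_rep2")
        ]
        m = cov.replicate_correlation(tracks)
        assert m.loc["control_rep1", "control_rep2"] > 0.8
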