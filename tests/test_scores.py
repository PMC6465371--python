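"""Per-gene statistics: IR index, PCPA scores, usage OR, DE, gene-set z."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcpakit import scores as sc
from pcpakit.annotation import GeneModel


def ir_table(rows):
    return pd.DataFrame(
        rows,
        columns=["exon_treated", "exon_control", "intron_treated",
                 "intron_control"],
        index=[f"g{i}" for i in range(len(rows))],
    )


class TestIntronRetentionIndex:
    def test_hand_arithmetic(self):
        # exon ratio (9+1)/(4+1)=2, intron ratio (4+1)/(9+1)=0.5 -> IR -2
        out = sc.intron_retention_index(
            ir_table([(9, 4, 4, 9)]), min_exon_reads=0, min_intron_reads=0
        )
        assert out["ir_index"].iloc[0] == pytest.approx(-2.0)

    def test_symmetric_counts_zero(self):
        out = sc.intron_retention_index(
            ir_table([(20, 20, 20, 20)])
        )
        assert out["ir_index"].iloc[0] == pytest.approx(0.0)
        assert out["ir_class"].iloc[0] == "none"

    def test_low_coverage_untested(self):
        out = sc.intron_retention_index(ir_table([(8, 8, 100, 100)]))
        assert np.isnan(out["ir_index"].iloc[0])
        assert out["ir_class"].iloc[0] == "none"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sc.intron_retention_index(ir_table([(-1, 5, 5, 5)]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_antisymmetric_under_condition_swap(self, counts):
        et, ec, it, ic = counts
        fwd = sc.intron_retention_index(
            ir_table([(et, ec, it, ic)]), min_exon_reads=0, min_intron_reads=0
        )
        rev = sc.intron_retention_index(
            ir_table([(ec, et, ic, it)]), min_exon_reads=0, min_intron_reads=0
        )
        assert fwd["ir_index"].iloc[0] == pytest.approx(
            -rev["ir_index"].iloc[0], abs=1e-12
        )

    def test_classification_thresholds(self):
        # strong retention vs strong loss, with clear counts
        rows = [(100, 100, 800, 100), (100, 100, 100, 800)] + [
            (100, 100, 100, 100)
        ] * 4
        out = sc.intron_retention_index(ir_table(rows))
        assert out["ir_class"].iloc[0] == "retention"
        assert out["ir_class"].iloc[1] == "loss"
        assert (out["ir_class"].iloc[2:] == "none").all()


class TestPcpaCall:
    def table(self, ft, fc, lt, lc, iq1, iq4, assessable=True):
        return pd.DataFrame(
            [{"first_treated": ft, "first_control": fc, "last_treated": lt,
              "last_control": lc, "iq1": iq1, "iq4": iq4,
              "assessable": assessable}],
            index=["g"],
        )

    def test_hand_arithmetic(self):
        # exon: log2(26/101) - log2(101/101) = -1.9578; iQ: log2(81/11) = 2.8803
        out = sc.pcpa_call(self.table(100, 100, 25, 100, 80, 10))
        assert out["exon_score"].iloc[0] == pytest.approx(
            np.log2(26 / 101), abs=1e-9
        )
        assert out["iq_score"].iloc[0] == pytest.approx(np.log2(81 / 11), abs=1e-9)
        assert bool(out["pcpa"].iloc[0])

    def test_null_not_called(self):
        out = sc.pcpa_call(self.table(50, 50, 50, 50, 30, 30))
        assert out["exon_score"].iloc[0] == pytest.approx(0.0)
        assert out["iq_score"].iloc[0] == pytest.approx(0.0)
        assert not bool(out["pcpa"].iloc[0])

    def test_requires_both_thresholds(self):
        # exon-score far below -1 but iQ-score below 1: no call
        out = sc.pcpa_call(self.table(800, 100, 100, 800, 20, 15))
        assert out["exon_score"].iloc[0] < -3
        assert out["iq_score"].iloc[0] < 1
        assert not bool(out["pcpa"].iloc[0])

    def test_single_exon_not_assessable(self):
        out = sc.pcpa_call(self.table(10, 100, 1, 100, 500, 1, assessable=False))
        assert not bool(out["pcpa"].iloc[0])
        assert not bool(out["assessable"].iloc[0])


class TestUsageOddsRatio:
    def table(self, it, ic, ut, uc, gene="g"):
        return pd.DataFrame(
            [{"intronic_treated": it, "intronic_control": ic,
              "utr_treated": ut, "utr_control": uc}],
            index=[gene],
        )

    def test_hand_arithmetic(self):
        out = sc.intronic_usage_or(self.table(20, 5, 5, 20))
        expected = (20.5 / 5.5) / (5.5 / 20.5)
        assert out["odds_ratio"].iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(13.89, abs=0.01)

    def test_identity(self):
        out = sc.intronic_usage_or(self.table(7, 7, 30, 30))
        assert out["odds_ratio"].iloc[0] == pytest.approx(1.0)

    def test_no_intronic_reads_excluded_flag(self):
        out = sc.intronic_usage_or(self.table(0, 0, 30, 30))
        assert bool(out["excluded"].iloc[0])

    def test_tpm_filter(self):
        tbl = pd.concat(
            [self.table(5, 5, 5, 5, "hi"), self.table(5, 5, 5, 5, "lo")]
        )
        out = sc.intronic_usage_or(tbl, tpm={"hi": 10.0, "lo": 0.5})
        assert list(out.index) == ["hi"]

    def test_ks_comparison(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(0, 0.3, 200)
        b = rng.lognormal(1.0, 0.3, 200)
        stat, p = sc.compare_or_distributions(a, b)
        assert p < 1e-6
        _, p_same = sc.compare_or_distributions(a, a)
        assert p_same == pytest.approx(1.0)


class TestDifferentialExpression:
    def test_identical_replicates_null(self):
        counts = pd.DataFrame(
            {"c1": [100, 50], "c2": [100, 50], "t1": [100, 50], "t2": [100, 50]},
            index=["g1", "g2"],
        )
        cond = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        out = sc.differential_expression(counts, cond)
        assert np.allclose(out["log2fc"], 0.0)
        assert not out["de_significant"].any()

    def test_sub_threshold_fold_change_not_significant(self):
        # |log2fc| ~ 0.9 with tiny p must not pass the effect-size rule
        counts = pd.DataFrame(
            {"c1": [1000], "c2": [1000], "t1": [1866], "t2": [1866]},
            index=["g"],
        )
        cond = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        out = sc.differential_expression(counts, cond)
        assert abs(out["log2fc"].iloc[0]) < 1.0
        assert not out["de_significant"].any()

    def test_low_count_genes_never_significant(self):
        counts = pd.DataFrame(
            {"c1": [2], "c2": [1], "t1": [0], "t2": [0]}, index=["g"]
        )
        cond = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        out = sc.differential_expression(counts, cond)
        assert not out["de_significant"].any()

    def test_missing_condition_errors(self):
        counts = pd.DataFrame({"c1": [10]}, index=["g"])
        with pytest.raises(ValueError):
            sc.differential_expression(counts, {"c1": "control"})

    def test_planted_effect_recovered(self):
        # 100 genes at 4-fold depression plus nulls; >=90% recovered
        rng = np.random.default_rng(2)
        n_eff, n_null, mu = 100, 300, 400.0
        rows = {}
        for i in range(n_eff + n_null):
            scale = 0.25 if i < n_eff else 1.0
            rows[f"g{i}"] = {
                "c1": rng.poisson(mu), "c2": rng.poisson(mu),
                "t1": rng.poisson(mu * scale), "t2": rng.poisson(mu * scale),
            }
        counts = pd.DataFrame.from_dict(rows, orient="index")
        cond = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        out = sc.differential_expression(counts, cond)
        eff = out.iloc[:n_eff]
        null = out.iloc[n_eff:]
        assert ((eff["de_significant"]) & (eff["log2fc"] < 0)).mean() >= 0.9
        assert null["de_significant"].mean() <= 0.05


class TestFlankingWindows:
    def test_isolated_gene_full_windows(self):
        g = GeneModel("g", "c", "+", 10000, 20000, [(10000, 20000)])
        out = sc.build_flanking_windows({"g": g})
        up = out[out["side"] == "upstream"].iloc[0]
        down = out[out["side"] == "downstream"].iloc[0]
        assert (up["start"], up["end"]) == (7950, 9950)
        assert (down["start"], down["end"]) == (20050, 22050)

    def test_same_strand_neighbor_truncates(self):
        a = GeneModel("a", "c", "+", 10000, 20000, [(10000, 20000)])
        b = GeneModel("b", "c", "+", 21000, 30000, [(21000, 30000)])
        out = sc.build_flanking_windows({"a": a, "b": b})
        down_a = out[(out["gene_id"] == "a") & (out["side"] == "downstream")]
        # window [20050, 22050) minus gene b [21000, 30000) -> [20050, 21000)
        assert len(down_a) == 1
        assert (down_a.iloc[0]["start"], down_a.iloc[0]["end"]) == (20050, 21000)

    def test_fragment_below_minimum_dropped(self):
        a = GeneModel("a", "c", "+", 10000, 20000, [(10000, 20000)])
        b = GeneModel("b", "c", "+", 20150, 30000, [(20150, 30000)])
        out = sc.build_flanking_windows({"a": a, "b": b})
        down_a = out[(out["gene_id"] == "a") & (out["side"] == "downstream")]
        assert down_a.empty  # only 100 bp remain before gene b

    def test_opposite_strand_neighbor_ignored(self):
        a = GeneModel("a", "c", "+", 10000, 20000, [(10000, 20000)])
        b = GeneModel("b", "c", "-", 21000, 30000, [(21000, 30000)])
        out = sc.build_flanking_windows({"a": a, "b": b})
        down_a = out[(out["gene_id"] == "a") & (out["side"] == "downstream")]
        assert (down_a.iloc[0]["start"], down_a.iloc[0]["end"]) == (20050, 22050)

    def test_minus_strand_orientation(self):
        g = GeneModel("g", "c", "-", 10000, 20000, [(10000, 20000)])
        out = sc.build_flanking_windows({"g": g}).set_index("side")
        assert (out.at["upstream", "start"], out.at["upstream", "end"]) == (
            20050, 22050,
        )
        assert (out.at["downstream", "start"], out.at["downstream", "end"]) == (
            7950, 9950,
        )


class TestGenesetZscore:
    def test_null_set_near_zero(self):
        rng = np.random.default_rng(3)
        changes = pd.Series(rng.normal(0, 1, 2000),
                            index=[f"g{i}" for i in range(2000)])
        members = [f"g{i}" for i in rng.choice(2000, 100, replace=False)]
        z = sc.geneset_zscore(changes, members, seed=3)
        assert abs(z) < 2.0

    def test_shifted_set_strongly_negative(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 0.5, 2000)
        base[:100] -= 1.0
        changes = pd.Series(base, index=[f"g{i}" for i in range(2000)])
        z = sc.geneset_zscore(changes, [f"g{i}" for i in range(100)], seed=4)
        assert z < -3.0

    def test_oversized_set_errors(self):
        changes = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        with pytest.raises(ValueError):
            sc.geneset_zscore(changes, ["a", "b", "c"], seed=0)


class TestLengthExpressionCorrelation:
    def test_planted_negative_relation(self):
        rng = np.random.default_rng(5)
        lengths = pd.Series(
            np.exp(rng.uniform(7, 12, 500)), index=[f"g{i}" for i in range(500)]
        )
        lfc = pd.Series(
            -0.5 * np.log2(lengths) + rng.normal(0, 0.2, 500),
            index=lengths.index,
        )
        rho, p, smooth = sc.length_expression_correlation(lfc, lengths)
        assert rho < -0.8 and p < 1e-10
        assert len(smooth) == 500

    def test_shuffled_pairing_uncorrelated(self):
        rng = np.random.default_rng(6)
        lengths = pd.Series(
            np.exp(rng.uniform(7, 12, 1000)),
            index=[f"g{i}" for i in range(1000)],
        )
        lfc = pd.Series(rng.normal(0, 1, 1000), index=lengths.index)
        rho, _, _ = sc.length_expression_correlation(lfc, lengths)
        assert abs(rho) < 0.1

    def test_constant_fold_change_flagged(self):
        lengths = pd.Series(
            np.arange(1, 21) * 1000.0, index=[f"g{i}" for i in range(20)]
        )
        lfc = pd.Series(0.0, index=lengths.index)
        rho, p, _ = sc.length_expression_correlation(lfc, lengths)
        assert np.isnan(rho)
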