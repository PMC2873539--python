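"""Tests of NI/SI computation, the splicing tests and the bias diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonbias import (
    SummarizationOptions,
    chi_square_one_to_one,
    enrichment_table,
    exclude_inconsistent,
    flag_background_anomalies,
    intensity_effect_correlation,
    normalized_index,
    pd_statistic,
    percent,
    ps_statistic,
    rma_summarize,
    si_dg_correlation,
    si_strata_summary,
    splice_test_table,
    splicing_index_paired,
    splicing_index_unpaired,
)
from exonbias import test_gene_expression as gene_level_test
from exonbias import test_splicing as ni_level_test
from exonbias.splicing import NIMatrix


def _signals(exon_rows, gene_rows, samples, parent_map):
    exon = pd.DataFrame(exon_rows, columns=samples)
    gene = pd.DataFrame(gene_rows, columns=samples)
    parent = pd.Series(parent_map)
    return exon, gene, parent


class TestNormalizedIndex:
    def test_direct_subtraction(self):
        exon, gene, parent = _signals(
            {"e0": [10.0, 8.0]}, {"g0": [10.0, 6.0]}, None, {"e0": "g0"}
        )
        exon, gene = exon.T, gene.T
        ni = normalized_index(exon, gene, parent)
        np.testing.assert_allclose(ni.ni.loc["e0"], [0.0, 2.0])

    def test_shift_invariance(self):
        exon, gene, parent = _signals(
            {"e0": [7.0, 5.0]}, {"g0": [6.0, 3.0]}, None, {"e0": "g0"}
        )
        exon, gene = exon.T, gene.T
        ni1 = normalized_index(exon, gene, parent)
        ni2 = normalized_index(exon + 3.0, gene + 3.0, parent)
        np.testing.assert_allclose(ni1.ni.values, ni2.ni.values)

    def test_orphan_probeset_omitted(self):
        exon = pd.DataFrame({"s": [1.0, 2.0]}, index=["e0", "e1"])
        gene = pd.DataFrame({"s": [1.0]}, index=["g0"])
        parent = pd.Series({"e0": "g0", "e1": "g_missing"})
        ni = normalized_index(exon, gene, parent)
        assert list(ni.ni.index) == ["e0"]


def _paired_frames(e_a, e_b, g_a, g_b):
    """One probeset / one gene / one pair with given log2 signals."""
    design = pd.DataFrame(
        {"group": ["normal", "cancer", "normal", "cancer"],
         "pair_id": ["p1", "p1", "p2", "p2"]},
        index=["n1", "c1", "n2", "c2"],
    )
    exon = pd.DataFrame({"n1": [e_b], "c1": [e_a], "n2": [e_b], "c2": [e_a]}, index=["e0"])
    gene = pd.DataFrame({"n1": [g_b], "c1": [g_a], "n2": [g_b], "c2": [g_a]}, index=["g0"])
    parent = pd.Series({"e0": "g0"})
    return exon, gene, parent, design


class TestSplicingIndex:
    def test_equal_changes_give_zero_si(self):
        exon, gene, parent, design = _paired_frames(8.0, 6.0, 8.0, 6.0)
        ni = normalized_index(exon, gene, parent)
        rec = splicing_index_paired(ni, gene, design, "cancer")
        np.testing.assert_allclose(rec["si"], 0.0)

    def test_exon_one_gene_three_gives_minus_two(self):
        exon, gene, parent, design = _paired_frames(7.0, 6.0, 9.0, 6.0)
        ni = normalized_index(exon, gene, parent)
        rec = splicing_index_paired(ni, gene, design, "cancer")
        np.testing.assert_allclose(rec["si"], -2.0)
        np.testing.assert_allclose(rec["dg"], 3.0)

    def test_algebraic_identity_on_simulated_data(self, paired_dataset):
        """SI = (E_test - E_ref) - (G_test - G_ref) per probeset and pair."""
        ds = paired_dataset
        summ = rma_summarize(ds, "both", SummarizationOptions(method="rma"))
        parent = ds.transcript_of_probeset
        ni = normalized_index(summ.exon_signal, summ.gene_signal, parent)
        rec = splicing_index_paired(ni, summ.gene_signal, ds.design, "cancer")
        pairs = {p: dict(g) for p, g in (
            ds.design.reset_index().groupby("pair_id")[["group", "sample_id"]]
            .apply(lambda d: list(zip(d["group"], d["sample_id"]))).items()
        )}
        check = rec.sample(50, random_state=0)
        for _, row in check.iterrows():
            members = pairs[row["pair_id"]]
            e = summ.exon_signal.loc[row["probeset_id"]]
            g = summ.gene_signal.loc[row["transcript_id"]]
            expected = (e[members["cancer"]] - e[members["normal"]]) - (
                g[members["cancer"]] - g[members["normal"]]
            )
            assert row["si"] == pytest.approx(expected)

    def test_unpaired_group_mean_identity(self, multigroup_dataset):
        ds = multigroup_dataset
        summ = rma_summarize(ds, "both", SummarizationOptions(method="rma"))
        parent = ds.transcript_of_probeset
        ni = normalized_index(summ.exon_signal, summ.gene_signal, parent)
        test_group = ds.groups[0]
        rec = splicing_index_unpaired(ni, summ.gene_signal, ds.design, test_group)
        test_cols = ds.design.index[ds.design["group"] == test_group]
        rest_cols = ds.design.index[ds.design["group"] != test_group]
        e = summ.exon_signal
        g = summ.gene_signal
        expected = (
            (e[test_cols].mean(axis=1) - e[rest_cols].mean(axis=1))
            - (g[test_cols].mean(axis=1) - g[rest_cols].mean(axis=1)).loc[
                parent.reindex(e.index)
            ].to_numpy()
        )
        np.testing.assert_allclose(rec["si"].to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_identical_group_means_zero_si(self):
        design = pd.DataFrame(
            {"group": ["a", "a", "b", "b"], "pair_id": ""},
            index=["a1", "a2", "b1", "b2"],
        )
        ni = NIMatrix(
            ni=pd.DataFrame({"a1": [1.0], "a2": [3.0], "b1": [2.0], "b2": [2.0]}, index=["e0"]),
            parent=pd.Series({"e0": "g0"}),
        )
        gene = pd.DataFrame({"a1": [5.0], "a2": [5.0], "b1": [5.0], "b2": [5.0]}, index=["g0"])
        rec = splicing_index_unpaired(ni, gene, design, "a")
        assert rec["si"].iloc[0] == pytest.approx(0.0)


class TestSplicingTests:
    def _ni_with_diffs(self, diffs):
        """NI matrix whose per-pair (test - ref) differences are ``diffs``."""
        n = len(diffs)
        design = pd.DataFrame(
            {
                "group": ["normal", "cancer"] * n,
                "pair_id": np.repeat([f"p{i}" for i in range(n)], 2),
            },
            index=[f"s{i}" for i in range(2 * n)],
        )
        ref = np.zeros(n)
        row = np.empty(2 * n)
        row[0::2] = ref
        row[1::2] = ref + np.asarray(diffs, dtype=float)
        ni = NIMatrix(
            ni=pd.DataFrame([row], index=["e0"], columns=design.index),
            parent=pd.Series({"e0": "g0"}),
        )
        return ni, design

    def test_paired_t_closed_form(self):
        """Differences (1,2,3): t = 2*sqrt(3) with 2 df, two-sided p ~ 0.07418."""
        ni, design = self._ni_with_diffs([1.0, 2.0, 3.0])
        out = ni_level_test(ni, design, mode="paired_t", test_group="cancer")
        t_expected = 2.0 / (1.0 / np.sqrt(3.0))
        assert out["mean_diff"].iloc[0] == pytest.approx(2.0)
        assert out["p"].iloc[0] == pytest.approx(
            2.0 * stats.t.sf(t_expected, df=2), rel=1e-12
        )
        assert out["p"].iloc[0] == pytest.approx(0.07418, abs=5e-5)

    def test_zero_variance_differences_degenerate(self):
        ni, design = self._ni_with_diffs([0.0, 0.0, 0.0])
        out = ni_level_test(ni, design, mode="paired_t", test_group="cancer")
        assert out["p"].iloc[0] == 1.0
        assert bool(out["degenerate"].iloc[0])

    def test_welch_satterthwaite_matches_scipy(self):
        rng = np.random.default_rng(0)
        design = pd.DataFrame(
            {"group": ["t"] * 4 + ["o"] * 6, "pair_id": ""},
            index=[f"s{i}" for i in range(10)],
        )
        vals = rng.normal(size=(5, 10))
        ni = NIMatrix(
            ni=pd.DataFrame(vals, index=[f"e{i}" for i in range(5)], columns=design.index),
            parent=pd.Series({f"e{i}": "g0" for i in range(5)}),
        )
        out = ni_level_test(ni, design, mode="welch_t", test_group="t")
        ref = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1, equal_var=False)
        np.testing.assert_allclose(out["p"].to_numpy(), ref.pvalue, rtol=1e-10)

    def test_gene_test_recovers_noiseless_fold_change(self, noiseless_dataset):
        ds = noiseless_dataset
        summ = rma_summarize(
            ds, "transcript", SummarizationOptions(method="rma", quantile_normalize=False)
        )
        out = gene_level_test(summ.gene_signal, ds.design, mode="paired_t")
        true_fc = (
            ds.truth.gene_log2_expression["cancer"]
            - ds.truth.gene_log2_expression["normal"]
        )
        np.testing.assert_allclose(
            out["dg"].to_numpy(), true_fc.loc[out.index].to_numpy(), atol=1e-9
        )
        de = true_fc.loc[out.index] != 0
        assert (np.sign(out["dg"][de.to_numpy()]) == np.sign(true_fc.loc[out.index][de])).all()

    def test_null_gene_pvalues_uniform(self, paired_dataset):
        """Kolmogorov-Smirnov sanity check on non-DE genes' p-values."""
        ds = paired_dataset
        summ = rma_summarize(
            ds, "transcript", SummarizationOptions(method="rma", quantile_normalize=False)
        )
        out = gene_level_test(summ.gene_signal, ds.design, mode="paired_t")
        true_fc = (
            ds.truth.gene_log2_expression["cancer"]
            - ds.truth.gene_log2_expression["normal"]
        )
        null_p = out["p"][(true_fc.loc[out.index] == 0).to_numpy()]
        ks = stats.kstest(null_p, "uniform")
        assert ks.pvalue > 0.001


class TestPsPd:
    def test_ps_examples(self):
        samples = ["s"]
        exon = pd.DataFrame({"s": [1.0, 2.0, 3.0, 4.0]}, index=[f"e{i}" for i in range(4)])
        parent = pd.Series({f"e{i}": "g0" for i in range(4)})
        gene = pd.DataFrame({"s": [2.5]}, index=["g0"])
        assert ps_statistic(exon, gene, parent).iloc[0, 0] == pytest.approx(0.5)
        gene_hi = pd.DataFrame({"s": [10.0]}, index=["g0"])
        assert ps_statistic(exon, gene_hi, parent).iloc[0, 0] == pytest.approx(1.0)
        exon_eq = pd.DataFrame({"s": [2.0] * 4}, index=exon.index)
        gene_eq = pd.DataFrame({"s": [2.0]}, index=["g0"])
        assert ps_statistic(exon_eq, gene_eq, parent).iloc[0, 0] == pytest.approx(0.0)

    def test_pd_examples(self):
        design = pd.DataFrame(
            {"group": ["a", "b"], "pair_id": ""}, index=["s_a", "s_b"]
        )
        parent = pd.Series({"e0": "g0", "e1": "g0"})
        exon = pd.DataFrame({"s_a": [0.5, 1.5], "s_b": [0.0, 0.0]}, index=["e0", "e1"])
        gene = pd.DataFrame({"s_a": [1.0], "s_b": [0.0]}, index=["g0"])
        out = pd_statistic(exon, gene, parent, design, "a")
        assert out.iloc[0] == pytest.approx(0.5)
        gene_flat = pd.DataFrame({"s_a": [0.0], "s_b": [0.0]}, index=["g0"])
        assert pd_statistic(exon, gene_flat, parent, design, "a").iloc[0] == 0.0
        exon_same = pd.DataFrame({"s_a": [1.0, 1.0], "s_b": [0.0, 0.0]}, index=["e0", "e1"])
        assert pd_statistic(exon_same, gene, parent, design, "a").iloc[0] == 0.0


class TestCorrelations:
    def test_perfect_negative(self):
        dg = np.linspace(-2, 2, 20)
        p, s = si_dg_correlation(-dg, dg)
        assert p == pytest.approx(-1.0)
        assert s == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(1)
        si, dg = rng.normal(size=10000), rng.normal(size=10000)
        p, s = si_dg_correlation(si, dg)
        assert abs(p) < 0.05 and abs(s) < 0.05

    def test_duplication_invariance(self):
        rng = np.random.default_rng(2)
        si, dg = rng.normal(size=50), rng.normal(size=50)
        p1, s1 = si_dg_correlation(si, dg)
        p2, s2 = si_dg_correlation(np.tile(si, 2), np.tile(dg, 2))
        assert p1 == pytest.approx(p2)
        assert s1 == pytest.approx(s2)

    def test_intensity_effect_constructed_monotone(self):
        design = pd.DataFrame({"group": ["a", "b"], "pair_id": ""}, index=["sa", "sb"])
        parent = pd.Series({f"e{i}": "g0" for i in range(4)})
        levels = np.array([2.0, 4.0, 6.0, 8.0])
        exon = pd.DataFrame(
            {"sa": levels + levels / 4.0, "sb": levels - levels / 4.0},
            index=parent.index,
        )
        r = intensity_effect_correlation(exon, parent, design, "a")
        assert r.loc["g0"] > 0.99

    def test_two_probeset_gene_excluded(self):
        design = pd.DataFrame({"group": ["a", "b"], "pair_id": ""}, index=["sa", "sb"])
        parent = pd.Series({"e0": "g0", "e1": "g0"})
        exon = pd.DataFrame({"sa": [1.0, 2.0], "sb": [0.5, 1.0]}, index=["e0", "e1"])
        r = intensity_effect_correlation(exon, parent, design, "a")
        assert "g0" not in r.index


class TestEnrichment:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["si", "p_splice", "delta_g", "p_gene"]
        )

    def test_manual_tally(self):
        rows = [
            (-1.0, 0.0001, 2.0, 0.01),  # up gene, skipped
            (+1.0, 0.0001, 2.0, 0.01),  # up gene, included
            (-1.0, 0.0001, -2.0, 0.01),  # down gene, skipped
            (+1.0, 0.5, 2.0, 0.01),  # not significant
        ]
        table = enrichment_table(self._results(rows), alpha_splice=0.001)
        assert table.n_significant == 3
        assert table.up_skipped == 1 and table.up_included == 1
        assert table.down_skipped == 1 and table.down_included == 0
        assert table.up_skipped_pct == pytest.approx(50.0)

    def test_no_significant_probesets(self):
        table = enrichment_table(self._results([(1.0, 0.9, 1.0, 0.9)]), alpha_splice=0.001)
        assert table.n_significant == 0
        assert np.isnan(table.up_skipped_pct)

    def test_gene_level_alpha_applies(self):
        rows = [(-1.0, 0.0001, 2.0, 0.5)]  # significant splicing, non-DE gene
        table = enrichment_table(self._results(rows), alpha_splice=0.001)
        assert table.n_significant == 1
        assert table.n_on_de_genes == 0


class TestStrata:
    def test_all_dg_zero_populates_middle(self):
        res = pd.DataFrame({"si": [1.0, -1.0], "delta_g": [0.0, 0.0]})
        out = si_strata_summary(res)
        assert out.loc["dg_between", "n"] == 2
        assert out.loc["dg_gt_1", "n"] == 0 and out.loc["dg_lt_minus1", "n"] == 0

    def test_si_minus_dg_orders_medians(self):
        dg = np.concatenate([np.full(10, 2.0), np.zeros(10), np.full(10, -2.0)])
        res = pd.DataFrame({"si": -dg, "delta_g": dg})
        out = si_strata_summary(res)
        assert out.loc["dg_gt_1", "median"] < 0 < out.loc["dg_lt_minus1", "median"]

    def test_partition_counts(self):
        rng = np.random.default_rng(3)
        res = pd.DataFrame({"si": rng.normal(size=100), "delta_g": rng.normal(scale=2, size=100)})
        out = si_strata_summary(res)
        assert out["n"].sum() == 100


class TestChiSquareAndBookkeeping:
    def test_balanced_counts(self):
        stat, p = chi_square_one_to_one(100, 100)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_published_count_pair(self):
        """877 vs 867: statistic 2*(5^2)/872 ~ 0.0573, p ~ 0.811."""
        stat, p = chi_square_one_to_one(877, 867)
        assert stat == pytest.approx(100.0 / 1744.0)
        assert stat == pytest.approx(0.0573, abs=5e-4)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-12)
        assert p == pytest.approx(0.811, abs=5e-3)

    def test_extreme_imbalance(self):
        stat, p = chi_square_one_to_one(0, 20)
        assert stat == pytest.approx(20.0)
        assert p < 1e-4

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chi_square_one_to_one(0, 0)

    def test_exclude_inconsistent(self):
        assert exclude_inconsistent(10, 3) == 7
        with pytest.raises(ValueError):
            exclude_inconsistent(5, 6)

    def test_percent(self):
        assert percent(1, 4) == pytest.approx(25.0)
        assert np.isnan(percent(0, 0))


class TestBackgroundAnomalies:
    def _frames(self, pm_mean, gcbg_mean):
        pm = pd.DataFrame({"s1": [pm_mean], "s2": [pm_mean]}, index=["tx0"])
        gc = pd.DataFrame({"s1": [gcbg_mean], "s2": [gcbg_mean]}, index=["tx0"])
        return pm, gc

    def test_eightfold_flagged(self):
        out = flag_background_anomalies(*self._frames(100.0, 800.0))
        assert bool(out.loc["tx0", "flagged"])

    def test_slightly_smaller_not_flagged(self):
        out = flag_background_anomalies(*self._frames(100.0, 90.0))
        assert not bool(out.loc["tx0", "flagged"])

    def test_fold_one_boundary(self):
        out = flag_background_anomalies(*self._frames(100.0, 100.0), fold=1.0)
        assert bool(out.loc["tx0", "flagged"])

    def test_zero_pm_mean_infinite_ratio(self):
        out = flag_background_anomalies(*self._frames(0.0, 10.0))
        assert np.isinf(out.loc["tx0", "ratio"])
        assert bool(out.loc["tx0", "flagged"])


def test_splice_test_table_sign_consistency(paired_dataset):
    """sign(si) always matches the recorded NI-difference sign."""
    ds = paired_dataset
    summ = rma_summarize(ds, "both", SummarizationOptions(method="rma"))
    table = splice_test_table(
        summ.exon_signal, summ.gene_signal, ds.transcript_of_probeset, ds.design
    )
    nonzero = table[table["si"] != 0]
    assert (np.sign(nonzero["si"]) == nonzero["si_sign"]).all()
    assert ((table["p_splice"] >= 0) & (table["p_splice"] <= 1)).all()
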