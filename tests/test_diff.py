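"""Exact tests, BH control, DE stand-in, mutation and overlap tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from melsubtypes import diff
from melsubtypes.containers import OmicsMatrix
from melsubtypes.states import call_cnv_states, call_met_states

from conftest import frame


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ([[2, 0], [0, 2]], 1 / 3),
        ([[1, 1], [1, 1]], 1.0),
        ([[3, 0], [0, 3]], 0.1),
    ])
    def test_enumerated_examples(self, table, expected):
        assert diff.fisher_exact_2x2(table) == pytest.approx(expected)

    def test_matches_scipy_over_small_margins(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if a + b + c + d == 0:
                continue
            ours = diff.fisher_exact_2x2([[a, b], [c, d]])
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-12), (a, b, c, d)

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            diff.fisher_exact_2x2([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            diff.fisher_exact_2x2([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            diff.fisher_exact_2x2([[0.5, 2], [3, 4]])


class TestBH:
    def test_stepup_hand_example(self):
        out = diff.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_and_all_ones(self):
        assert diff.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(diff.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20),
           st.integers(0, 19), st.floats(0, 1))
    @settings(deadline=None, max_examples=50)
    def test_monotone_raising_p_never_lowers_q(self, ps, idx, bump):
        idx = idx % len(ps)
        raised = list(ps)
        raised[idx] = min(1.0, raised[idx] + bump)
        q0 = diff.bh_adjust(ps)
        q1 = diff.bh_adjust(raised)
        assert (q1 >= q0 - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_adjust([0.5, 1.5])


class TestStateEnrichment:
    def _labels(self, n_a=3, n_b=3):
        return pd.Series(["A"] * n_a + ["B"] * n_b,
                         index=[f"s{i}" for i in range(n_a + n_b)])

    def test_all_gain_vs_all_normal(self):
        vals = np.array([[0.6, 0.6, 0.6, 0.0, 0.0, 0.0]])
        sm = call_cnv_states(frame(vals, assay="CNV"))
        res = diff.state_enrichment_test(sm, self._labels(), "A", "B")
        gain = res[res["direction"] == "Gain"]
        assert gain["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_distributions_p_one(self):
        vals = np.array([[0.6, 0.0, 0.6, 0.0, 0.6, 0.0]])
        sm = call_cnv_states(frame(vals, assay="CNV"))
        res = diff.state_enrichment_test(sm, self._labels(), "A", "B")
        assert (res[res["direction"] == "Gain"]["p"] == 1.0).all()

    def test_planted_hypermethylation_detected(self):
        rng = np.random.default_rng(0)
        n = 100
        beta = rng.uniform(0.3, 0.6, (60, n))
        beta[:20, :50] = rng.uniform(0.85, 0.95, (20, 50))  # hyper in group A
        m = frame(beta, assay="MET")
        sm = call_met_states(m)
        labels = pd.Series(["A"] * 50 + ["B"] * 50, index=m.sample_ids)
        res = diff.state_enrichment_test(sm, labels, "A", "B")
        hyper = res[res["direction"] == "Hyper"].set_index("feature")
        planted = [f"f{i}" for i in range(20)]
        assert (hyper.loc[planted, "q"] < 0.05).mean() >= 0.8

    def test_type_one_control_on_null(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.5, (1000, 60))
        sm = call_cnv_states(frame(vals, assay="CNV"))
        labels = pd.Series(["A"] * 30 + ["B"] * 30,
                           index=[f"s{i}" for i in range(60)])
        res = diff.state_enrichment_test(sm, labels, "A", "B")
        assert (res["p"] < 0.05).mean() <= 0.07


class TestDifferentialExpression:
    def _counts(self, G=2000, n=40, seed=1, shifted=None, fold=4.0):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.normal(5, 1, G))
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), (G, n))
        if shifted is not None:
            mu2 = fold * mu[shifted]
            counts[np.ix_(shifted, np.arange(n // 2))] = rng.negative_binomial(
                r, r / (r + mu2[:, None]), (len(shifted), n // 2))
        m = frame(counts, prefix_r="g", assay="EXPR")
        labels = pd.Series(["A"] * (n // 2) + ["B"] * (n // 2),
                           index=m.sample_ids)
        return m, labels

    def test_null_p_approximately_uniform(self):
        m, labels = self._counts()
        de = diff.differential_expression(m, labels, "A", "B")
        frac = (de["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_fold_change_power(self):
        shifted = np.arange(100)
        m, labels = self._counts(shifted=shifted)
        de = diff.differential_expression(m, labels, "A", "B").set_index("feature")
        hits = de.loc[[f"g{i}" for i in shifted]]
        assert (hits["q"] < 0.05).mean() >= 0.95
        assert hits["log2_fold_change"].mean() == pytest.approx(2.0, abs=0.3)

    def test_all_zero_gene_excluded(self):
        m, labels = self._counts(G=50, n=10)
        m.values.iloc[7] = 0
        de = diff.differential_expression(m, labels, "A", "B")
        assert "g7" in de.attrs["excluded"]
        assert "g7" not in set(de["feature"])

    def test_small_group_rejected(self):
        m, labels = self._counts(G=10, n=4)
        labels.iloc[:] = ["A", "B", "B", "B"]
        with pytest.raises(ValueError):
            diff.differential_expression(m, labels, "A", "B")


class TestMutations:
    def test_maf_silent_never_counts(self):
        maf = pd.DataFrame({
            "Hugo_Symbol": ["g1", "g1", "g2"],
            "Tumor_Sample_Barcode": ["s1", "s2", "s1"],
            "Variant_Classification": ["Missense_Mutation", "Silent",
                                       "Nonsense_Mutation"]})
        mat = diff.maf_to_mutation_matrix(maf, samples=["s1", "s2"])
        assert mat.loc["g1", "s1"] == 1
        assert mat.loc["g1", "s2"] == 0
        assert mat.loc["g2", "s1"] == 1

    def test_extreme_frequency_difference(self):
        mat = pd.DataFrame(
            np.concatenate([np.ones((1, 10)), np.zeros((1, 10))], axis=1),
            index=["gX"], columns=[f"s{i}" for i in range(20)]).astype(int)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=mat.columns)
        res = diff.mutation_frequency_test(mat, labels, "A", "B", alpha=0.01)
        expected = 2 / 184756  # 2 / C(20, 10)
        assert res["p"].iloc[0] == pytest.approx(expected)
        assert res["passed"].iloc[0]

    def test_unmutated_gene_p_one(self):
        mat = pd.DataFrame(np.zeros((1, 20), dtype=int), index=["gY"],
                           columns=[f"s{i}" for i in range(20)])
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=mat.columns)
        res = diff.mutation_frequency_test(mat, labels, "A", "B")
        assert res["p"].iloc[0] == 1.0
        assert not res["passed"].iloc[0]


class TestChiSquare:
    def test_identical_balanced_labelings(self):
        labels = pd.Series(["x", "y", "z"] * 66 + ["x", "y"],
                           index=[f"s{i}" for i in range(200)])
        chi2, df, p, _ = diff.chi_square_contingency(labels, labels)
        assert df == 4
        assert chi2 == pytest.approx(2 * 200)
        assert p < 1e-5

    def test_independent_labelings_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            a = pd.Series(rng.choice(["x", "y"], 120))
            b = pd.Series(rng.choice(["u", "v"], 120))
            ps.append(diff.chi_square_contingency(a, b)[2])
        assert 0.3 < np.mean(ps) < 0.7

    def test_constant_labeling_errors(self):
        a = pd.Series(["x"] * 10)
        b = pd.Series(["u", "v"] * 5)
        with pytest.raises(ValueError):
            diff.chi_square_contingency(a, b)


class TestConcordantGenes:
    def _frames(self):
        met = pd.DataFrame({
            "feature": ["g1", "g2", "g3"], "direction": "Hyper",
            "freq_a": [0.8, 0.8, 0.1], "freq_b": [0.1, 0.1, 0.8],
            "p": [0.001, 0.001, 0.001], "q": [0.01, 0.01, 0.01]})
        cnv = pd.DataFrame({
            "feature": ["g1", "g3"], "direction": "Loss",
            "freq_a": [0.8, 0.8], "freq_b": [0.1, 0.1],
            "p": [0.001, 0.001], "q": [0.01, 0.01]})
        de = pd.DataFrame({
            "feature": ["g1", "g2", "g3"],
            "log2_fold_change": [-2.0, -2.0, -2.0],
            "p": [0.001] * 3, "q": [0.01] * 3})
        return met, cnv, de

    def test_requires_all_three_and_direction(self):
        met, cnv, de = self._frames()
        out = diff.concordant_genes(met, cnv, de,
                                    direction_rule=("Hyper", "down"))
        assert out == ["g1"]  # g2 lacks CNV; g3 fails the Hyper direction

    def test_two_of_three_excluded(self):
        met, cnv, de = self._frames()
        out = diff.concordant_genes(met, cnv, de, direction_rule=None)
        assert "g2" not in out

    def test_empty_inputs(self):
        empty = pd.DataFrame(columns=["feature", "direction", "freq_a",
                                      "freq_b", "p", "q"])
        de = pd.DataFrame(columns=["feature", "log2_fold_change", "p", "q"])
        assert diff.concordant_genes(empty, empty, de) == []
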