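"""Correlation screen: coefficients, Fisher z, skewness, gene-set selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melsubtypes import screen
from melsubtypes.containers import OmicsMatrix
from melsubtypes.synthetic import SimConfig, generate_cohort, generate_survival

from conftest import frame


class TestPearson:
    def test_perfect_linear(self):
        r, p = screen.pearson_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_hand_computed_half(self):
        r, _ = screen.pearson_correlation([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            screen.pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_pairwise_complete(self):
        r, _ = screen.pearson_correlation([1, 2, 3, np.nan], [1, 3, 2, 5])
        assert r == pytest.approx(0.5)


class TestFisherZ:
    def test_closed_forms(self):
        assert screen.fisher_z(0.0) == 0.0
        assert screen.fisher_z(0.5) == pytest.approx(0.5 * np.log(3))

    def test_boundary_errors(self):
        for r in (1.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                screen.fisher_z(r)

    @given(st.floats(min_value=-0.999, max_value=0.999),
           st.floats(min_value=-0.999, max_value=0.999))
    @settings(deadline=None, max_examples=50)
    def test_odd_and_strictly_monotone(self, r1, r2):
        assert screen.fisher_z(-r1) == pytest.approx(-screen.fisher_z(r1))
        if r1 < r2:
            assert screen.fisher_z(r1) < screen.fisher_z(r2)


class TestCorrelateAssay:
    def test_planted_directions(self, small_cohort):
        c = small_cohort
        rec = screen.correlate_assay_with_expression(c.cnv, c.expr_log)
        planted = rec[rec["gene"].isin(c.truth.cnvcor_genes)]
        background = rec[~rec["gene"].isin(c.truth.cnvcor_genes)]
        assert planted["r"].mean() > 0.3
        assert abs(background["r"].mean()) < 0.1

    def test_permuted_expression_breaks_correlation(self, small_cohort):
        c = small_cohort
        rng = np.random.default_rng(0)
        perm = c.expr_log.values.iloc[:, rng.permutation(c.expr_log.values.shape[1])]
        perm.columns = c.expr_log.sample_ids
        rec = screen.correlate_assay_with_expression(
            c.cnv, OmicsMatrix(perm, "EXPR"))
        assert abs(rec["r"].mean()) < 0.05

    def test_record_fields_consistent(self, small_cohort):
        c = small_cohort
        rec = screen.correlate_assay_with_expression(c.cnv, c.expr_log)
        assert (rec["r"].abs() <= 1).all()
        assert np.allclose(rec["z"], np.arctanh(rec["r"].clip(-1 + 1e-15,
                                                              1 - 1e-15)))
        assert (rec["n"] >= 3).all()
        assert rec["p"].between(0, 1).all()


class TestRepresentativeProbe:
    def _records(self, rs):
        return pd.DataFrame({
            "gene": ["gA"] * len(rs),
            "probe": [f"p{i}" for i in range(len(rs))],
            "assay": "MET", "r": rs,
            "z": np.arctanh(rs), "p": 0.5, "n": 50,
        })

    def test_single_probe_either_rule(self):
        rec = self._records([0.4])
        for rule in ("extreme", "mean"):
            out = screen.select_representative_probe(rec, rule)
            assert out["r"].iloc[0] == pytest.approx(0.4)

    def test_extreme_takes_most_negative(self):
        out = screen.select_representative_probe(self._records([-0.6, -0.2]),
                                                 "extreme")
        assert out["r"].iloc[0] == pytest.approx(-0.6)
        assert out["probe"].iloc[0] == "p0"

    def test_mean_rule_averages(self):
        out = screen.select_representative_probe(self._records([0.2, 0.4]),
                                                 "mean")
        assert out["r"].iloc[0] == pytest.approx(0.3)


class TestSkewness:
    def test_symmetric_sample_zero(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        sym = np.concatenate([x, -x])
        g, _ = screen.skewness_test(sym)
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_right_skewed_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000) ** 2
        g, p = screen.skewness_test(x)
        assert g > 0 and p < 1e-5

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            screen.skewness_test([1, 2, 3, 4, 5])


class TestSelectCorGenes:
    def _setup(self):
        # gA: strong positive CNV record; gB: strong but survival-null;
        # gC: negative record for the MET side
        rng = np.random.default_rng(1)
        n = 90
        samples = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        expr = pd.DataFrame(
            {s: [xv, xv, -xv] for s, xv in zip(samples, x)},
            index=["gA", "gB", "gC"])
        expr.loc["gB"] = rng.normal(size=n)  # survival-independent control
        cnv_rec = pd.DataFrame({
            "gene": ["gA", "gB"], "probe": ["gA", "gB"], "assay": "CNV",
            "r": [0.6, 0.6], "z": np.arctanh([0.6, 0.6]),
            "p": [1e-8, 1e-8], "n": n})
        met_rec = pd.DataFrame({
            "gene": ["gC"], "probe": ["pC"], "assay": "MET",
            "r": [-0.6], "z": np.arctanh([-0.6]), "p": [1e-8], "n": n})
        # survival driven by gA expression tertile (levels sorted: hi, lo)
        labels = pd.Series(np.where(x > np.quantile(x, 2 / 3), "hi", "lo"),
                           index=samples)
        surv = generate_survival(labels, (4.0, 1.0), 0.1, seed=4)
        return cnv_rec, met_rec, surv, OmicsMatrix(expr, "EXPR")

    def test_survival_filter_semantics(self):
        cnv_rec, met_rec, surv, expr = self._setup()
        sets = screen.select_cor_genes(cnv_rec, met_rec, surv, expr,
                                       os_alpha=0.05)
        assert "gA" in sets.cnvcor
        assert "gB" not in sets.cnvcor

    def test_filter_disabled_keeps_both(self):
        cnv_rec, met_rec, surv, expr = self._setup()
        sets = screen.select_cor_genes(cnv_rec, met_rec, None, expr,
                                       apply_os_filter=False)
        assert set(sets.cnvcor) == {"gA", "gB"}
        assert sets.metcor == ["gC"]

    def test_overlap_is_intersection(self):
        cnv_rec, met_rec, _, expr = self._setup()
        met2 = met_rec.copy()
        met2["gene"] = "gA"
        met2["r"] = -0.6
        sets = screen.select_cor_genes(cnv_rec, met2, None, expr,
                                       apply_os_filter=False)
        assert sets.overlap == ["gA"]

    def test_sign_constraint(self):
        cnv_rec, met_rec, _, expr = self._setup()
        flipped = cnv_rec.copy()
        flipped["r"] = -flipped["r"]
        sets = screen.select_cor_genes(flipped, met_rec, None, expr,
                                       apply_os_filter=False)
        assert sets.cnvcor == []


class TestArmFrequency:
    def _arms(self):
        return pd.Series(["1p"] * 8 + ["1q"] * 4,
                         index=[f"g{i}" for i in range(12)])

    def test_select_all_and_none(self):
        arms = self._arms()
        assert (screen.arm_frequency(arms.index, arms, arms.index) == 1).all()
        assert (screen.arm_frequency([], arms, arms.index) == 0).all()

    def test_counting(self):
        arms = self._arms()
        out = screen.arm_frequency(["g0", "g1"], arms, arms.index)
        assert out["1p"] == pytest.approx(2 / 8)
        assert out["1q"] == 0.0


class TestCpgTally:
    def test_totals_conserved_and_match_bruteforce(self, small_cohort):
        ann = small_cohort.annotation
        probes = ann["probe_id"].iloc[:50]
        by_cpg, by_region = screen.cpg_category_tally(probes, ann)
        assert by_cpg.sum() == 50 and by_region.sum() == 50
        sub = ann.set_index("probe_id").loc[probes]
        for cat, count in by_cpg.items():
            assert count == (sub["cpg_region"] == cat).sum()


class TestScreenRecovery:
    def test_planted_sets_recovered(self):
        c = generate_cohort(SimConfig(n_samples=150, n_genes=800,
                                      n_cnvcor_genes=60, n_metcor_genes=60,
                                      n_overlap_genes=20, seed=9))
        rec = screen.correlate_assay_with_expression(c.cnv, c.expr_log)
        rep = screen.select_representative_probe(rec, "mean")
        prom = c.annotation[c.annotation["gene_region"] == "Promoter"]
        pairing = list(zip(prom["probe_id"], prom["gene"]))
        met = OmicsMatrix(c.met.values.apply(
            lambda row: row.fillna(row.mean()), axis=1), "MET")
        met_rec = screen.correlate_assay_with_expression(met, c.expr_log,
                                                         pairing)
        met_rep = screen.select_representative_probe(met_rec, "extreme")
        sets = screen.select_cor_genes(rep, met_rep, None, c.expr_log,
                                       apply_os_filter=False)
        tc, tm = set(c.truth.cnvcor_genes), set(c.truth.metcor_genes)
        assert len(set(sets.cnvcor) & tc) / len(tc) >= 0.9
        assert len(set(sets.cnvcor) - tc) / max(1, len(sets.cnvcor)) <= 0.1
        assert len(set(sets.metcor) & tm) / len(tm) >= 0.9
        assert len(set(sets.metcor) - tm) / max(1, len(sets.metcor)) <= 0.1
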