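"""Filtering, imputation, normalization and mapping contracts."""

import numpy as np
import pandas as pd
import pytest

from melsubtypes import preprocess
from melsubtypes.containers import OmicsMatrix

from conftest import frame


class TestFilterProbes:
    def test_probe_above_missing_threshold_removed(self):
        vals = np.ones((2, 10))
        vals[0, :4] = np.nan  # 40% missing
        m = frame(vals, assay="EXPR")
        out = preprocess.filter_probes(m, max_missing_frac=0.30)
        assert list(out.feature_ids) == ["f1"]

    def test_no_missing_unchanged(self):
        m = frame(np.arange(12.0).reshape(3, 4))
        out = preprocess.filter_probes(m, 0.30)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_all_removed_raises_naming_threshold(self):
        vals = np.full((2, 4), np.nan)
        vals[:, 0] = 1.0
        with pytest.raises(ValueError, match="0.3"):
            preprocess.filter_probes(frame(vals), 0.30)

    def test_drop_sex_chromosome_probes(self):
        m = frame(np.ones((3, 4)))
        ann = pd.DataFrame({
            "probe_id": ["f0", "f1", "f2"],
            "chromosome": ["1", "X", "2"],
        })
        out = preprocess.filter_probes(m, 1.0, drop_sex=True, annotation=ann)
        assert list(out.feature_ids) == ["f0", "f2"]

    def test_drop_sex_order_insensitive(self):
        vals = np.ones((3, 10))
        vals[0, :5] = np.nan
        m = frame(vals)
        ann = pd.DataFrame({"probe_id": ["f0", "f1", "f2"],
                            "chromosome": ["1", "X", "2"]})
        both = preprocess.filter_probes(m, 0.3, drop_sex=True, annotation=ann)
        seq = preprocess.filter_probes(
            preprocess.filter_probes(m, 1.0, drop_sex=True, annotation=ann), 0.3)
        pd.testing.assert_frame_equal(both.values, seq.values)


class TestKnnImpute:
    def test_no_missing_identity(self):
        m = frame(np.arange(12.0).reshape(3, 4))
        out = preprocess.knn_impute(m, k=2)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_two_equal_neighbors_give_their_value(self):
        vals = np.array([
            [1.0, 1.0, np.nan, 1.0],
            [1.0, 1.0, 0.6, 1.0],
            [1.0, 1.0, 0.6, 1.0],
            [9.0, 9.0, 9.0, 9.0],
        ])
        out = preprocess.knn_impute(frame(vals), k=2)
        assert out.values.loc["f0", "s2"] == pytest.approx(0.6)

    def test_observed_entries_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 10))
        mask = rng.random(vals.shape) < 0.1
        m = frame(np.where(mask, np.nan, vals))
        out = preprocess.knn_impute(m, k=3)
        observed = ~m.values.isna()
        assert np.allclose(out.values.to_numpy()[observed],
                           m.values.to_numpy()[observed])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(15, 8))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        once = preprocess.knn_impute(frame(vals), k=3)
        twice = preprocess.knn_impute(once, k=3)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_fully_missing_feature_errors(self):
        vals = np.ones((3, 4))
        vals[0] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            preprocess.knn_impute(frame(vals), k=1)


class TestNormalizeToNormal:
    def test_tumor_equal_baseline_gives_zero(self):
        m = frame([[4.0, 4.0]], assay="EXPR")
        base = pd.Series({"f0": 4.0})
        out = preprocess.normalize_to_normal(m, base)
        assert np.allclose(out.values, 0.0)

    def test_doubling_gives_log2_of_one(self):
        m = frame([[8.0]], assay="EXPR")
        out = preprocess.normalize_to_normal(m, pd.Series({"f0": 4.0}),
                                             pseudocount=0.0)
        assert out.values.iloc[0, 0] == pytest.approx(1.0)

    def test_zero_baseline_finite_with_pseudocount(self):
        m = frame([[7.0]], assay="EXPR")
        out = preprocess.normalize_to_normal(m, pd.Series({"f0": 0.0}),
                                             pseudocount=1.0)
        assert np.isfinite(out.values.iloc[0, 0])
        assert out.values.iloc[0, 0] == pytest.approx(3.0)

    def test_cnv_and_met_are_subtractive(self):
        m = frame([[0.5, 0.7]], assay="CNV")
        out = preprocess.normalize_to_normal(m, pd.Series({"f0": 0.2}))
        assert np.allclose(out.values, [[0.3, 0.5]])


class TestSegmentMapping:
    def _gene_model(self):
        return pd.DataFrame({
            "gene": ["gA"], "chromosome": ["1"], "start": [1], "end": [100]})

    def test_gene_inside_single_segment(self):
        seg = pd.DataFrame({"sample": ["s1"], "chromosome": ["1"],
                            "start": [1], "end": [500], "seg_mean": [0.5]})
        out = preprocess.map_segments_to_genes(seg, self._gene_model())
        assert out.values.loc["gA", "s1"] == pytest.approx(0.5)

    def test_overlap_weighted_mean(self):
        # 60 bases at 0.2, 40 bases at 0.7 -> 0.6*0.2 + 0.4*0.7 = 0.4
        seg = pd.DataFrame({
            "sample": ["s1", "s1"], "chromosome": ["1", "1"],
            "start": [1, 61], "end": [60, 100], "seg_mean": [0.2, 0.7]})
        out = preprocess.map_segments_to_genes(seg, self._gene_model())
        assert out.values.loc["gA", "s1"] == pytest.approx(0.4)

    def test_no_overlap_is_missing(self):
        seg = pd.DataFrame({"sample": ["s1"], "chromosome": ["2"],
                            "start": [1], "end": [500], "seg_mean": [0.5]})
        out = preprocess.map_segments_to_genes(seg, self._gene_model())
        assert np.isnan(out.values.loc["gA", "s1"])

    def test_constant_dosage_conserved(self, small_cohort):
        seg = small_cohort.segments.copy()
        seg["seg_mean"] = 0.25
        out = preprocess.map_segments_to_genes(seg, small_cohort.gene_model)
        vals = out.values.to_numpy()
        assert np.allclose(vals[~np.isnan(vals)], 0.25)

    def test_roundtrip_recovers_generated_gene_values(self, small_cohort):
        out = preprocess.map_segments_to_genes(small_cohort.segments,
                                               small_cohort.gene_model)
        got = out.values.loc[small_cohort.cnv.feature_ids,
                             small_cohort.cnv.sample_ids]
        assert np.allclose(got, small_cohort.cnv.values, atol=1e-9)

    def test_malformed_interval_errors(self):
        seg = pd.DataFrame({"sample": ["s1"], "chromosome": ["1"],
                            "start": [100], "end": [50], "seg_mean": [0.1]})
        with pytest.raises(ValueError):
            preprocess.map_segments_to_genes(seg, self._gene_model())


class TestProbeGeneMapping:
    def _ann(self):
        return pd.DataFrame({
            "probe_id": ["p1", "p2", "p3"],
            "chromosome": ["1", "1", "X"],
            "arm": ["1p"] * 3,
            "position": [100, 5000, 100],
            "gene": ["gA", "", "gB"],
            "cpg_region": ["Island", "OpenSea", "Island"],
            "gene_region": ["Promoter", "Intergenic", "Promoter"],
            "strand": ["+"] * 3,
        })

    def test_promoter_probe_paired_intergenic_and_sex_dropped(self):
        m = frame(np.ones((3, 4)) * 0.5, prefix_r="p", assay="MET")
        m.values.index = ["p1", "p2", "p3"]
        pairs = preprocess.map_probes_to_genes(m, self._ann())
        assert pairs == [("p1", "gA")]


class TestQuantileNormalize:
    def test_identical_samples_unchanged_up_to_log2(self):
        m = frame([[1.0, 1.0], [3.0, 3.0], [7.0, 7.0]])
        out = preprocess.quantile_log_normalize(m)
        assert np.allclose(out.values, np.log2(m.values + 1))

    def test_columns_identical_after_normalization(self):
        m = frame([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        out = preprocess.quantile_log_normalize(m)
        a = np.sort(out.values["s0"].to_numpy())
        b = np.sort(out.values["s1"].to_numpy())
        assert np.allclose(a, b)
        expected_low = (np.log2(2.0) + np.log2(11.0)) / 2
        assert out.values.iloc[0, 0] == pytest.approx(expected_low)

    def test_zero_column_with_pseudocount_finite(self):
        m = frame([[0.0, 5.0], [0.0, 1.0]])
        out = preprocess.quantile_log_normalize(m, pseudocount=1.0)
        assert np.isfinite(out.values.to_numpy()).all()

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            preprocess.quantile_log_normalize(frame([[-1.0, 2.0]]))
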