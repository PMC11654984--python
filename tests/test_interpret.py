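import numpy as np
import pandas as pd
import pytest

import scmomtf as sm
from scmomtf.data_io import ValidationError
from scmomtf.interpret import (
    AttributionTable,
    attribution_long_table,
    parse_peak_id,
    read_gene_annotation,
    sampling_shapley,
)

from _oracles import exact_shapley


class TestSamplingShapley:
    def test_matches_exhaustive_oracle_on_three_feature_model(self):
        # nonlinear 3-feature model solved exactly by coalition enumeration
        def f(X):
            X = np.atleast_2d(X)
            return (2.0 * X[:, 0] + X[:, 1] * X[:, 2] - 0.5 * X[:, 2] ** 2)[:, None]

        rng = np.random.default_rng(17)
        background = rng.random((8, 3))
        x = np.array([0.9, 0.4, 0.7])
        expected = exact_shapley(
            lambda v: float(f(np.array(v))[0, 0]), x, background, 3
        )
        phi = sampling_shapley(f, x[None, :], background, n_samples=4000, seed=0)[0, :, 0]
        np.testing.assert_allclose(phi, expected, atol=0.02)

    def test_local_accuracy_holds_exactly_per_run(self):
        # telescoping walks make per-cell attributions sum to
        # f(x) - mean f(backgrounds actually used); with a single background
        # row the target is exact
        def f(X):
            X = np.atleast_2d(X)
            return np.tanh(X.sum(axis=1))[:, None]

        background = np.zeros((1, 5))
        x = np.linspace(-1, 1, 5)
        phi = sampling_shapley(f, x[None, :], background, n_samples=600, seed=1)[0, :, 0]
        assert phi.sum() == pytest.approx(float(f(x[None, :])[0, 0] - f(background)[0, 0]), abs=1e-12)

    def test_constant_model_gets_zero_attribution(self):
        f = lambda X: np.full((np.atleast_2d(X).shape[0], 1), 3.14)
        phi = sampling_shapley(f, np.ones((2, 4)), np.zeros((3, 4)), n_samples=50, seed=0)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_seeded_reproducibility(self):
        f = lambda X: np.atleast_2d(X).sum(axis=1, keepdims=True) ** 2
        rng = np.random.default_rng(2)
        X, bg = rng.random((2, 4)), rng.random((5, 4))
        a = sampling_shapley(f, X, bg, n_samples=100, seed=9)
        b = sampling_shapley(f, X, bg, n_samples=100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_budget_below_one_walk_is_raised_with_warning(self):
        f = lambda X: np.atleast_2d(X).sum(axis=1, keepdims=True)
        with pytest.warns(UserWarning, match="raising"):
            phi = sampling_shapley(f, np.ones((1, 6)), np.zeros((1, 6)), n_samples=3, seed=0)
        assert phi.shape == (1, 6, 1)

    def test_rank_stability_under_doubled_budget(self):
        rng = np.random.default_rng(3)
        w = np.array([5.0, 3.0, 2.0, 1.0, 0.5, 0.1])

        def f(X):
            return (np.atleast_2d(X) @ w)[:, None]

        X, bg = rng.random((1, 6)), rng.random((10, 6))
        r1 = np.abs(sampling_shapley(f, X, bg, n_samples=700, seed=5)[0, :, 0]).argsort()[::-1]
        r2 = np.abs(sampling_shapley(f, X, bg, n_samples=1400, seed=6)[0, :, 0]).argsort()[::-1]
        top5_pos1 = {feat: pos for pos, feat in enumerate(r1[:5])}
        for pos, feat in enumerate(r2[:5]):
            assert abs(top5_pos1.get(feat, pos) - pos) <= 1


class TestAttributeFeatures:
    def test_planted_markers_dominate_attribution(self, trained_small):
        state, _, ds, gt = trained_small
        t_rna, t_atac = sm.attribute_features(
            state, ds, task="classification", background_size=40,
            n_samples=1200, max_cells_per_type=10, seed=0,
        )
        for t in sorted(gt.marker_features_of_type):
            planted = set(gt.marker_features_of_type[t]["RNA"])
            scores = t_rna.scores[t]
            marker_mean = scores[scores.index.isin(planted)].mean()
            other_mean = scores[~scores.index.isin(planted)].mean()
            assert marker_mean > 2 * other_mean
            top3 = set(sm.rank_markers(t_rna, t, top_k=3).index)
            assert len(top3 & planted) >= 2

    def test_dimension_reduction_task_produces_tables(self, trained_small):
        state, _, ds, gt = trained_small
        sub = ds.subset_cells(np.arange(60))
        t_rna, t_atac = sm.attribute_features(
            state, sub, task="dimension_reduction", background_size=20,
            n_samples=300, max_cells_per_type=3, seed=1,
        )
        assert t_rna.task_tag == "dimension_reduction"
        assert list(t_rna.scores.index) == ds.modality_1.feature_ids
        assert (t_rna.scores.to_numpy() >= 0).all()

    def test_normalized_scores_attain_zero_and_one(self, trained_small):
        state, _, ds, _ = trained_small
        sub = ds.subset_cells(np.arange(50))
        t_rna, _ = sm.attribute_features(
            state, sub, task="classification", background_size=15,
            n_samples=250, max_cells_per_type=2, seed=2,
        )
        norm = t_rna.normalized_scores.to_numpy()
        assert norm.min() == 0.0 and norm.max() == 1.0

    def test_unknown_task_rejected(self, trained_small):
        state, _, ds, _ = trained_small
        with pytest.raises(ValidationError):
            sm.attribute_features(state, ds, task="saliency")


class TestRankMarkers:
    def _table(self, scores):
        return AttributionTable(scores, "RNA", "classification")

    def test_single_nonzero_feature_ranked_first_with_score_one(self):
        scores = pd.DataFrame({"t0": [0.0, 0.7, 0.0]}, index=["g0", "g1", "g2"])
        top = sm.rank_markers(self._table(scores), "t0", top_k=2)
        assert top.index[0] == "g1"
        assert top.iloc[0] == 1.0

    def test_top_k_beyond_features_returns_all(self):
        scores = pd.DataFrame({"t0": [0.1, 0.2]}, index=["g0", "g1"])
        assert len(sm.rank_markers(self._table(scores), "t0", top_k=10)) == 2

    def test_ties_broken_lexicographically(self):
        scores = pd.DataFrame({"t0": [0.5, 0.5, 0.9]}, index=["gb", "ga", "gz"])
        top = sm.rank_markers(self._table(scores), "t0", top_k=3)
        assert list(top.index) == ["gz", "ga", "gb"]

    def test_unknown_type_rejected(self):
        scores = pd.DataFrame({"t0": [0.5]}, index=["g0"])
        with pytest.raises(ValidationError):
            sm.rank_markers(self._table(scores), "t9")

    def test_long_table_columns(self):
        scores = pd.DataFrame({"t0": [0.5, 0.1]}, index=["g0", "g1"])
        long = attribution_long_table([self._table(scores)])
        assert set(long.columns) == {
            "feature", "cell_type", "modality", "task", "score", "normalized_score"
        }


class TestPeakToGene:
    GENES = [
        sm.GeneInterval("GENE_A", "chr1", 150, 500, "+"),
        sm.GeneInterval("GENE_B", "chr1", 1000, 2000, "+"),
        sm.GeneInterval("GENE_C", "chr2", 100, 200, "-"),
    ]

    def test_direct_overlap_mapped(self):
        out = sm.map_peaks_to_genes(["chr1:100-200"], self.GENES, window=0)
        assert out["chr1:100-200"] == ["GENE_A"]

    def test_different_chromosome_unmapped(self):
        out = sm.map_peaks_to_genes(["chr2:100-200"], self.GENES[:2], window=0)
        assert out["chr2:100-200"] == []

    def test_promoter_window_upstream_of_tss(self):
        # peak ends 1000 bp before GENE_B's start; the 2000 bp promoter
        # window on the + strand reaches it
        out = sm.map_peaks_to_genes(["chr1:0-50"], [self.GENES[1]], window=2000)
        assert out["chr1:0-50"] == ["GENE_B"]
        out0 = sm.map_peaks_to_genes(["chr1:0-50"], [self.GENES[1]], window=0)
        assert out0["chr1:0-50"] == []

    def test_minus_strand_window_is_downstream_in_coordinates(self):
        # GENE_C is on -, so its promoter window extends past `end`
        out = sm.map_peaks_to_genes(["chr2:300-400"], [self.GENES[2]], window=500)
        assert out["chr2:300-400"] == ["GENE_C"]
        out0 = sm.map_peaks_to_genes(["chr2:300-400"], [self.GENES[2]], window=50)
        assert out0["chr2:300-400"] == []

    def test_malformed_peak_named_in_error(self):
        with pytest.raises(ValidationError, match="badpeak"):
            sm.map_peaks_to_genes(["badpeak"], self.GENES)
        with pytest.raises(ValidationError):
            parse_peak_id("chr1:500-100")  # start >= end

    def test_bed6_reader(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t500\tGENE_A\t0\t+\nchr2\t0\t50\tGENE_B\t0\t-\n")
        genes = read_gene_annotation(bed)
        assert [g.gene_id for g in genes] == ["GENE_A", "GENE_B"]
        assert genes[0].start == 100 and genes[1].strand == "-"

    def test_gtf_reader_converts_to_zero_based(self, tmp_path):
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t101\t500\t.\t+\t.\tgene_id "GENE_A"; gene_name "A";\n'
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "GENE_A";\n'
        )
        genes = read_gene_annotation(gtf)
        assert len(genes) == 1
        assert genes[0].start == 100 and genes[0].end == 500
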