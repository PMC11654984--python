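import numpy as np
import pandas as pd
import pytest

import scmomtf as sm
from scmomtf.data_io import OmicsMatrix, PairedDataset, ValidationError


def _toy_pair(n=3, labels=None, ids=None):
    ids = ids or [f"c{i}" for i in range(n)]
    rna = OmicsMatrix(np.arange(n * 4).reshape(n, 4) + 1.0, [f"g{i}" for i in range(4)], "RNA")
    atac = OmicsMatrix(np.ones((n, 3)), ["chr1:0-100", "chr1:200-300", "chr2:0-50"], "ATAC")
    return PairedDataset(rna, atac, ids, cell_labels=labels)


class TestContainers:
    def test_duplicate_feature_ids_rejected(self):
        with pytest.raises(ValidationError):
            OmicsMatrix(np.ones((2, 2)), ["a", "a"], "RNA")

    def test_negative_raw_counts_rejected(self):
        m = OmicsMatrix(np.array([[1.0, -1.0]]), ["a", "b"], "RNA")
        with pytest.raises(ValidationError):
            PairedDataset(m, OmicsMatrix(np.ones((1, 1)), ["p"], "ATAC"), ["c0"])

    def test_row_misalignment_rejected(self):
        m1 = OmicsMatrix(np.ones((3, 2)), ["a", "b"], "RNA")
        m2 = OmicsMatrix(np.ones((2, 2)), ["c", "d"], "ATAC")
        with pytest.raises(ValidationError):
            PairedDataset(m1, m2, ["x", "y", "z"])

    def test_label_codec_bijective(self):
        codec = sm.LabelCodec.from_labels(["b", "a", "b", "c"])
        codes = codec.encode(["a", "c", "b"])
        assert codec.decode(codes) == ["a", "c", "b"]
        assert codec.n_classes == 3


class TestReadWrite:
    @pytest.mark.parametrize("fmt", ["csv", "tsv", "mtx", "h5ad"])
    def test_round_trip_preserves_values_and_order(self, tmp_path, fmt):
        ds = _toy_pair(labels=["t0", "t1", "t0"])
        out = tmp_path / "ds"
        sm.write_paired_dataset(ds, out, fmt=fmt)
        if fmt == "mtx":
            paths = (out / "modality1", out / "modality2")
        else:
            paths = (out / f"modality1.{fmt}", out / f"modality2.{fmt}")
        back = sm.read_paired_dataset(*paths, labels_path=out / "labels.csv", fmt=fmt)
        np.testing.assert_array_equal(back.modality_1.values, ds.modality_1.values)
        np.testing.assert_array_equal(back.modality_2.values, ds.modality_2.values)
        assert back.cell_ids == ds.cell_ids
        assert back.modality_1.feature_ids == ds.modality_1.feature_ids
        assert back.cell_labels == ds.cell_labels

    def test_alignment_drops_unshared_cells(self, tmp_path, caplog):
        ds1 = _toy_pair(ids=["a", "b", "c"])
        ds2 = _toy_pair(ids=["b", "c", "d"])
        p1, p2 = tmp_path / "m1.csv", tmp_path / "m2.csv"
        pd.DataFrame(ds1.modality_1.values, index=ds1.cell_ids,
                     columns=ds1.modality_1.feature_ids).to_csv(p1)
        pd.DataFrame(ds2.modality_2.values, index=ds2.cell_ids,
                     columns=ds2.modality_2.feature_ids).to_csv(p2)
        import logging
        with caplog.at_level(logging.WARNING):
            back = sm.read_paired_dataset(p1, p2)
        assert back.cell_ids == ["b", "c"]
        assert "only one modality" in caplog.text

    def test_zero_overlap_is_error(self, tmp_path):
        pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["g1", "g2"]).to_csv(tmp_path / "m1.csv")
        pd.DataFrame(np.ones((2, 2)), index=["x", "y"], columns=["p1", "p2"]).to_csv(tmp_path / "m2.csv")
        with pytest.raises(ValidationError, match="overlap"):
            sm.read_paired_dataset(tmp_path / "m1.csv", tmp_path / "m2.csv")

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            sm.read_paired_dataset(tmp_path / "nope.csv", tmp_path / "nope.csv")

    def test_labels_missing_barcode_is_error(self, tmp_path):
        ds = _toy_pair()
        sm.write_paired_dataset(ds, tmp_path, fmt="csv")
        pd.DataFrame({"cell_id": ["c0", "c1"], "cell_type": ["a", "b"]}).to_csv(
            tmp_path / "partial.csv", index=False
        )
        with pytest.raises(ValidationError, match="missing"):
            sm.read_paired_dataset(
                tmp_path / "modality1.csv", tmp_path / "modality2.csv",
                labels_path=tmp_path / "partial.csv",
            )


class TestNormalize:
    def test_depth_normalize_then_log1p_arithmetic(self):
        # single cell with counts (2, 0, 2): target total is its own total (4),
        # so the depth-normalized values are unchanged and log1p follows
        rna = OmicsMatrix(np.array([[2.0, 0.0, 2.0]]), ["g1", "g2", "g3"], "RNA")
        atac = OmicsMatrix(np.array([[1.0]]), ["chr1:0-10"], "ATAC")
        out = sm.normalize_counts(PairedDataset(rna, atac, ["c0"]))
        np.testing.assert_allclose(
            out.modality_1.values, [[np.log(3.0), 0.0, np.log(3.0)]]
        )

    def test_all_zero_cell_removed_with_warning(self):
        vals = np.ones((5, 3))
        vals[2] = 0.0
        rna = OmicsMatrix(vals, ["g1", "g2", "g3"], "RNA")
        atac = OmicsMatrix(np.ones((5, 2)), ["chr1:0-10", "chr1:20-30"], "ATAC")
        ds = PairedDataset(rna, atac, [f"c{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="all-zero"):
            out = sm.normalize_counts(ds)
        assert out.n_cells == 4
        assert "c2" not in out.cell_ids

    def test_idempotent_on_normalized_data(self, small_normalized):
        ds, _ = small_normalized
        again = sm.normalize_counts(ds)
        assert again is ds

    def test_adt_clr_centers_log_values_per_cell(self):
        rna = OmicsMatrix(np.ones((3, 4)), [f"g{i}" for i in range(4)], "RNA")
        adt = OmicsMatrix(np.array([[0.0, 3.0, 8.0]] * 3), ["p1", "p2", "p3"], "ADT")
        out = sm.normalize_counts(PairedDataset(rna, adt, ["a", "b", "c"]))
        clr = out.modality_2.values
        np.testing.assert_allclose(clr.mean(axis=1), 0.0, atol=1e-12)
        expected = np.log1p([0.0, 3.0, 8.0])
        np.testing.assert_allclose(clr[0], expected - expected.mean())

    def test_output_finite(self, small_normalized):
        ds, _ = small_normalized
        assert np.isfinite(ds.modality_1.values).all()
        assert np.isfinite(ds.modality_2.values).all()


class TestHighlyVariable:
    def test_top4_of_10_matches_dispersion_ranking(self):
        # genes 0-3 get strongly inflated spread at similar means; the
        # oracle ranks by the mean-binned normalized dispersion computed
        # through a direct scanpy call, independent of the selection wrapper
        import anndata as ad
        import scanpy as sc

        rng = np.random.default_rng(5)
        n = 60
        base = rng.poisson(20.0, size=(n, 10)).astype(float)
        for g in range(4):
            base[:, g] = np.clip(base[:, g] + rng.normal(0, 25, n), 0, None).round()
        rna = OmicsMatrix(base, [f"g{i}" for i in range(10)], "RNA")
        atac = OmicsMatrix(np.ones((n, 2)), ["chr1:0-10", "chr1:20-30"], "ATAC")
        ds = sm.normalize_counts(PairedDataset(rna, atac, [f"c{i}" for i in range(n)]))

        adata = ad.AnnData(X=ds.modality_1.values.copy())
        sc.pp.highly_variable_genes(
            adata, flavor="seurat", min_mean=-np.inf, max_mean=np.inf, min_disp=-np.inf
        )
        disp = np.nan_to_num(adata.var["dispersions_norm"].to_numpy(), nan=-np.inf)
        expected = {f"g{i}" for i in np.argsort(disp)[-4:]}

        out = sm.select_highly_variable(ds, n_rna=4, n_atac=2)
        assert out.modality_1.n_features == 4
        assert set(out.modality_1.feature_ids) == expected

    def test_adt_features_all_preserved(self):
        rng = np.random.default_rng(0)
        rna = OmicsMatrix(rng.poisson(5, (30, 20)).astype(float) + 1, [f"g{i}" for i in range(20)], "RNA")
        adt = OmicsMatrix(rng.poisson(9, (30, 224)).astype(float), [f"p{i}" for i in range(224)], "ADT")
        ds = sm.normalize_counts(PairedDataset(rna, adt, [f"c{i}" for i in range(30)]))
        out = sm.select_highly_variable(ds, n_rna=10)
        assert out.modality_2.n_features == 224
        assert out.modality_1.n_features == 10

    def test_requesting_too_many_keeps_all_with_warning(self, small_normalized):
        ds, _ = small_normalized
        with pytest.warns(UserWarning, match="keeping all"):
            out = sm.select_highly_variable(ds, n_rna=10_000, n_atac=10_000)
        assert out.modality_1.n_features == ds.modality_1.n_features

    def test_selection_deterministic(self, small_normalized):
        ds, _ = small_normalized
        a = sm.select_highly_variable(ds, n_rna=50, n_atac=40)
        b = sm.select_highly_variable(ds, n_rna=50, n_atac=40)
        assert a.modality_1.feature_ids == b.modality_1.feature_ids
        assert a.modality_2.feature_ids == b.modality_2.feature_ids


class TestSplitFolds:
    def test_exact_stratification_two_classes(self):
        ds = _toy_pair(n=10, labels=["a"] * 5 + ["b"] * 5,
                       ids=[f"c{i}" for i in range(10)])
        folds = sm.split_folds(ds, k=5, seed=0)
        labels = np.array(ds.cell_labels)
        for train, test in folds:
            assert len(test) == 2
            assert set(labels[test]) == {"a", "b"}

    def test_test_sets_partition_all_indices(self, small_normalized):
        ds, _ = small_normalized
        folds = sm.split_folds(ds, k=5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(ds.n_cells))

    def test_same_seed_identical_folds(self, small_normalized):
        ds, _ = small_normalized
        f1 = sm.split_folds(ds, k=5, seed=7)
        f2 = sm.split_folds(ds, k=5, seed=7)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_rare_class_stays_in_training(self):
        ds = _toy_pair(n=8, labels=["a"] * 6 + ["b"] * 2,
                       ids=[f"c{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="fewer than"):
            folds = sm.split_folds(ds, k=4, seed=0)
        labels = np.array(ds.cell_labels)
        for train, test in folds:
            assert "b" not in labels[test]
            assert (labels[train] == "b").sum() == 2

    def test_labels_required(self):
        ds = _toy_pair()
        with pytest.raises(ValidationError, match="labels"):
            sm.split_folds(ds, k=2, seed=0)
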