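import numpy as np
import pandas as pd
import pytest

import polyen as pe
from polyen.features import _fit_cell_pca, polynomial_expand


class TestAggregateDonorStats:
    def test_mean_and_sample_variance(self):
        # donor d1 has cells [1, 2, 3] for gene gA -> mean 2, var 1 (n-1 denom)
        values = np.array([[1.0, 2.0], [2.0, 0.0], [3.0, 1.0], [5.0, 4.0], [5.0, 4.0]])
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(5)],
            "donor_id": ["d1"] * 3 + ["d2"] * 2,
            "cell_type": ["T"] * 5,
        })
        donors = pd.DataFrame({"donor_id": ["d1", "d2"], "age": [30.0, 60.0]})
        ds = pe.CellExpressionDataset(values, cells, donors, ["gA", "gB"])
        U, V, retained, dropped = pe.aggregate_donor_stats(ds, "T", min_cells=2)
        assert retained == ["d1", "d2"] and dropped == []
        assert U.loc["d1", "gA"] == pytest.approx(2.0)
        assert V.loc["d1", "gA"] == pytest.approx(1.0)
        # identical cells -> zero variance
        assert U.loc["d2", "gA"] == pytest.approx(5.0)
        assert V.loc["d2", "gA"] == pytest.approx(0.0)

    def test_min_cells_drops_and_reports(self, manual_dataset):
        # d2 has a single cell of type T
        U, V, retained, dropped = pe.aggregate_donor_stats(manual_dataset, "T", min_cells=2)
        assert retained == ["d1"]
        assert dropped == ["d2"]

    def test_unknown_cell_type_errors(self, manual_dataset):
        with pytest.raises(ValueError, match="Missing"):
            pe.aggregate_donor_stats(manual_dataset, "Missing", min_cells=2)

    def test_min_cells_below_two_rejected(self, manual_dataset):
        with pytest.raises(ValueError, match="min_cells"):
            pe.aggregate_donor_stats(manual_dataset, "T", min_cells=1)

    def test_variance_matches_two_pass_formula(self, tiny_cohort):
        dataset, _ = tiny_cohort
        U, V, retained, _ = pe.aggregate_donor_stats(dataset, "TypeA", min_cells=2)
        donor_of_cell = dataset.cell_annotations["donor_id"].to_numpy()
        type_mask = (dataset.cell_annotations["cell_type"] == "TypeA").to_numpy()
        d = retained[0]
        block = dataset.values[type_mask & (donor_of_cell == d)]
        mean = block.sum(axis=0) / len(block)
        two_pass = ((block - mean) ** 2).sum(axis=0) / (len(block) - 1)
        np.testing.assert_allclose(V.loc[d].to_numpy(), two_pass, rtol=1e-10)


class TestPolynomialExpand:
    def test_column_layout_and_squares(self):
        U = np.array([[1.0, 2.0], [0.0, 1.0], [2.0, 0.0]])
        V = np.array([[1.0, 0.0], [4.0, 1.0], [0.0, 2.0]])
        fm = polynomial_expand(U, V, np.array([30.0, 40.0, 50.0]), sources=["g1", "g2"])
        assert fm.n_features == 8
        assert list(fm.column_meta["kind"]) == ["mean1"] * 2 + ["var1"] * 2 + ["mean2"] * 2 + ["var2"] * 2
        # mean^2 column of gene 1 is the element-wise square of its mean column
        mean2_g1 = fm.X[:, fm.column_names.index("g1|mean2")]
        np.testing.assert_allclose(mean2_g1, [1.0, 0.0, 4.0])

    @pytest.mark.parametrize("n_genes", [1, 3, 7])
    def test_four_columns_per_gene(self, n_genes):
        rng = np.random.default_rng(0)
        U = rng.random((4, n_genes))
        V = rng.random((4, n_genes))
        fm = polynomial_expand(U, V, rng.uniform(20, 80, 4))
        assert fm.n_features == 4 * n_genes

    def test_all_zero_input_gives_all_zero_matrix(self):
        fm = polynomial_expand(np.zeros((3, 2)), np.zeros((3, 2)), np.array([30.0, 40, 50]))
        assert not fm.X.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            polynomial_expand(np.zeros((3, 2)), np.zeros((3, 3)), np.zeros(3))

    def test_squared_column_invariant_holds(self, tiny_features):
        fm = tiny_features
        n = fm.n_features // 4
        np.testing.assert_allclose(fm.X[:, 2 * n:3 * n], fm.X[:, :n] ** 2, rtol=1e-12)
        np.testing.assert_allclose(fm.X[:, 3 * n:], fm.X[:, n:2 * n] ** 2, rtol=1e-12)
        assert np.all(fm.X[:, n:2 * n] >= 0)  # variances non-negative in gene space


class TestFeatureInvariances:
    def test_cell_order_permutation_leaves_features_unchanged(self, tiny_cohort):
        dataset, _ = tiny_cohort
        rng = np.random.default_rng(3)
        perm = rng.permutation(dataset.n_cells)
        shuffled = pe.CellExpressionDataset(
            dataset.values[perm],
            dataset.cell_annotations.iloc[perm],
            dataset.donor_annotations,
            dataset.gene_ids,
        )
        a = pe.gene_space_features(dataset, "TypeA", min_cells=2)
        b = pe.gene_space_features(shuffled, "TypeA", min_cells=2)
        np.testing.assert_allclose(a.X, b.X, rtol=1e-10)

    def test_constant_shift_moves_mean_not_variance(self, tiny_cohort):
        dataset, _ = tiny_cohort
        c = 1.7
        shifted = pe.CellExpressionDataset(
            dataset.values + np.r_[c, np.zeros(dataset.n_genes - 1)],
            dataset.cell_annotations,
            dataset.donor_annotations,
            dataset.gene_ids,
        )
        a = pe.gene_space_features(dataset, "TypeA", min_cells=2)
        b = pe.gene_space_features(shifted, "TypeA", min_cells=2)
        g = dataset.gene_ids[0]
        cols = a.column_names
        np.testing.assert_allclose(
            b.X[:, cols.index(f"{g}|mean1")], a.X[:, cols.index(f"{g}|mean1")] + c, rtol=1e-10
        )
        np.testing.assert_allclose(
            b.X[:, cols.index(f"{g}|var1")], a.X[:, cols.index(f"{g}|var1")], rtol=1e-10
        )
        np.testing.assert_allclose(
            b.X[:, cols.index(f"{g}|mean2")],
            (a.X[:, cols.index(f"{g}|mean1")] + c) ** 2,
            rtol=1e-10,
        )


class TestPCAFeatures:
    def test_four_k_columns(self, tiny_cohort):
        dataset, _ = tiny_cohort
        fm, tf = pe.pca_features(dataset, "TypeA", k=5, min_cells=2)
        assert fm.n_features == 20
        assert not fm.is_gene
        assert tf.k == 5

    def test_k_exceeding_rank_errors(self, manual_dataset):
        with pytest.raises(ValueError, match="rank"):
            pe.pca_features(manual_dataset, "T", k=10, min_cells=2)

    def test_held_out_projection_matches_eigendecomposition_oracle(self, tiny_cohort):
        """Projecting held-out cells with stored loadings equals projecting with
        loadings recomputed by an independent eigendecomposition of the training
        covariance."""
        dataset, _ = tiny_cohort
        donors = dataset.donor_ids
        train = dataset.subset_donors(donors[:-2])
        test = dataset.subset_donors(donors[-2:])
        _, tf = pe.pca_features(train, "TypeA", k=3, min_cells=2)

        mask = (train.cell_annotations["cell_type"] == "TypeA").to_numpy()
        cells = train.values[mask]
        centered = cells - cells.mean(axis=0)
        cov = centered.T @ centered / len(cells)
        evals, evecs = np.linalg.eigh(cov)
        top = evecs[:, np.argsort(evals)[::-1][:3]].T

        proj_pkg = tf.project(test.values)
        proj_oracle = (test.values - cells.mean(axis=0)) @ top.T
        # eigenvectors are sign-ambiguous: compare column-wise up to sign
        for j in range(3):
            col, ora = proj_pkg[:, j], proj_oracle[:, j]
            assert np.allclose(col, ora, atol=1e-8) or np.allclose(col, -ora, atol=1e-8)

    def test_rank_one_data_recovered_exactly(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=40)
        direction = np.array([3.0, 0.0, 4.0]) / 5.0
        values = np.outer(t, direction) + 2.0
        tf = _fit_cell_pca(values, k=1)
        scores = tf.project(values)
        recon = scores @ tf.components + tf.center
        np.testing.assert_allclose(recon, values, atol=1e-10)


class TestMetaFeatures:
    def test_concatenation_then_k_columns(self, tiny_cohort):
        dataset, _ = tiny_cohort
        fm, dropped = pe.meta_features(dataset, ["TypeA", "TypeB"], k=4, min_cells=2)
        assert fm.n_features == 4
        assert dropped == []
        assert fm.cell_type == "TypeA+TypeB"

    def test_donor_missing_one_type_is_dropped(self, tiny_cohort):
        dataset, _ = tiny_cohort
        # remove TypeB cells of the first donor
        first = dataset.donor_ids[0]
        drop = (
            (dataset.cell_annotations["donor_id"] == first)
            & (dataset.cell_annotations["cell_type"] == "TypeB")
        ).to_numpy()
        reduced = pe.CellExpressionDataset(
            dataset.values[~drop],
            dataset.cell_annotations.loc[~drop],
            dataset.donor_annotations,
            dataset.gene_ids,
        )
        fm, dropped = pe.meta_features(reduced, ["TypeA", "TypeB"], k=3, min_cells=2)
        assert first in dropped
        assert first not in fm.donor_ids

    def test_unpenalized_fit_invariant_to_full_rank_rotation(self, tiny_cohort):
        """At alpha = 0 a full-rank PC rotation of the design cannot change the
        least-squares fitted values, so training R^2 matches gene space."""
        dataset, _ = tiny_cohort
        gene_fm = pe.gene_space_features(dataset, "TypeA", min_cells=2)
        k = gene_fm.n_donors - 1  # full rank of the centered donor matrix
        meta_fm, _ = pe.meta_features(dataset, ["TypeA"], k=k, min_cells=2)
        m_gene = pe.fit_elastic_net(gene_fm, alpha=0.0, rho=0.5)
        m_meta = pe.fit_elastic_net(meta_fm, alpha=0.0, rho=0.5)
        r2_gene = pe.r2_score(gene_fm.y, m_gene.predict(gene_fm))
        r2_meta = pe.r2_score(meta_fm.y, m_meta.predict(meta_fm))
        assert r2_meta == pytest.approx(r2_gene, abs=1e-8)


class TestPseudoBulk:
    def test_pools_cells_across_types(self):
        # one donor, two cell types contributing [1,3] and [5,7] for one gene
        values = np.array([[1.0], [3.0], [5.0], [7.0]])
        cells = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3", "c4"],
            "donor_id": ["d1"] * 4,
            "cell_type": ["A", "A", "B", "B"],
        })
        donors = pd.DataFrame({"donor_id": ["d1", "d2"], "age": [50.0, 60.0]})
        cells2 = pd.concat([cells, pd.DataFrame({
            "cell_id": ["c5", "c6"], "donor_id": ["d2", "d2"], "cell_type": ["A", "A"]
        })], ignore_index=True)
        values2 = np.vstack([values, [[2.0], [2.0]]])
        ds = pe.CellExpressionDataset(values2, cells2, donors, ["gA"])
        fm = pe.pseudo_bulk_features(ds, min_cells=2)
        cols = fm.column_names
        i = fm.donor_ids.index("d1")
        assert fm.X[i, cols.index("gA|mean1")] == pytest.approx(4.0)
        assert fm.X[i, cols.index("gA|var1")] == pytest.approx(20.0 / 3.0)

    def test_single_type_dataset_equals_per_type_aggregation(self, tiny_cohort):
        dataset, _ = tiny_cohort
        only_a = (dataset.cell_annotations["cell_type"] == "TypeA").to_numpy()
        reduced = pe.CellExpressionDataset(
            dataset.values[only_a],
            dataset.cell_annotations.loc[only_a],
            dataset.donor_annotations,
            dataset.gene_ids,
        )
        pb = pe.pseudo_bulk_features(reduced, min_cells=2)
        ga = pe.gene_space_features(reduced, "TypeA", min_cells=2)
        np.testing.assert_allclose(pb.X, ga.X, rtol=1e-12)

    def test_unannotated_cells_are_included(self, tiny_cohort):
        dataset, _ = tiny_cohort
        cells = dataset.cell_annotations.copy()
        cells.loc[cells.index[:5], "cell_type"] = None
        ds = pe.CellExpressionDataset(
            dataset.values, cells, dataset.donor_annotations, dataset.gene_ids
        )
        pb = pe.pseudo_bulk_features(ds, min_cells=2)
        total_cells = sum(pb.n_cells_per_donor.values())
        assert total_cells == ds.n_cells


class TestSerialization:
    def test_feature_matrix_csv_round_trip(self, tiny_features, tmp_path):
        path = tmp_path / "features.csv"
        tiny_features.to_csv(str(path))
        back = pe.DonorFeatureMatrix.from_csv(str(path))
        np.testing.assert_allclose(back.X, tiny_features.X, rtol=1e-12)
        np.testing.assert_allclose(back.y, tiny_features.y, rtol=1e-12)
        assert back.donor_ids == tiny_features.donor_ids
        assert list(back.column_meta["kind"]) == list(tiny_features.column_meta["kind"])
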