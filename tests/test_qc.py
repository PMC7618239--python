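import math

import numpy as np
import pytest

from sstdiv.qc import (
    batch_center,
    lognormalize,
    pca,
    qc_filter,
    scale_center,
    select_variable_features,
)
from sstdiv.simulate import SimSpec, flat_spec, simulate_counts

from conftest import toy_counts, toy_metadata


class TestQCFilter:
    def test_hand_counted_cell_removal(self):
        """6 cells; 2 fail the gene-count criterion, 1 fails mito -> 3 kept.

        Gene-count threshold is lowered to 3 for the toy scale; detection
        and adaptive filters are disabled by construction.
        """
        x = np.array(
            [
                [5, 4, 3, 2, 1],  # 5 genes
                [5, 4, 3, 2, 1],
                [5, 4, 3, 2, 1],
                [5, 0, 0, 0, 0],  # 1 gene -> fails
                [5, 4, 0, 0, 0],  # 2 genes -> fails
                [5, 4, 3, 2, 1],  # fails mito
            ]
        )
        cm = toy_counts(x)
        meta = toy_metadata(cm, pct_mito=[0.01] * 5 + [0.2])
        out, meta_out, report = qc_filter(
            cm, meta, min_cells_per_gene=1, min_genes_per_cell=3
        )
        assert out.n_cells == 3
        assert report.cells_removed_low_genes == 2
        assert report.cells_removed_high_mito == 1

    def test_degenerate_distribution_removes_none(self):
        x = np.tile([3, 2, 1, 1], (8, 1))
        cm = toy_counts(x)
        meta = toy_metadata(cm)
        out, _, report = qc_filter(
            cm, meta, min_cells_per_gene=1, min_genes_per_cell=2
        )
        assert report.cells_removed_low_aligned == 0
        assert report.cells_removed_low_umi == 0
        assert out.n_cells == 8

    def test_gene_detected_in_nine_cells_removed(self):
        x = np.zeros((12, 3), dtype=int)
        x[:, 0] = 5
        x[:, 2] = 5
        x[:9, 1] = 1  # detected in exactly 9 cells
        cm = toy_counts(x)
        meta = toy_metadata(cm)
        out, _, report = qc_filter(cm, meta, min_genes_per_cell=0)
        assert "g1" not in out.gene_ids
        assert report.genes_removed_low_detection == 1

    def test_flagged_gene_classes_removed(self):
        x = np.ones((12, 4), dtype=int) * 3
        cm = toy_counts(
            x,
            gene_ids=["mt-A", "Rps9", "Ddx3y", "Actb"],
            mitochondrial=["mt-A"],
            ribosomal=["Rps9"],
            y_chromosome=["Ddx3y"],
        )
        meta = toy_metadata(cm)
        out, _, report = qc_filter(cm, meta, min_genes_per_cell=2)
        assert out.gene_ids == ["Actb"]
        assert report.genes_removed_flagged == 3

    def test_permutation_invariance_of_retained_set(self, rng):
        cm, meta = simulate_counts(flat_spec(n_cells=50, n_genes=300, seed=3))
        out1, _, _ = qc_filter(cm, meta, min_genes_per_cell=100)
        perm = rng.permutation(cm.n_cells)
        out2, _, _ = qc_filter(cm.subset_cells(perm), meta, min_genes_per_cell=100)
        assert sorted(out1.cell_ids) == sorted(out2.cell_ids)

    def test_stressed_cells_preferentially_removed(self):
        cm, meta = simulate_counts(SimSpec(seed=2, stressed_fraction=0.1))
        out, meta_out, _ = qc_filter(cm, meta)
        before = meta.table["truth_stressed"].mean()
        after = meta_out.table["truth_stressed"].mean()
        assert after < before / 2


class TestLognormalize:
    def test_zero_maps_to_zero_and_formula_value(self):
        cm = toy_counts([[0, 1000], [1, 999]])
        norm = lognormalize(cm, S=1000)
        assert norm.values[0, 0] == 0.0
        assert norm.values[1, 0] == pytest.approx(math.log(2), rel=1e-12)

    def test_library_size_invariance(self):
        cm1 = toy_counts([[2, 8], [3, 7]])
        cm2 = toy_counts([[4, 16], [6, 14]])
        n1, n2 = lognormalize(cm1), lognormalize(cm2)
        np.testing.assert_allclose(n1.values, n2.values)

    def test_monotone_within_cell(self, rng):
        x = rng.integers(0, 50, size=(1, 30))
        norm = lognormalize(toy_counts(x + 0))
        order_x = np.argsort(x[0], kind="stable")
        assert np.all(np.diff(norm.values[0][order_x]) >= 0)

    def test_zero_total_cell_rejected(self):
        cm = toy_counts([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="QC"):
            lognormalize(cm)


class TestVariableFeatures:
    def test_constant_gene_ranks_last(self, rng):
        x = rng.poisson(2.0, size=(100, 20))
        x[:, 5] = 4
        cm = toy_counts(x)
        vf = select_variable_features(cm, n=10)
        assert vf.iloc[-1]["gene"] == "g5"
        assert vf.iloc[-1]["std_variance"] == 0.0

    def test_planted_markers_rank_high(self):
        hits = 0
        for seed in range(10):
            cm, meta = simulate_counts(flat_spec(n_cells=80, seed=seed))
            vf = select_variable_features(cm, n=100)
            top = set(vf.loc[vf["selected"], "gene"])
            markers = set(cm.gene_ids[:60])
            hits += len(markers & top) / len(markers)
        assert hits / 10 >= 0.95

    def test_requesting_more_than_available_warns(self, rng):
        cm = toy_counts(rng.poisson(1.0, size=(30, 10)))
        with pytest.warns(UserWarning, match="variable features"):
            vf = select_variable_features(cm, n=50)
        assert vf["selected"].all()


class TestScaleCenter:
    def test_mean_zero_unit_variance(self, rng):
        from sstdiv.containers import NormalizedMatrix

        vals = rng.gamma(2, 1, size=(200, 10))
        norm = NormalizedMatrix(vals, [f"c{i}" for i in range(200)], [f"g{j}" for j in range(10)])
        z = scale_center(norm, norm.gene_ids, clip=100)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(z.var(axis=0), 1, atol=1e-8)

    def test_constant_gene_all_zero(self):
        from sstdiv.containers import NormalizedMatrix

        vals = np.ones((50, 2))
        vals[:, 1] = np.arange(50)
        norm = NormalizedMatrix(vals, [f"c{i}" for i in range(50)], ["g0", "g1"])
        z = scale_center(norm, ["g0", "g1"])
        assert np.all(z[:, 0] == 0)
        assert np.isfinite(z).all()

    def test_clipping_cap(self, rng):
        from sstdiv.containers import NormalizedMatrix

        vals = rng.standard_cauchy(size=(500, 5)) ** 2  # heavy tails
        norm = NormalizedMatrix(np.abs(vals), [f"c{i}" for i in range(500)], [f"g{j}" for j in range(5)])
        z = scale_center(norm, norm.gene_ids, clip=10)
        assert np.abs(z).max() <= 10


class TestBatchCenter:
    def test_single_batch_identity(self, rng):
        x = rng.normal(size=(40, 6))
        out = batch_center(x, ["b"] * 40)
        np.testing.assert_allclose(out, x - x.mean(axis=0))

    def test_additive_shift_removed(self, rng):
        x = rng.normal(size=(60, 8))
        shift = np.zeros(8)
        shift[:4] = 3.0
        x2 = np.vstack([x, x + shift])
        batches = ["b1"] * 60 + ["b2"] * 60
        out = batch_center(x2, batches)
        c1 = out[:60].mean(axis=0)
        c2 = out[60:].mean(axis=0)
        np.testing.assert_allclose(np.linalg.norm(c1 - c2), 0, atol=1e-10)

    def test_tiny_batch_left_unadjusted(self, rng):
        x = rng.normal(size=(5, 3))
        out = batch_center(x, ["a", "a", "a", "a", "b"])
        np.testing.assert_allclose(out[4], x[4])


class TestPCA:
    def test_rank_one_data(self):
        u = np.arange(30.0)[:, None]
        v = np.array([[1.0, 2.0, 3.0]])
        emb, evr = pca(u @ v, n_components=3)
        assert evr[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        x = rng.normal(size=(40, 12))
        xc = x - x.mean(axis=0)
        from sklearn.decomposition import PCA

        model = PCA(n_components=12, svd_solver="full").fit(x)
        rec = model.inverse_transform(model.transform(x))
        np.testing.assert_allclose(rec, x, atol=1e-8)
        emb, evr = pca(x, n_components=12)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_top_subspace_matches_eigendecomposition(self, rng):
        x = rng.normal(size=(50, 20)) @ np.diag(np.linspace(3, 0.5, 20))
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (len(x) - 1)
        evals, evecs = np.linalg.eigh(cov)
        top3 = evecs[:, ::-1][:, :3]
        emb, _ = pca(x, n_components=3)
        proj_oracle = xc @ top3
        # compare spanned subspaces via canonical correlations
        q1, _ = np.linalg.qr(emb)
        q2, _ = np.linalg.qr(proj_oracle)
        s = np.linalg.svd(q1.T @ q2, compute_uv=False)
        np.testing.assert_allclose(s, 1.0, atol=1e-8)
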