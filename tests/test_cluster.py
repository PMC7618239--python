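import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sstdiv.cluster import (
    COLLAPSED,
    cluster_once,
    iterative_cluster,
    merge_failed,
    qualify_clusters,
)
from sstdiv.containers import NormalizedMatrix
from sstdiv.qc import lognormalize
from sstdiv.simulate import flat_spec, simulate_counts


def blobs(rng, centers, n_per, scale=0.3):
    xs, labels = [], []
    for i, c in enumerate(centers):
        xs.append(rng.normal(loc=c, scale=scale, size=(n_per, len(c))))
        labels += [i] * n_per
    return np.vstack(xs), np.array(labels)


class TestClusterOnce:
    def test_two_blobs_recovered_exactly(self, rng):
        x, truth = blobs(rng, [np.zeros(10), np.full(10, 3.0) * np.sign(np.arange(10) - 4.5)], 40)
        labels, k, sils = cluster_once(x, metric="euclidean_pca")
        assert k == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_three_blobs_beat_brute_force_silhouette(self, rng):
        """The selected cut maximizes mean silhouette over all cuts 2..20,
        checked against direct evaluation of every cut."""
        centers = [np.zeros(8), np.r_[np.full(4, 4.0), np.zeros(4)], np.r_[np.zeros(4), np.full(4, 4.0)]]
        x, truth = blobs(rng, centers, 30)
        labels, k, sils = cluster_once(x, metric="euclidean_pca")
        assert k == 3
        assert adjusted_rand_score(truth, labels) == 1.0
        assert sils[k] == max(sils.values())

    def test_k_range_truncated_by_cell_count(self, rng):
        x = rng.normal(size=(10, 5))
        labels, k, sils = cluster_once(x, metric="euclidean_pca")
        assert max(sils) <= 9

    def test_identical_cells_single_cluster(self):
        x = np.ones((20, 5))
        with pytest.warns(UserWarning, match="identical"):
            labels, k, sils = cluster_once(x)
        assert k == 1
        assert len(np.unique(labels)) == 1


class TestQualifyClusters:
    def make_norm(self, rng, n=120, n_genes=60, planted=True):
        x = rng.poisson(1.0, size=(n, n_genes)).astype(float)
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        if planted:
            x[labels == "a", :10] += rng.poisson(5.0, size=(n // 2, 10))
        vals = np.log1p(x)
        return (
            NormalizedMatrix(vals, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(n_genes)]),
            labels,
        )

    def test_small_cluster_fails_on_size(self, rng):
        norm, labels = self.make_norm(rng, n=120)
        labels = np.array(["a"] * 49 + ["b"] * 71)
        norm.values[:49, :10] += 5.0
        qual = qualify_clusters(norm, labels)
        assert not qual.loc["a", "passed"]
        assert qual.loc["a", "descore"] > 60  # fails despite a huge DEscore

    def test_boundary_descore_of_sixty_passes(self):
        """Three capped genes give exactly 60, which is not < 60."""
        from sstdiv.de import de_score

        assert de_score([1e-25, 1e-25, 1e-25]) == 60.0

    def test_twin_clusters_fail(self, rng):
        norm, labels = self.make_norm(rng, planted=False)
        qual = qualify_clusters(norm, labels)
        assert not qual["passed"].any()
        assert (qual["descore"] < 60).all()

    def test_planted_split_passes(self, rng):
        norm, labels = self.make_norm(rng, planted=True)
        qual = qualify_clusters(norm, labels)
        assert qual.loc["a", "passed"]


class TestMergeFailed:
    def test_failed_absorbed_by_nearest(self, rng):
        x = np.vstack(
            [
                rng.normal(0, 0.2, size=(60, 6)) + [3, 0, 0, 0, 0, 0],
                rng.normal(0, 0.2, size=(60, 6)) + [0, 3, 0, 0, 0, 0],
                rng.normal(0, 0.2, size=(10, 6)) + [2.4, 0.6, 0, 0, 0, 0],  # near A
            ]
        )
        labels = np.array(["A"] * 60 + ["B"] * 60 + ["F"] * 10)
        qual = pd.DataFrame(
            {"passed": [True, True, False], "size": [60, 60, 10], "descore": [100, 100, 0]},
            index=["A", "B", "F"],
        )
        merged = merge_failed(labels, qual, x)
        assert set(np.unique(merged)) == {"A", "B"}
        assert (merged[-10:] == "A").all()

    def test_no_failed_is_identity(self, rng):
        x = rng.normal(size=(20, 4))
        labels = np.array(["A", "B"] * 10)
        qual = pd.DataFrame({"passed": [True, True]}, index=["A", "B"])
        merged = merge_failed(labels, qual, x)
        assert np.array_equal(merged, labels)

    def test_single_qualifier_collapses(self, rng):
        x = rng.normal(size=(30, 4))
        labels = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        qual = pd.DataFrame({"passed": [True, False, False]}, index=["A", "B", "C"])
        assert merge_failed(labels, qual, x) == COLLAPSED


class TestIterativeCluster:
    def test_planted_hierarchy_recovered(self, hier_dataset):
        from sstdiv.qc import qc_filter

        cm, meta, _ = hier_dataset
        cm, meta, _ = qc_filter(cm, meta)
        norm = lognormalize(cm)
        tree = iterative_cluster(cm, norm)
        lab = tree.leaf_assignments()
        truth = meta.table["truth_label"].loc[lab.index]
        assert adjusted_rand_score(truth, lab) >= 0.9
        # leaves partition the cells exactly
        assert sorted(lab.index) == sorted(cm.cell_ids)
        # every subdivided node's surviving children passed DEscore and size
        def walk(node):
            if node.children:
                passed = [q for q in node.qualification.values() if q["passed"]]
                assert passed, f"subdivided node {node.label} without qualifying children"
            for ch in node.children:
                walk(ch)

        walk(tree)

    def test_determinism(self):
        cm, meta = simulate_counts(flat_spec(n_cells=80, n_genes=400, seed=21))
        norm = lognormalize(cm)
        t1 = iterative_cluster(cm, norm)
        t2 = iterative_cluster(cm, norm)
        assert t1.leaf_assignments().equals(t2.leaf_assignments())

    def test_homogeneous_data_single_leaf(self):
        from sstdiv.simulate import null_spec

        cm, meta = simulate_counts(null_spec(n_cells=200, n_genes=600, seed=13))
        norm = lognormalize(cm)
        tree = iterative_cluster(cm, norm)
        assert len(tree.leaves()) == 1
        assert tree.leaves()[0].label == "0"

    def test_small_strong_cluster_kept_but_not_subdivided(self):
        """A 60-cell cluster with strong markers appears as a leaf (>= 50)
        but is below the recursion size of 100 and is never subdivided."""
        spec = flat_spec(n_clusters=2, n_cells=200, n_genes=800, seed=31)
        spec.hierarchy = {"A": ["1"], "B": ["1"], "S": ["1"]}
        import dataclasses

        spec = dataclasses.replace(spec)
        cm, meta = simulate_counts(spec)
        # shrink cluster S to 60 cells
        keep = np.ones(cm.n_cells, dtype=bool)
        s_cells = np.flatnonzero(meta.table["truth_type"] == "S")
        keep[s_cells[60:]] = False
        cm = cm.subset_cells(keep)
        meta = meta.subset(cm.cell_ids)
        norm = lognormalize(cm)
        tree = iterative_cluster(cm, norm)
        truth = meta.table["truth_type"]
        small_leaves = [
            leaf for leaf in tree.leaves() if 50 <= len(leaf.cell_ids) < 100
        ]
        assert small_leaves, "expected a leaf between the size and recursion limits"
        s_leaf = small_leaves[0]
        # the small leaf is dominated by the planted 60-cell cluster ...
        assert (truth.loc[s_leaf.cell_ids] == "S").mean() > 0.8
        # ... and was accepted as terminal without subdivision
        assert not s_leaf.children and s_leaf.status == "terminal"
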