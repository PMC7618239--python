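"""Recursive DEscore-guided hierarchical clustering.

Each node is processed with the same seven steps: recompute variable genes
and scale within the node; average-linkage hierarchical clustering; pick the
dendrogram cut k in 2..20 with the best mean silhouette; compute one-vs-rest
DEGs per candidate cluster at a minimum logFC of ln(2); score each cluster
(DEscore) and fail any with DEscore < 60 or fewer than 50 cells; merge
failed clusters into the nearest qualifying cluster (re-checking the merged
ones); recurse into qualifying clusters of at least 100 cells.  A node whose
candidate children all fail — or that collapses to a single qualifying
cluster — is returned as a terminal identity.

The dissimilarity is 1 - Pearson correlation between cells over the node's
scaled variable genes (Euclidean on PCA available via config).  Clustering
is fully deterministic: no randomness enters at any step.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .config import PipelineConfig
from .containers import CountMatrix, NormalizedMatrix
from .de import de_score, filter_degs, wilcoxon_one_vs_rest
from .qc import batch_center, pca, scale_center, select_variable_features

log = logging.getLogger("sstdiv")

COLLAPSED = "__collapsed__"


def correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows sit at distance 1."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    d = np.ones((x.shape[0], x.shape[0]))
    if ok.sum() >= 2:
        c = np.corrcoef(x[ok])
        d[np.ix_(ok, ok)] = 1.0 - c
    # constant profiles are mutually identical (distance 0) but uncorrelated
    # with everything else (distance 1)
    if (~ok).sum() >= 2:
        d[np.ix_(~ok, ~ok)] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_distance_once(
    dist: np.ndarray, k_min: int = 2, k_max: int = 20
) -> tuple[np.ndarray, int, dict[int, float]]:
    """Average-linkage clustering of a precomputed dissimilarity matrix.

    Cuts the dendrogram at every k in [k_min, min(k_max, n-1)], scores each
    cut by mean silhouette width under the same dissimilarity, and returns
    the labels at the best k (ties broken toward smaller k).
    """
    n = dist.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items to cluster")
    if not np.any(dist > 1e-12):
        warnings.warn("all items identical; returning a single cluster")
        return np.zeros(n, dtype=int), 1, {}
    z = linkage(squareform(dist, checks=False), method="average")
    hi = min(k_max, n - 1)
    sils: dict[int, float] = {}
    labels_at: dict[int, np.ndarray] = {}
    for k in range(k_min, hi + 1):
        lab = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2 or len(np.unique(lab)) != k:
            continue
        labels_at[k] = lab
        sils[k] = float(silhouette_score(dist, lab, metric="precomputed"))
    if not sils:
        warnings.warn("no valid dendrogram cut; returning a single cluster")
        return np.zeros(n, dtype=int), 1, {}
    best_k = min(k for k, s in sils.items() if s >= max(sils.values()) - 1e-12)
    labels = _canonical_labels(labels_at[best_k])
    return labels, best_k, sils


def _canonical_labels(lab: np.ndarray) -> np.ndarray:
    """Relabel to 0..k-1 in order of first occurrence (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty(lab.size, dtype=int)
    for i, v in enumerate(lab):
        if v not in mapping:
            mapping[v] = len(mapping)
        out[i] = mapping[v]
    return out


def cluster_once(
    scaled: np.ndarray,
    k_min: int = 2,
    k_max: int = 20,
    metric: str = "correlation",
    n_pcs: int = 15,
) -> tuple[np.ndarray, int, dict[int, float]]:
    """Cluster one node's cells from its scaled matrix (see module docstring)."""
    if metric == "correlation":
        dist = correlation_distance(scaled)
    elif metric == "euclidean_pca":
        emb, _ = pca(scaled, n_components=min(n_pcs, min(scaled.shape)))
        diff = emb[:, None, :] - emb[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return cluster_distance_once(dist, k_min=k_min, k_max=k_max)


def qualify_clusters(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    descore_min: float = 60.0,
    size_min: int = 50,
    lfc_min: float = np.log(2.0),
    alpha: float = 0.01,
) -> pd.DataFrame:
    """DEscore / size qualification of candidate clusters within one node.

    DEGs are one-vs-rest within the node's cells only; a cluster fails iff
    DEscore < descore_min OR size < size_min (strict comparisons).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 clusters to qualify")
    rows = []
    for c in uniq:
        res = wilcoxon_one_vs_rest(norm, labels, c)
        degs = filter_degs(res, lfc_min=lfc_min, alpha=alpha)
        score = de_score(res.table.loc[degs, "p_adj"])
        size = int((labels == c).sum())
        rows.append(
            {
                "cluster": c,
                "size": size,
                "n_degs": len(degs),
                "descore": score,
                "passed": not (score < descore_min or size < size_min),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def merge_failed(
    labels: np.ndarray,
    qual: pd.DataFrame,
    scaled: np.ndarray,
    requalify=None,
) -> np.ndarray | str:
    """Absorb failed clusters into the nearest qualifying cluster.

    "Nearest" is the smallest centroid distance in correlation-distance
    space.  After each merge round the merged clusters are re-qualified via
    ``requalify`` (labels -> qualification frame); a merged cluster that
    still fails is pushed into its next-nearest qualifying partner on the
    following round.  Returns the final labels, or :data:`COLLAPSED` when
    only one qualifying cluster remains.
    """
    labels = np.asarray(labels).copy()
    while True:
        failed = qual.index[~qual["passed"]].tolist()
        passing = qual.index[qual["passed"]].tolist()
        if not failed:
            return labels
        if len(passing) <= 1:
            return COLLAPSED
        centroids = {c: scaled[labels == c].mean(axis=0) for c in qual.index}
        for c in failed:
            dists = {
                q: float(correlation_distance(np.vstack([centroids[c], centroids[q]]))[0, 1])
                for q in passing
            }
            target = min(sorted(dists), key=lambda q: (dists[q], str(q)))
            labels[labels == c] = target
        if requalify is None:
            return labels
        if len(np.unique(labels)) < 2:
            return COLLAPSED
        qual = requalify(labels)


@dataclass
class ClusterNode:
    """One node of the recursive clustering tree."""

    label: str
    cell_ids: list[str]
    k_max: int | None = None
    silhouettes: dict = field(default_factory=dict)
    qualification: dict = field(default_factory=dict)
    status: str = "terminal"  # "subdivided" or "terminal"
    reason: str = ""
    children: list = field(default_factory=list)

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        return [leaf for ch in self.children for leaf in ch.leaves()]

    def leaf_assignments(self) -> pd.Series:
        pairs = [(cid, leaf.label) for leaf in self.leaves() for cid in leaf.cell_ids]
        ser = pd.Series(dict(pairs), name="label")
        return ser

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_cells": len(self.cell_ids),
            "k_max": self.k_max,
            "silhouettes": {str(k): v for k, v in self.silhouettes.items()},
            "qualification": self.qualification,
            "status": self.status,
            "reason": self.reason,
            "children": [c.to_dict() for c in self.children],
            "cell_ids": self.cell_ids if not self.children else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


class ClusterTree(ClusterNode):
    """Alias for the root node of a clustering run."""


def iterative_cluster(
    counts: CountMatrix,
    norm: NormalizedMatrix,
    config: PipelineConfig | None = None,
    batches=None,
) -> ClusterNode:
    """Run the recursive clustering on a QC'd dataset.

    ``counts`` supplies raw counts for per-node variable-gene selection;
    ``norm`` supplies log-normalized values for scaling and for DE.  If
    ``batches`` is given the scaled matrix is batch-centered per node before
    distances are computed (DE still reads ``norm`` only).
    """
    cfg = config or PipelineConfig()
    if counts.cell_ids != norm.cell_ids or counts.gene_ids != norm.gene_ids:
        raise ValueError("counts and norm must share cells and genes")
    batches = np.asarray(batches) if batches is not None else None
    idx = np.arange(counts.n_cells)
    return _cluster_node(counts, norm, cfg, batches, idx, label="0")


def _node_scaled(counts, norm, cfg, batches, idx):
    sub_counts = counts.subset_cells(idx)
    expressed = sub_counts.cells_per_gene() >= 1
    pool = sub_counts.subset_genes(expressed)
    n_var = min(cfg.n_variable_features, pool.n_genes)
    vf = select_variable_features(pool, n=n_var)
    genes = vf.loc[vf["selected"], "gene"].tolist()
    scaled = scale_center(norm.subset_cells(idx), genes, clip=cfg.scale_clip)
    if batches is not None:
        scaled = batch_center(scaled, batches[idx])
    return scaled


def _cluster_node(counts, norm, cfg, batches, idx, label) -> ClusterNode:
    cell_ids = [counts.cell_ids[i] for i in idx]
    node = ClusterNode(label=label, cell_ids=cell_ids)
    if idx.size < 3:
        node.reason = "too few cells"
        return node

    scaled = _node_scaled(counts, norm, cfg, batches, idx)
    labels, k_max, sils = cluster_once(
        scaled, cfg.k_min, cfg.k_max, metric=cfg.cluster_metric, n_pcs=cfg.n_pcs
    )
    node.k_max = k_max
    node.silhouettes = sils
    if k_max < 2:
        node.reason = "no valid subdivision"
        return node

    norm_node = norm.subset_cells(idx)

    def requalify(lab):
        return qualify_clusters(
            norm_node,
            lab,
            descore_min=cfg.descore_min,
            size_min=cfg.cluster_size_min,
            lfc_min=cfg.cluster_lfc_min,
            alpha=cfg.de_alpha,
        )

    qual = requalify(labels)
    node.qualification = {
        str(c): {k: (float(v) if k != "passed" else bool(v)) for k, v in row.items()}
        for c, row in qual.iterrows()
    }
    if not qual["passed"].any():
        node.reason = "all candidate clusters failed"
        return node

    merged = merge_failed(labels, qual, scaled, requalify=requalify)
    if isinstance(merged, str) and merged == COLLAPSED:
        node.reason = "collapsed to a single qualifying cluster"
        return node
    labels = merged
    uniq = np.unique(labels)
    if uniq.size < 2:
        node.reason = "collapsed to a single qualifying cluster"
        return node

    node.status = "subdivided"
    for j, c in enumerate(uniq):
        child_idx = idx[labels == c]
        child_label = f"{label}.{j}"
        if child_idx.size >= cfg.recurse_size_min:
            child = _cluster_node(counts, norm, cfg, batches, child_idx, child_label)
        else:
            child = ClusterNode(
                label=child_label,
                cell_ids=[counts.cell_ids[i] for i in child_idx],
                reason="below recursion size",
            )
        node.children.append(child)
    return node
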