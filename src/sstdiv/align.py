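"""Cross-dataset cluster correspondence and marker-based annotation.

Cluster replicability between two labeled datasets is scored by
neighbor voting on a rank-standardized Spearman correlation network
(MetaNeighbor-style): cells of both datasets are joined over a common gene
set, each dataset-B cell receives a vote for cluster a equal to its
normalized network connectivity to a's cells, and the AUROC of those votes
for picking out cluster b among dataset-B cells is the correspondence score
for the pair (a, b).  AUROC > 0.75 is read as a strong identity match
(> 0.8 for spatial panels).

Cluster annotation scores each cluster against candidate marker sets with
the DEscore restricted to the marker genes; a stress-marker DEscore above 10
flags the cluster as stressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix
from .de import MarkerSet, de_score, filter_degs, wilcoxon_one_vs_rest


@dataclass
class AlignmentMatrix:
    """Cluster x cluster AUROC table (rows: dataset A, columns: dataset B)."""

    auroc: pd.DataFrame
    gene_set: list
    threshold: float = 0.75

    def __post_init__(self) -> None:
        vals = self.auroc.to_numpy(dtype=float)
        if np.any((vals < -1e-9) | (vals > 1 + 1e-9)):
            raise ValueError("AUROC outside [0, 1]")
        if self.auroc.index.has_duplicates or self.auroc.columns.has_duplicates:
            raise ValueError("duplicate cluster labels")

    def to_tsv(self, path) -> None:
        self.auroc.to_csv(path, sep="\t", index_label="cluster_a")


def rank_auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUROC by the rank (Mann-Whitney) formula with average ranks for ties."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n1 = int(positives.sum())
    n2 = positives.size - n1
    if n1 == 0 or n2 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[positives].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def neighbor_voting_auroc(
    norm_a: NormalizedMatrix,
    labels_a,
    norm_b: NormalizedMatrix,
    labels_b,
    gene_set: list[str],
) -> AlignmentMatrix:
    """Neighbor-voting replicability AUROC for every cluster pair (a, b)."""
    if not gene_set:
        raise ValueError("empty gene set")
    labels_a = np.asarray(labels_a).astype(str)
    labels_b = np.asarray(labels_b).astype(str)
    for lab, n in ((labels_a, norm_a.n_cells), (labels_b, norm_b.n_cells)):
        if lab.size != n:
            raise ValueError("labels length mismatch")
    for labels in (labels_a, labels_b):
        counts = pd.Series(labels).value_counts()
        if (counts < 2).any():
            raise ValueError("every cluster needs >= 2 cells")

    xa = norm_a.values[:, norm_a.gene_index(list(gene_set))]
    xb = norm_b.values[:, norm_b.gene_index(list(gene_set))]
    x = np.vstack([xa, xb])
    n_a = xa.shape[0]

    # Spearman network between cells: Pearson on per-cell gene ranks
    ranks = stats.rankdata(x, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((ranks**2).sum(axis=1))
    denom[denom == 0] = 1.0
    ranks /= denom[:, None]
    net = ranks @ ranks.T

    # rank-standardize the whole network to [0, 1]
    flat = stats.rankdata(net.ravel())
    net = (flat / flat.max()).reshape(net.shape)
    np.fill_diagonal(net, 0.0)

    b_rows = net[n_a:, :n_a]  # B cells' connectivity into dataset A
    degree = b_rows.sum(axis=1)
    degree[degree == 0] = 1.0

    clusters_a = sorted(np.unique(labels_a))
    clusters_b = sorted(np.unique(labels_b))
    out = pd.DataFrame(index=clusters_a, columns=clusters_b, dtype=float)
    for a in clusters_a:
        votes = b_rows[:, labels_a == a].sum(axis=1) / degree
        for b in clusters_b:
            out.loc[a, b] = rank_auroc(votes, labels_b == b)
    return AlignmentMatrix(out, gene_set=list(gene_set))


def match_clusters(m: AlignmentMatrix, threshold: float = 0.75) -> dict:
    """All pairs with AUROC strictly above ``threshold`` (one-to-many kept)."""
    pairs = []
    for a in m.auroc.index:
        for b in m.auroc.columns:
            v = float(m.auroc.loc[a, b])
            if v > threshold:
                pairs.append({"cluster_a": a, "cluster_b": b, "auroc": v})
    pairs.sort(key=lambda r: (-r["auroc"], str(r["cluster_a"]), str(r["cluster_b"])))
    matched_a = {p["cluster_a"] for p in pairs}
    matched_b = {p["cluster_b"] for p in pairs}
    return {
        "matches": pairs,
        "unmatched_a": [c for c in m.auroc.index if c not in matched_a],
        "unmatched_b": [c for c in m.auroc.columns if c not in matched_b],
        "threshold": threshold,
    }


def annotate_by_marker_descore(
    norm: NormalizedMatrix,
    labels,
    marker_sets: list[MarkerSet],
    stress_markers: list[str] | None = None,
    stress_cut: float = 10.0,
    lfc_min: float = np.log(1.5),
    alpha: float = 0.01,
    ambiguity_rel_diff: float = 0.10,
) -> pd.DataFrame:
    """Assign each cluster the marker set with the highest restricted DEscore.

    The DE test is restricted to each candidate set's genes (Bonferroni over
    the genes tested in that restricted run); only up-regulated significant
    markers contribute.  Clusters whose stress-marker DEscore exceeds
    ``stress_cut`` are labeled "stressed"; near-ties (top two scores within
    ``ambiguity_rel_diff`` relative difference) or all-zero scores are
    "ambiguous" — to be resolved by cross-dataset alignment.
    """
    if not marker_sets or any(not m.genes for m in marker_sets):
        raise ValueError("marker sets must be non-empty")
    labels = np.asarray(labels).astype(str)
    present = set(norm.gene_ids)
    rows = []
    for c in sorted(np.unique(labels)):
        scores = {}
        for ms in marker_sets:
            genes = [g for g in ms.genes if g in present]
            scores[ms.label] = _restricted_descore(norm, labels, c, genes, lfc_min, alpha)
        stress_score = 0.0
        if stress_markers:
            genes = [g for g in stress_markers if g in present]
            stress_score = _restricted_descore(norm, labels, c, genes, lfc_min, alpha)
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        top_label, top = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else 0.0
        if stress_score > stress_cut:
            call = "stressed"
        elif top <= 0:
            call = "ambiguous"
        elif second > 0 and (top - second) / top < ambiguity_rel_diff:
            call = "ambiguous"
        else:
            call = top_label
        rows.append(
            {"cluster": c, "call": call, "stress_descore": stress_score, **scores}
        )
    return pd.DataFrame(rows).set_index("cluster")


def _restricted_descore(norm, labels, cluster, genes, lfc_min, alpha) -> float:
    if not genes:
        return 0.0
    res = wilcoxon_one_vs_rest(norm, labels, cluster, genes=genes)
    degs = filter_degs(res, lfc_min=lfc_min, alpha=alpha)
    return de_score(res.table.loc[degs, "p_adj"])


def intersect_deg_gene_set(
    norm_a: NormalizedMatrix, labels_a, norm_b: NormalizedMatrix, labels_b,
    lfc_min: float = np.log(1.5), alpha: float = 0.01,
) -> list[str]:
    """Default alignment gene set: intersection of the two datasets' DEG unions."""
    def deg_union(norm, labels):
        out = set()
        for c in np.unique(np.asarray(labels).astype(str)):
            res = wilcoxon_one_vs_rest(norm, np.asarray(labels).astype(str), c)
            out.update(filter_degs(res, lfc_min=lfc_min, alpha=alpha))
        return out

    return sorted(deg_union(norm_a, labels_a) & deg_union(norm_b, labels_b))
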