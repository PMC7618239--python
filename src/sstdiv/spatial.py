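"""Spatial transcriptomics downstream analysis.

Works on a per-cell table from a multiplexed smFISH panel (~94 genes) with
x/y position and a cortical layer annotation.  SST+ interneurons are
isolated by gating: the table is clustered and only clusters in which all
four gate genes (Sst, Gad1, Gad2, Lhx6) are significantly enriched are
retained.  Laminar distributions are tabulated per cluster, and the
superficial (layers 1-4) versus deep (layers 5-6) split is compared between
conditions with a two-sided Fisher exact test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.stats.contingency import odds_ratio

from .align import match_clusters, neighbor_voting_auroc
from .cluster import iterative_cluster
from .config import PipelineConfig
from .containers import CountMatrix, NormalizedMatrix
from .de import filter_degs, wilcoxon_one_vs_rest
from .qc import lognormalize

log = logging.getLogger("sstdiv")

META_COLS = ("x", "y", "layer", "truth_cluster", "is_sst", "cluster")


def panel_genes(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def table_to_counts(table: pd.DataFrame) -> CountMatrix:
    genes = panel_genes(table)
    counts = sp.csr_matrix(table[genes].to_numpy(dtype=np.int64))
    return CountMatrix(counts, table.index.astype(str).tolist(), genes)


def cluster_spatial(table: pd.DataFrame, config: PipelineConfig | None = None) -> pd.Series:
    """Cluster panel counts with the same iterative procedure as scRNA-seq.

    Small panels support shallower trees; size thresholds come from config.
    """
    cfg = config or PipelineConfig()
    cm = table_to_counts(table)
    keep = cm.total_umi() > 0
    cm = cm.subset_cells(keep)
    norm = lognormalize(cm, S=cfg.scale_factor)
    tree = iterative_cluster(cm, norm, cfg)
    labels = tree.leaf_assignments()
    return labels.reindex(table.index.astype(str))


def gate_sst_cells(
    table: pd.DataFrame,
    gate_genes=("Sst", "Gad1", "Gad2", "Lhx6"),
    labels: pd.Series | None = None,
    config: PipelineConfig | None = None,
    lfc_min: float = np.log(1.5),
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Retain only clusters in which every gate gene is enriched.

    Intersection semantics: a cluster must show each gate gene with
    p_adj < 0.01 and lfc > ln(1.5) in a one-vs-rest test to survive.
    Returns the filtered table with a ``cluster`` column.
    """
    cfg = config or PipelineConfig()
    missing = [g for g in gate_genes if g not in table.columns]
    if missing:
        raise KeyError(f"gate genes missing from panel: {missing}")
    if labels is None:
        labels = cluster_spatial(table, cfg)
    labels = labels.reindex(table.index.astype(str))
    cm = table_to_counts(table)
    expressed = cm.total_umi() > 0
    cm = cm.subset_cells(expressed)
    lab = labels.loc[cm.cell_ids].to_numpy()
    norm = lognormalize(cm, S=cfg.scale_factor)

    if pd.unique(lab[~pd.isna(lab)]).size < 2:
        log.warning("only one cluster found; gate cannot be evaluated, returning empty")
        out = table.iloc[0:0].copy()
        out["cluster"] = pd.Series(dtype=object)
        return out

    passing = []
    for c in pd.unique(lab):
        if pd.isna(c) or (lab == c).sum() < 3:
            continue
        res = wilcoxon_one_vs_rest(norm, lab, c, genes=list(gate_genes))
        degs = set(filter_degs(res, lfc_min=lfc_min, alpha=alpha))
        if all(g in degs for g in gate_genes):
            passing.append(c)
    if not passing:
        log.warning("no cluster passed the gate; returning an empty table")
    keep_ids = [cid for cid, l in labels.items() if l in passing]
    out = table.loc[table.index.astype(str).isin(keep_ids)].copy()
    out["cluster"] = labels.loc[out.index.astype(str)].to_numpy()
    return out


def annotate_spatial_clusters(
    gated: pd.DataFrame,
    ref_norm: NormalizedMatrix,
    ref_labels,
    auroc_threshold: float = 0.80,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Label gated spatial clusters by neighbor-voting AUROC against a
    reference; a cluster is annotated only when its best AUROC is strictly
    above the threshold, and one-to-many matches are all recorded."""
    cfg = config or PipelineConfig()
    if "cluster" not in gated.columns:
        raise ValueError("gated table lacks a 'cluster' column; run gate_sst_cells")
    shared = sorted(set(panel_genes(gated)) & set(ref_norm.gene_ids))
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared with the reference (< 10)")
    cm = table_to_counts(gated)
    keep = cm.total_umi() > 0
    cm = cm.subset_cells(keep)
    sp_norm = lognormalize(cm, S=cfg.scale_factor)
    gated_str = gated.set_axis(gated.index.astype(str))
    sp_labels = gated_str["cluster"].loc[cm.cell_ids]

    am = neighbor_voting_auroc(ref_norm, ref_labels, sp_norm, sp_labels.to_numpy(), shared)
    matches = match_clusters(am, threshold=auroc_threshold)
    rows = []
    for c in am.auroc.columns:  # spatial clusters
        col = am.auroc[c].astype(float)
        best = col.idxmax()
        hits = [m for m in matches["matches"] if m["cluster_b"] == c]
        rows.append(
            {
                "cluster": c,
                "annotation": best if col.max() > auroc_threshold else None,
                "best_auroc": float(col.max()),
                "all_matches": [m["cluster_a"] for m in hits],
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def laminar_distribution(gated: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x layer contingency counts and row-normalized fractions."""
    if "layer" not in gated.columns:
        raise ValueError("layer labels required")
    counts = pd.crosstab(gated["cluster"], gated["layer"])
    counts = counts.reindex(columns=sorted(counts.columns), fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return counts, fractions


def superficial_deep_split(
    gated: pd.DataFrame,
    superficial=(1, 2, 3, 4),
    deep=(5, 6),
) -> pd.DataFrame:
    """Per-cluster counts in superficial (layers 1-4) vs deep (5-6) layers."""
    sup = gated["layer"].isin(superficial)
    dp = gated["layer"].isin(deep)
    return pd.DataFrame(
        {
            "superficial": gated.loc[sup].groupby("cluster").size(),
            "deep": gated.loc[dp].groupby("cluster").size(),
        }
    ).fillna(0).astype(int)


def superficial_deep_test(counts_a: dict, counts_b: dict) -> dict:
    """Two-sided Fisher exact comparison of two superficial/deep splits.

    ``counts_a`` and ``counts_b`` each map {"superficial": n, "deep": n}.
    Returns the conditional-MLE odds ratio and the exact two-sided p.
    """
    table = np.array(
        [
            [counts_a["superficial"], counts_a["deep"]],
            [counts_b["superficial"], counts_b["deep"]],
        ],
        dtype=int,
    )
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("a margin of the 2x2 table is zero")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    or_res = odds_ratio(table, kind="conditional")
    return {"odds_ratio": float(or_res.statistic), "p_value": float(p)}
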