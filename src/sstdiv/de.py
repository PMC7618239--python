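"""One-vs-rest differential expression and the DEscore statistic.

The workhorse is a Wilcoxon rank-sum test of one cell group against all
remaining cells, run for every gene at once on ranked columns.  Small groups
(min size <= 8) switch to exact enumeration of the rank-sum distribution,
where the normal approximation is at its worst.  Log fold changes are in
natural-log units so that thresholds like ln(1.5) and ln(2) read directly.

DEscore summarizes how distinct a cluster is: the sum over its DEGs of
-log10 of the Bonferroni-adjusted p-value, each gene capped at 20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix

log = logging.getLogger("sstdiv")

LFC_EPS = 1e-9


@dataclass
class DEResult:
    """Per-gene one-vs-rest test results (natural-log fold changes)."""

    table: pd.DataFrame  # index: gene; columns: log_fold_change, p_raw, p_adj, pct_in, pct_out
    target_label: str = ""
    n_tested: int = 0

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and not np.all(t["p_adj"] >= t["p_raw"] - 1e-15):
            raise ValueError("p_adj < p_raw")


def _rank_matrix(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def _tie_term(x: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per column."""
    out = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        _, counts = np.unique(x[:, j], return_counts=True)
        t = counts[counts > 1].astype(float)
        out[j] = np.sum(t**3 - t)
    return out


def _exact_rank_sum_p(col: np.ndarray, in_mask: np.ndarray) -> float:
    """Exact two-sided p by enumeration of all group assignments.

    Two-sided tail defined symmetrically around the null mean of the
    rank-sum: p = P(|R - mu| >= |r_obs - mu|).
    """
    n = col.size
    n1 = int(in_mask.sum())
    ranks = stats.rankdata(col)
    r_obs = ranks[in_mask].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(r_obs - mu)
    hits = 0
    total = comb(n, n1)
    for subset in combinations(range(n), n1):
        r = ranks[list(subset)].sum()
        if abs(r - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_one_vs_rest(
    norm: NormalizedMatrix,
    labels,
    target_label,
    genes: list[str] | None = None,
    exact_max_group: int = 8,
    exact_max_enum: int = 50_000,
) -> DEResult:
    """Two-sided Wilcoxon rank-sum of ``target_label`` cells vs all the rest.

    Bonferroni multiplicity is the number of genes actually tested: genes
    expressed in at least one cell of the union.  Unexpressed genes get
    p = 1 and lfc = 0.  lfc = ln((mean(expm1(x)) + eps) / (mean_rest + eps)).
    """
    labels = np.asarray(labels)
    if labels.size != norm.n_cells:
        raise ValueError("labels length does not match cells")
    in_mask = labels == target_label
    n1 = int(in_mask.sum())
    n2 = int((~in_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"group {target_label!r} or its complement is empty")

    if genes is not None:
        gidx = norm.gene_index(genes)
        x = norm.values[:, gidx]
        gene_ids = list(genes)
    else:
        x = norm.values
        gene_ids = list(norm.gene_ids)
    x = np.asarray(x, dtype=float)
    n = n1 + n2

    expressed = (x > 0).any(axis=0)
    n_tested = int(expressed.sum())

    p_raw = np.ones(x.shape[1])
    if n_tested:
        xt = x[:, expressed]
        if min(n1, n2) <= exact_max_group and comb(n, n1) <= exact_max_enum:
            p_raw[expressed] = [
                _exact_rank_sum_p(xt[:, j], in_mask) for j in range(xt.shape[1])
            ]
        else:
            ranks = _rank_matrix(xt)
            r1 = ranks[in_mask].sum(axis=0)
            mu = n1 * (n + 1) / 2.0
            tie = _tie_term(xt)
            var = (n1 * n2 / 12.0) * ((n + 1) - tie / (n * (n - 1)))
            sd = np.sqrt(np.maximum(var, 0))
            dev = np.abs(r1 - mu)
            # continuity correction toward the mean
            z = np.where(sd > 0, np.maximum(dev - 0.5, 0) / np.where(sd > 0, sd, 1), 0.0)
            p = 2 * stats.norm.sf(z)
            p_raw[expressed] = np.minimum(p, 1.0)

    p_adj = np.minimum(p_raw * max(n_tested, 1), 1.0)
    p_adj[~expressed] = 1.0

    expr = np.expm1(x)
    mean_in = expr[in_mask].mean(axis=0)
    mean_out = expr[~in_mask].mean(axis=0)
    lfc = np.log((mean_in + LFC_EPS) / (mean_out + LFC_EPS))
    pct_in = (x[in_mask] > 0).mean(axis=0)
    pct_out = (x[~in_mask] > 0).mean(axis=0)

    table = pd.DataFrame(
        {
            "log_fold_change": lfc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "pct_in": pct_in,
            "pct_out": pct_out,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return DEResult(table, target_label=str(target_label), n_tested=n_tested)


def de_score(p_adj_list, cap: float = 20.0) -> float:
    """Sum over genes of min(-log10(p_adj), cap); p_adj = 0 contributes cap."""
    p = np.asarray(list(p_adj_list), dtype=float)
    if p.size == 0:
        return 0.0
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("adjusted p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return float(np.sum(np.minimum(neglog, cap)))


def filter_degs(res: DEResult, lfc_min: float, alpha: float = 0.01) -> list[str]:
    """Genes with lfc strictly above ``lfc_min`` and p_adj strictly below alpha,
    ordered by descending log fold change (gene id breaks ties)."""
    t = res.table
    keep = t[(t["log_fold_change"] > lfc_min) & (t["p_adj"] < alpha)]
    order = np.lexsort((keep.index.to_numpy(), -keep["log_fold_change"].to_numpy()))
    return keep.index.to_numpy()[order].tolist()


@dataclass
class MarkerSet:
    label: str
    genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate marker genes")


def derive_marker_sets(
    norm: NormalizedMatrix,
    labels,
    top_n: int = 10,
    lfc_min: float = np.log(1.5),
    alpha: float = 0.01,
    min_cells: int = 3,
) -> list[MarkerSet]:
    """Top-``top_n`` DEGs by log fold change for every label (one-vs-rest)."""
    labels = np.asarray(labels)
    uniq = sorted(pd.unique(labels).tolist(), key=str)
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels")
    out = []
    for lab in uniq:
        if (labels == lab).sum() < min_cells:
            log.warning("label %s has < %d cells; skipped", lab, min_cells)
            continue
        res = wilcoxon_one_vs_rest(norm, labels, lab)
        degs = filter_degs(res, lfc_min=lfc_min, alpha=alpha)
        out.append(MarkerSet(str(lab), degs[:top_n]))
    return out


def write_de_table(res: DEResult, path) -> None:
    cols = ["log_fold_change", "p_raw", "p_adj", "pct_in", "pct_out"]
    res.table[cols].to_csv(path, sep="\t", index_label="gene")
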