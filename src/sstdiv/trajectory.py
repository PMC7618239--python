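"""Gene modules, diffusion pseudotime, branch assignment and Moran's I.

Module construction starts from a counts-per-million matrix: genes present
in fewer than 10 cells and cells with fewer than 700 detected genes are
discounted; a gene enters the module computation only if its Spearman
correlation reaches 0.3 with at least 3 other genes.  Genes are then
clustered hierarchically on 1 - Spearman with silhouette-selected k, and
modules failing validity (a member gene detected in < 5% of cells, or mean
within-module correlation below the threshold) are discarded and the loop
repeated until every surviving module is valid.

Pseudotime: a diffusion map with locally adaptive Gaussian kernel and
density-normalized transition matrix; diffusion pseudotime (DPT) is the
diffusion distance from a root cell computed from the accumulated transition
operator through its spectrum, d(x, y)^2 = sum_i (l_i/(1-l_i))^2
(psi_i(x) - psi_i(y))^2 over the non-stationary eigenpairs.  Branches are
tips found by farthest-point search in DPT distance, each cell joining its
nearest tip, with a trunk zone near the root left unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .cluster import cluster_distance_once
from .containers import CountMatrix

log = logging.getLogger("sstdiv")


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts-per-million normalization (cells x genes DataFrame)."""
    total = counts.total_umi().astype(float)
    if np.any(total <= 0):
        raise ValueError("cells with zero totals; filter first")
    vals = counts.dense() / total[:, None] * 1e6
    return pd.DataFrame(vals, index=counts.cell_ids, columns=counts.gene_ids)


def prefilter_module_matrix(
    counts: CountMatrix, min_cells_per_gene: int = 10, min_genes_per_cell: int = 700
) -> pd.DataFrame:
    """CPM matrix restricted to genes in >= 10 cells and cells with >= 700 genes."""
    keep_cells = counts.genes_per_cell() >= min_genes_per_cell
    cm = counts.subset_cells(keep_cells)
    keep_genes = cm.cells_per_gene() >= min_cells_per_gene
    cm = cm.subset_genes(keep_genes)
    return cpm(cm)


def _spearman_gene_corr(values: pd.DataFrame) -> np.ndarray:
    ranks = stats.rankdata(values.to_numpy(dtype=float), axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    denom = np.sqrt((ranks**2).sum(axis=0))
    denom[denom == 0] = 1.0
    ranks = ranks / denom[None, :]
    return ranks.T @ ranks


def correlation_filter_genes(
    values: pd.DataFrame,
    rho_min: float = 0.3,
    min_partners: int = 3,
    absolute: bool = False,
) -> list[str]:
    """Genes whose Spearman correlation reaches ``rho_min`` with at least
    ``min_partners`` other genes (signed by default)."""
    corr = _spearman_gene_corr(values)
    if absolute:
        corr = np.abs(corr)
    np.fill_diagonal(corr, -np.inf)
    n_partners = (corr >= rho_min).sum(axis=1)
    keep = n_partners >= min_partners
    return [g for g, k in zip(values.columns, keep) if k]


@dataclass
class GeneModuleSet:
    modules: list = field(default_factory=list)  # {module_id, genes, mean_spearman}
    discarded: list = field(default_factory=list)  # {gene, reason}

    def genes(self) -> list[str]:
        return [g for m in self.modules for g in m["genes"]]

    def to_json_dict(self) -> dict:
        return {"modules": self.modules, "discarded": self.discarded}


def compute_modules(
    values: pd.DataFrame,
    genes: list[str] | None = None,
    rho_min: float = 0.3,
    min_detect_frac: float = 0.05,
    k_min: int = 2,
    k_max: int = 20,
    max_rounds: int = 20,
    min_split_silhouette: float = 0.25,
) -> GeneModuleSet:
    """Iterative gene-module clustering with validity filtering.

    Deterministic and invariant to gene input order (genes are sorted
    internally before clustering).  When no dendrogram cut reaches
    ``min_split_silhouette`` the remaining genes form a single candidate
    module (a coherent block should not be force-split).
    """
    if genes is None:
        genes = list(values.columns)
    genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    out = GeneModuleSet()
    current = genes
    detect_frac = (values > 0).mean(axis=0)

    for _ in range(max_rounds):
        if len(current) < 2:
            for g in current:
                out.discarded.append({"gene": g, "reason": "too few genes left"})
            current = []
            break
        sub = values[current]
        corr = _spearman_gene_corr(sub)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        labels, k, sils = cluster_distance_once(dist, k_min=k_min, k_max=k_max)
        if sils and max(sils.values()) < min_split_silhouette:
            labels = np.zeros(len(current), dtype=int)
        modules_ok, dropped = [], []
        for c in np.unique(labels):
            mod_genes = [g for g, l in zip(current, labels) if l == c]
            m = np.isin(np.array(current), mod_genes)
            block = corr[np.ix_(m, m)]
            if len(mod_genes) > 1:
                mean_rho = float(block[np.triu_indices(len(mod_genes), 1)].mean())
            else:
                mean_rho = 1.0
            low_detect = [g for g in mod_genes if detect_frac[g] < min_detect_frac]
            if low_detect:
                dropped.append((mod_genes, f"{len(low_detect)} genes below detection fraction"))
            elif mean_rho < rho_min:
                dropped.append((mod_genes, f"mean within-module correlation {mean_rho:.3f} < {rho_min}"))
            else:
                modules_ok.append({"genes": mod_genes, "mean_spearman": mean_rho})
        if not dropped:
            out.modules = [
                {"module_id": f"M{j}", **m} for j, m in enumerate(modules_ok)
            ]
            return out
        for mod_genes, reason in dropped:
            for g in mod_genes:
                out.discarded.append({"gene": g, "reason": reason})
        current = sorted(set(current) - {g for mg, _ in dropped for g in mg})
    if current:
        # loop guard: treat what survived as final
        out.modules = [{"module_id": "M0", "genes": current, "mean_spearman": float("nan")}]
    return out


def select_developmental_module(
    values: pd.DataFrame, modules: GeneModuleSet, stages, alpha: float = 0.01
) -> dict:
    """The module whose per-cell score varies most across stages
    (largest Kruskal-Wallis statistic)."""
    stages = np.asarray(stages)
    if len(np.unique(stages)) < 2:
        raise ValueError("need >= 2 stages")
    if not modules.modules:
        raise ValueError("no modules")
    best = None
    for m in modules.modules:
        x = values[m["genes"]].to_numpy(dtype=float)
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd[sd == 0] = 1.0
        score = ((x - mu) / sd).mean(axis=1)
        groups = [score[stages == s] for s in np.unique(stages)]
        h, p = stats.kruskal(*groups)
        rec = {"module_id": m["module_id"], "genes": m["genes"], "H": float(h), "p": float(p)}
        if best is None or rec["H"] > best["H"]:
            best = rec
    best["significant"] = best["p"] < alpha
    if not best["significant"]:
        log.warning("no module varies significantly across stages (best p=%.3g)", best["p"])
    return best


@dataclass
class DiffusionMap:
    components: np.ndarray  # cells x n_components (stationary component dropped)
    eigenvalues: np.ndarray
    transition: np.ndarray  # row-stochastic
    cell_ids: list


def diffusion_map(
    expr: np.ndarray,
    cell_ids: list[str] | None = None,
    n_components: int = 15,
    k_neighbors: int = 15,
) -> DiffusionMap:
    """Diffusion map with locally adaptive Gaussian kernel.

    Bandwidth sigma_i is the distance to the k-th neighbor; the kernel is
    restricted to the symmetrized kNN graph and density-normalized before
    the transition matrix is formed.  Components carry a deterministic sign
    (largest-magnitude entry positive).
    """
    x = np.asarray(expr, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError("need >= 10 cells")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist_knn, idx_knn = nn.kneighbors(x)
    sigma = np.maximum(dist_knn[:, -1], 1e-12)

    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    cols = idx_knn[:, 1:].ravel()
    mask[rows, cols] = True
    mask |= mask.T

    ncomp, comp_labels = connected_components(mask, directed=False)
    if ncomp > 1:
        sizes = np.bincount(comp_labels)
        raise ValueError(
            f"kNN kernel graph is disconnected: {ncomp} components with sizes {sizes.tolist()}"
        )

    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    s2 = sigma[:, None] ** 2 + sigma[None, :] ** 2
    w = np.sqrt(2 * sigma[:, None] * sigma[None, :] / s2) * np.exp(-d2 / s2)
    w[~mask] = 0.0
    np.fill_diagonal(w, 0.0)

    q = w.sum(axis=1)
    q[q == 0] = 1.0
    w = w / (q[:, None] * q[None, :])  # density normalization (alpha = 1)
    d = w.sum(axis=1)
    d[d == 0] = 1.0
    transition = w / d[:, None]

    d_isqrt = 1.0 / np.sqrt(d)
    sym = w * d_isqrt[:, None] * d_isqrt[None, :]
    sym = (sym + sym.T) / 2.0
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    m = min(n_components + 1, n)
    evals = evals[order][:m]
    psi = evecs[:, order][:, :m] * d_isqrt[:, None]
    for i in range(psi.shape[1]):
        j = np.argmax(np.abs(psi[:, i]))
        if psi[j, i] < 0:
            psi[:, i] *= -1
    # drop the trivial stationary pair (eigenvalue 1, constant psi)
    return DiffusionMap(
        components=psi[:, 1:], eigenvalues=evals[1:], transition=transition,
        cell_ids=list(cell_ids),
    )


def _dpt_coords(dm: DiffusionMap) -> np.ndarray:
    lam = np.clip(dm.eigenvalues, None, 1 - 1e-10)
    weights = lam / (1 - lam)
    return dm.components * weights[None, :]


def diffusion_pseudotime(dm: DiffusionMap, root: str) -> pd.Series:
    """DPT: diffusion distance from the root cell via the accumulated operator."""
    if root not in dm.cell_ids:
        raise KeyError(f"root cell {root!r} not in dataset")
    coords = _dpt_coords(dm)
    r = dm.cell_ids.index(root)
    d = np.sqrt(((coords - coords[r]) ** 2).sum(axis=1))
    return pd.Series(d, index=dm.cell_ids, name="pseudotime")


def pick_root(dm: DiffusionMap, stages, earliest_stage) -> str:
    """Root = the earliest-stage cell at the extreme of DC1, oriented so the
    earliest stage sits low on DC1."""
    stages = np.asarray(stages)
    dc1 = dm.components[:, 0]
    early = stages == earliest_stage
    if not early.any():
        raise ValueError(f"no cells at stage {earliest_stage!r}")
    if (~early).any() and dc1[early].mean() > dc1[~early].mean():
        dc1 = -dc1
    i = int(np.flatnonzero(early)[np.argmin(dc1[early])])
    return dm.cell_ids[i]


def assign_branches(
    dm: DiffusionMap,
    pseudotime: pd.Series,
    n_branches: int = 3,
    trunk_quantile: float = 0.05,
) -> pd.Series:
    """Assign cells to the branch of their nearest tip in DPT distance.

    Tips are found by farthest-point search seeded at the root; cells below
    the ``trunk_quantile`` of pseudotime stay unassigned ("trunk").
    """
    if n_branches < 2:
        raise ValueError("need >= 2 branches")
    coords = _dpt_coords(dm)
    pt = pseudotime.loc[dm.cell_ids].to_numpy()
    root_idx = int(np.argmin(pt))

    def dist_from(i):
        return np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))

    tips = [int(np.argmax(dist_from(root_idx)))]
    while len(tips) < n_branches:
        min_d = np.min([dist_from(t) for t in tips], axis=0)
        cand = int(np.argmax(min_d))
        if min_d[cand] <= 1e-12 or cand in tips:
            raise ValueError(
                f"found only {len(tips)} distinct tips for {n_branches} branches"
            )
        tips.append(cand)

    tip_d = np.stack([dist_from(t) for t in tips], axis=1)
    branch = np.array([f"branch{j}" for j in np.argmin(tip_d, axis=1)], dtype=object)
    trunk = pt <= np.quantile(pt, trunk_quantile)
    branch[trunk] = "trunk"
    return pd.Series(branch, index=dm.cell_ids, name="branch")


def morans_i(
    values: np.ndarray,
    gene_ids: list[str],
    embedding: np.ndarray,
    k_neighbors: int = 15,
) -> pd.DataFrame:
    """Moran's I per gene on a kNN graph over the embedding.

    One-sided (positive autocorrelation) analytic z-test under normality,
    Bonferroni-adjusted over the non-constant genes; constant genes get NA
    and are excluded from the multiplicity correction.
    """
    x = np.asarray(values, dtype=float)
    emb = np.atleast_2d(np.asarray(embedding, dtype=float))
    if emb.shape[0] != x.shape[0]:
        emb = emb.T
    n = x.shape[0]
    if n < 10:
        raise ValueError("need >= 10 cells")
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    w = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    w[rows, idx[:, 1:].ravel()] = 1.0
    w = np.maximum(w, w.T)  # symmetric binary weights

    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    e_i = -1.0 / (n - 1)
    var_i = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - e_i**2
    sd_i = np.sqrt(max(var_i, 1e-300))

    z = x - x.mean(axis=0)
    denom = (z**2).sum(axis=0)
    num = (z * (w @ z)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        i_stat = np.where(denom > 0, (n / s0) * num / denom, np.nan)
    p_raw = np.where(np.isnan(i_stat), np.nan, stats.norm.sf((i_stat - e_i) / sd_i))
    n_tested = int(np.isfinite(i_stat).sum())
    p_adj = np.minimum(p_raw * max(n_tested, 1), 1.0)
    return pd.DataFrame(
        {"I": i_stat, "p_raw": p_raw, "p_adj": p_adj},
        index=pd.Index(gene_ids, name="gene"),
    )
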