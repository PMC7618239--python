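"""Quality control, normalization, feature selection, scaling and PCA.

Filter order is fixed: genes detected in < 10 cells are dropped first, then
cells are kept only if (i) unique gene count > 700, (ii) mitochondrial
content < 10%, (iii) fraction of confidently aligned reads > mean - 2 sd and
(iv) ln(total UMI) > mean - 2 sd, with the adaptive thresholds computed on
the post-gene-filter population of the dataset at hand.  Finally the
mitochondrial / ribosomal / Y-chromosome gene classes are removed.

Batch correction here is per-batch mean centering of the scaled matrix; the
centered matrix feeds clustering, classification and dimensionality
reduction only, while differential expression always reads the unadjusted
log-normalized matrix.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CellMetadata, CountMatrix, NormalizedMatrix, QCReport

log = logging.getLogger("sstdiv")


def qc_filter(
    counts: CountMatrix,
    meta: CellMetadata,
    min_cells_per_gene: int = 10,
    min_genes_per_cell: int = 700,
    max_pct_mito: float = 0.10,
    sd_multiplier: float = 2.0,
) -> tuple[CountMatrix, CellMetadata, QCReport]:
    """Apply the QC cascade and report what each step removed."""
    report = QCReport(n_cells_in=counts.n_cells, n_genes_in=counts.n_genes)
    table = meta.aligned_to(counts)

    detected = counts.cells_per_gene()
    gene_keep = detected >= min_cells_per_gene
    report.genes_removed_low_detection = int((~gene_keep).sum())
    cm = counts.subset_genes(gene_keep)
    if cm.n_genes == 0:
        raise ValueError("gene detection filter removed every gene")

    n_genes = cm.genes_per_cell()
    total = cm.total_umi()
    pct_mito = table["pct_mito"].to_numpy(dtype=float)
    pct_aligned = table["pct_aligned"].to_numpy(dtype=float)

    keep = np.ones(cm.n_cells, dtype=bool)

    ok = n_genes > min_genes_per_cell
    report.cells_removed_low_genes = int((keep & ~ok).sum())
    keep &= ok

    ok = pct_mito < max_pct_mito
    report.cells_removed_high_mito = int((keep & ~ok).sum())
    keep &= ok

    # "above mean - 2 sd": cells exactly at the threshold (e.g. a degenerate
    # zero-variance distribution) are not below it and are kept
    thr_aligned = pct_aligned.mean() - sd_multiplier * pct_aligned.std()
    report.threshold_aligned = float(thr_aligned)
    ok = (pct_aligned > thr_aligned) | np.isclose(pct_aligned, thr_aligned)
    report.cells_removed_low_aligned = int((keep & ~ok).sum())
    keep &= ok

    with np.errstate(divide="ignore"):
        log_umi = np.log(np.maximum(total, 1e-300))
    thr_umi = log_umi.mean() - sd_multiplier * log_umi.std()
    report.threshold_log_umi = float(thr_umi)
    ok = (log_umi > thr_umi) | np.isclose(log_umi, thr_umi)
    report.cells_removed_low_umi = int((keep & ~ok).sum())
    keep &= ok

    if not keep.any():
        first = next(
            name
            for name, n in (
                ("unique gene count", report.cells_removed_low_genes),
                ("mitochondrial content", report.cells_removed_high_mito),
                ("aligned-read fraction", report.cells_removed_low_aligned),
                ("ln(total UMI)", report.cells_removed_low_umi),
            )
            if n > 0
        )
        raise ValueError(f"cell QC removed every cell (first offending filter: {first})")

    cm = cm.subset_cells(keep)

    flags = cm.gene_flags
    flagged = (
        flags["mitochondrial"] | flags["ribosomal"] | flags["y_chromosome"]
    ).to_numpy()
    report.genes_removed_flagged = int(flagged.sum())
    cm = cm.subset_genes(~flagged)
    if cm.n_genes == 0:
        raise ValueError("flagged-gene removal left no genes")

    meta_out = meta.subset(cm.cell_ids)
    # refresh derived covariates after gene filtering
    meta_out.table = meta_out.table.assign(
        total_umi=cm.total_umi().astype(int), n_genes=cm.genes_per_cell().astype(int)
    )
    report.n_cells_out = cm.n_cells
    report.n_genes_out = cm.n_genes
    return cm, meta_out, report


def lognormalize(counts: CountMatrix, S: float = 1000.0) -> NormalizedMatrix:
    """x_norm = ln(1 + S * x / x_tot), with x_tot the cell's total count."""
    total = counts.total_umi().astype(float)
    if np.any(total <= 0):
        raise ValueError("cells with zero total count present; run QC first")
    x = counts.dense()
    vals = np.log1p(S * x / total[:, None])
    return NormalizedMatrix(vals, list(counts.cell_ids), list(counts.gene_ids), S)


def select_variable_features(
    counts: CountMatrix, n: int = 2000, lowess_frac: float = 0.3
) -> pd.DataFrame:
    """Rank genes by variance standardized against a smoothed mean-variance trend.

    Computed on raw counts: a lowess fit of log10(variance) on log10(mean)
    gives each gene an expected standard deviation; counts standardized with
    that sd are clipped at sqrt(n_cells) and their variance is the ranking
    statistic.  Deterministic ordering, gene id breaks ties.
    """
    x = counts.dense()
    n_cells = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if n_cells > 1 else np.zeros_like(mean)

    std_var = np.zeros_like(mean)
    positive = (mean > 0) & (var > 0)
    if positive.sum() >= 3:
        lm, lv = np.log10(mean[positive]), np.log10(var[positive])
        fitted = lowess(lv, lm, frac=lowess_frac, return_sorted=False)
        sd_exp = np.sqrt(10.0**fitted)
        clip = np.sqrt(n_cells)
        z = (x[:, positive] - mean[positive]) / sd_exp
        np.clip(z, -clip, clip, out=z)
        std_var[positive] = z.var(axis=0, ddof=1)
    elif positive.any():
        std_var[positive] = var[positive] / np.maximum(mean[positive], 1e-12)

    df = pd.DataFrame(
        {"gene": counts.gene_ids, "mean": mean, "variance": var, "std_variance": std_var}
    )
    order = np.lexsort((df["gene"].to_numpy(), -df["std_variance"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    if n < len(df):
        df = df.assign(selected=np.arange(len(df)) < n)
    else:
        if n > len(df):
            warnings.warn(
                f"requested {n} variable features but only {len(df)} genes available"
            )
        df = df.assign(selected=True)
    return df


def scale_center(
    norm: NormalizedMatrix, genes: list[str], clip: float = 10.0
) -> np.ndarray:
    """Per-gene z-score of the selected genes, clipped at ``clip``.

    Constant genes map to all-zeros.  Returns a dense cells x len(genes)
    array aligned with ``genes``.
    """
    idx = norm.gene_index(genes)
    x = np.asarray(norm.values[:, idx], dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd_safe
    z[:, sd == 0] = 0.0
    np.clip(z, -clip, clip, out=z)
    return z


def batch_center(scaled: np.ndarray, batches) -> np.ndarray:
    """Remove the per-gene per-batch mean; batches with < 2 cells are left as-is."""
    batches = np.asarray(batches)
    if batches.size != scaled.shape[0]:
        raise ValueError("batch labels length mismatch")
    out = scaled.copy()
    for b in pd.unique(batches):
        mask = batches == b
        if mask.sum() < 2:
            log.warning("batch %s has < 2 cells; left unadjusted", b)
            continue
        out[mask] -= out[mask].mean(axis=0)
    return out


def pca(scaled: np.ndarray, n_components: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """PCA with a deterministic sign convention.

    The sign of each component is fixed so its largest-magnitude gene loading
    is positive.  Returns (embedding, explained_variance_ratio).
    """
    n_components = min(n_components, min(scaled.shape))
    model = PCA(n_components=n_components, svd_solver="full")
    emb = model.fit_transform(scaled)
    for i, comp in enumerate(model.components_):
        j = np.argmax(np.abs(comp))
        if comp[j] < 0:
            emb[:, i] *= -1
            model.components_[i] *= -1
    return emb, model.explained_variance_ratio_
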