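"""Shared in-memory data model for the pipeline.

All matrices are cells-in-rows, genes-in-columns throughout the package;
this single convention avoids silent transposes between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

GENE_FLAG_NAMES = ("mitochondrial", "ribosomal", "y_chromosome", "stress_marker")


@dataclass
class CountMatrix:
    """Sparse cells x genes matrix of non-negative integer UMI counts.

    Parameters
    ----------
    counts
        Sparse (CSR) matrix, cells in rows, genes in columns.
    cell_ids, gene_ids
        Unique identifiers for rows and columns.
    gene_flags
        Boolean DataFrame indexed by gene with one column per flag in
        :data:`GENE_FLAG_NAMES` (mitochondrial / ribosomal / Y-chromosome /
        stress-marker genes, the classes the QC stage removes or scores).
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    gene_flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"counts has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"counts has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer counts")
        if self.gene_flags is None:
            self.gene_flags = pd.DataFrame(
                False, index=self.gene_ids, columns=list(GENE_FLAG_NAMES)
            )
        else:
            self.gene_flags = self.gene_flags.reindex(
                index=self.gene_ids, columns=list(GENE_FLAG_NAMES), fill_value=False
            ).astype(bool)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_umi(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_cells)
        return CountMatrix(
            self.counts[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            self.gene_flags,
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_genes)
        gids = [self.gene_ids[i] for i in idx]
        return CountMatrix(
            self.counts[:, idx], list(self.cell_ids), gids, self.gene_flags.loc[gids]
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)


def _as_index(mask_or_idx, n: int) -> np.ndarray:
    arr = np.asarray(mask_or_idx)
    if arr.dtype == bool:
        if arr.size != n:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    return arr.astype(int)


@dataclass
class CellMetadata:
    """Per-cell QC covariates, batch/stage labels and optional ground truth.

    ``table`` is indexed by cell id with columns
    total_umi, n_genes, pct_aligned, pct_mito, stage and (for synthetic data)
    truth_label plus any extra truth columns. Fractions live in [0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate cell ids in metadata")
        for col in ("pct_aligned", "pct_mito"):
            if col in self.table:
                vals = self.table[col].to_numpy(dtype=float)
                if np.any((vals < 0) | (vals > 1)):
                    raise ValueError(f"{col} outside [0, 1]")

    def aligned_to(self, cm: CountMatrix) -> pd.DataFrame:
        missing = set(cm.cell_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"metadata missing {len(missing)} cells")
        return self.table.loc[cm.cell_ids]

    def subset(self, cell_ids: list[str]) -> "CellMetadata":
        return CellMetadata(self.table.loc[cell_ids].copy())


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: x_norm = ln(1 + S * x / x_tot).

    Entries are >= 0 and zeros are preserved.  The batch-centered matrix used
    for clustering/classification is a different object (plain ndarray from
    :func:`sstdiv.qc.batch_center`); differential expression always consumes
    this unadjusted matrix.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    scale_factor: float = 1000.0
    log_base: str = "e"

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = _as_index(mask_or_idx, self.n_cells)
        return NormalizedMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            self.scale_factor,
            self.log_base,
        )


@dataclass
class QCReport:
    """Per-filter removal counts and the adaptive thresholds actually applied."""

    n_cells_in: int = 0
    n_genes_in: int = 0
    genes_removed_low_detection: int = 0
    cells_removed_low_genes: int = 0
    cells_removed_high_mito: int = 0
    cells_removed_low_aligned: int = 0
    cells_removed_low_umi: int = 0
    genes_removed_flagged: int = 0
    n_cells_out: int = 0
    n_genes_out: int = 0
    threshold_aligned: float = float("nan")
    threshold_log_umi: float = float("nan")
    per_step: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            k: (v if not isinstance(v, float) or np.isfinite(v) else None)
            for k, v in self.__dict__.items()
        }
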