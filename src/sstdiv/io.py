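"""Readers and writers for the standard interchange formats.

Counts travel as the 10x triplet (MatrixMarket ``matrix.mtx`` plus
``features.tsv`` / ``barcodes.tsv``); note the on-disk matrix is genes x cells
as Cell Ranger writes it, while in memory everything is cells x genes.
Metadata, assignments and DE tables are plain CSV/TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import GENE_FLAG_NAMES, CellMetadata, CountMatrix

log = logging.getLogger("sstdiv")


def _flag_genes(
    gene_ids: list[str],
    mito_prefixes=("mt-",),
    ribo_prefixes=("Rps", "Rpl"),
    y_genes=(),
    stress_genes=(),
) -> pd.DataFrame:
    """Assign gene class flags from configurable prefix rules and explicit lists."""
    y_set, stress_set = set(y_genes), set(stress_genes)
    flags = pd.DataFrame(False, index=gene_ids, columns=list(GENE_FLAG_NAMES))
    for g in gene_ids:
        if any(g.startswith(p) for p in mito_prefixes):
            flags.at[g, "mitochondrial"] = True
        if any(g.startswith(p) for p in ribo_prefixes):
            flags.at[g, "ribosomal"] = True
    if y_set:
        flags.loc[flags.index.isin(y_set), "y_chromosome"] = True
    if stress_set:
        flags.loc[flags.index.isin(stress_set), "stress_marker"] = True
    return flags


def read_10x_triplet(
    dir_path: str | Path,
    mito_prefixes=("mt-",),
    ribo_prefixes=("Rps", "Rpl"),
    y_genes=(),
    stress_genes=(),
) -> CountMatrix:
    """Read a 10x triplet directory into a :class:`CountMatrix`.

    Expects ``matrix.mtx`` (genes x cells), ``features.tsv`` and
    ``barcodes.tsv``.  Raises ``FileNotFoundError`` for a missing member and
    ``ValueError`` on dimension mismatches or non-integer values.
    """
    dir_path = Path(dir_path)
    paths = {name: dir_path / f"{name}" for name in ("matrix.mtx", "features.tsv", "barcodes.tsv")}
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"10x triplet member missing: {p}")
    mat = scipy.io.mmread(paths["matrix.mtx"])  # genes x cells on disk
    features = pd.read_csv(paths["features.tsv"], sep="\t", header=None)
    barcodes = pd.read_csv(paths["barcodes.tsv"], sep="\t", header=None)
    gene_ids = features.iloc[:, 0].astype(str).tolist()
    cell_ids = barcodes.iloc[:, 0].astype(str).tolist()
    if mat.shape[0] != len(gene_ids):
        raise ValueError(
            f"matrix.mtx declares {mat.shape[0]} genes but features.tsv has {len(gene_ids)} rows"
        )
    if mat.shape[1] != len(cell_ids):
        raise ValueError(
            f"matrix.mtx declares {mat.shape[1]} cells but barcodes.tsv has {len(cell_ids)} rows"
        )
    counts = sp.csr_matrix(mat.T)
    if counts.data.size and not np.allclose(counts.data, np.round(counts.data)):
        raise ValueError("matrix.mtx contains non-integer values")
    flags = _flag_genes(gene_ids, mito_prefixes, ribo_prefixes, y_genes, stress_genes)
    return CountMatrix(counts, cell_ids, gene_ids, flags)


def write_10x_triplet(cm: CountMatrix, dir_path: str | Path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(cm.counts.T), field="integer")
    pd.Series(cm.gene_ids).to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(dir_path / "barcodes.tsv", sep="\t", header=False, index=False)


def write_assignments(labels: dict | pd.Series, path: str | Path, cell_ids: list[str] | None = None) -> None:
    """Write per-cell labels as a two-column CSV (cell_id, label).

    If ``cell_ids`` is given, every one of those cells must be labeled.
    """
    ser = pd.Series(labels)
    if cell_ids is not None:
        missing = [c for c in cell_ids if c not in ser.index]
        if missing:
            raise ValueError(f"labels missing for {len(missing)} cells, e.g. {missing[:3]}")
        ser = ser.loc[cell_ids]
    df = pd.DataFrame({"cell_id": ser.index.astype(str), "label": ser.to_numpy()})
    df.to_csv(path, index=False)


def read_assignments(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype={"cell_id": str, "label": str})
    return pd.Series(df["label"].to_numpy(), index=df["cell_id"].to_numpy(), name="label")


def write_metadata(meta: CellMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index_label="cell_id")


def read_metadata(path: str | Path) -> CellMetadata:
    return CellMetadata(pd.read_csv(path, index_col="cell_id"))
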