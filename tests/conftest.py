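import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sstdiv.containers import CellMetadata, CountMatrix
from sstdiv.qc import lognormalize
from sstdiv.simulate import SimSpec, flat_spec, simulate_counts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def flat3():
    """Three well-separated planted clusters, 100 cells each (shared)."""
    cm, meta = simulate_counts(flat_spec(n_cells=100, seed=11))
    norm = lognormalize(cm)
    return cm, meta, norm


@pytest.fixture(scope="session")
def hier_dataset():
    """The standard two-level hierarchy simulation (3 types x 2 subtypes)."""
    cm, meta = simulate_counts(SimSpec(seed=7))
    norm = lognormalize(cm)
    return cm, meta, norm


def toy_counts(matrix, cell_ids=None, gene_ids=None, **flags):
    matrix = np.asarray(matrix)
    cells = cell_ids or [f"c{i}" for i in range(matrix.shape[0])]
    genes = gene_ids or [f"g{j}" for j in range(matrix.shape[1])]
    gene_flags = None
    if flags:
        gene_flags = pd.DataFrame(False, index=genes, columns=[
            "mitochondrial", "ribosomal", "y_chromosome", "stress_marker"])
        for col, members in flags.items():
            gene_flags.loc[list(members), col] = True
    return CountMatrix(sp.csr_matrix(matrix), cells, genes, gene_flags)


def toy_metadata(cm, pct_aligned=0.9, pct_mito=0.01, stage="P5", **overrides):
    n = cm.n_cells
    tbl = pd.DataFrame(
        {
            "total_umi": cm.total_umi().astype(int),
            "n_genes": cm.genes_per_cell().astype(int),
            "pct_aligned": np.full(n, pct_aligned, dtype=float),
            "pct_mito": np.full(n, pct_mito, dtype=float),
            "stage": [stage] * n,
        },
        index=pd.Index(cm.cell_ids, name="cell_id"),
    )
    for k, v in overrides.items():
        tbl[k] = v
    return CellMetadata(tbl)
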