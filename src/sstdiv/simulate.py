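"""Synthetic scRNA-seq, trajectory and spatial data with planted structure.

The generator emulates the statistical structure the analysis assumes:

* negative-binomial counts (gene-level dispersion, log-normal library sizes)
  with a planted two-level cluster hierarchy — large marker effects between
  types, smaller ones between nested subtypes;
* a contaminating "stressed" population with up-regulated stress markers,
  shrunken libraries and QC covariates drawn to preferentially violate the
  QC criteria;
* a branching maturation trajectory: a shared maturation program plus
  branch-specific programs whose means change monotonically in latent time;
* spatial cells with layer labels and cluster-dependent laminar placement,
  including Sst/Gad1/Gad2/Lhx6-analog gating genes expressed only in the
  designated SST+ clusters.

Counts are drawn per gene per cell from NB(mean = baseline * exp(lfc) *
library factor, dispersion theta); var = mu + mu^2/theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellMetadata, CountMatrix
from .io import _flag_genes


@dataclass
class TrajectorySpec:
    n_cells: int = 500
    n_branches: int = 3
    genes_per_branch: int = 40
    n_shared_genes: int = 40
    n_noise_genes: int = 1500
    effect: float = 3.0  # natural-log change of the mean across t in [0, 1]
    baseline_mean: float = 3.0
    dispersion: float = 8.0
    library_sigma: float = 0.2


@dataclass
class SpatialCluster:
    name: str
    n_cells: int
    layer_probs: dict  # layer (1..6) -> probability, sums to 1
    is_sst: bool = True


@dataclass
class SpatialSpec:
    clusters: list = field(default_factory=list)
    n_background: int = 400
    panel_size: int = 94
    n_markers_per_cluster: int = 8
    gate_genes: tuple = ("Sst", "Gad1", "Gad2", "Lhx6")
    gate_mean: float = 8.0
    marker_mean: float = 6.0
    baseline_mean: float = 0.5
    background_gate_mean: float = 0.0
    dispersion: float = 1.5
    # per-cell detection efficiency (segmentation / probe capture variation)
    efficiency_sigma: float = 0.4


@dataclass
class SimSpec:
    """Parameters of the planted-hierarchy count simulator.

    ``hierarchy`` maps each type to its subtypes; leaf labels are
    "type.subtype".  Marker log-fold changes are natural-log units.
    """

    hierarchy: dict = field(
        default_factory=lambda: {
            "A": ["1", "2"],
            "B": ["1", "2"],
            "C": ["1", "2"],
        }
    )
    n_cells_per_cluster: int = 200
    n_genes: int = 2000
    n_markers_type: int = 20
    n_markers_subtype: int = 40
    lfc_type: float = math.log(4.0)
    lfc_subtype: float = math.log(2.5)
    baseline_shape: float = 0.6
    baseline_scale: float = 2.0
    marker_baseline_mean: float = 3.0
    dispersion: float = 4.0
    library_sigma: float = 0.35
    stressed_fraction: float = 0.0
    n_stress_markers: int = 20
    stress_lfc: float = math.log(6.0)
    stress_library_factor: float = 0.35
    stages: tuple = ("E16.5", "P1", "P5")
    batch_shift: float = 0.0
    batch_gene_fraction: float = 0.1
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    spatial: SpatialSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        leaves = self.leaf_labels()
        if len(set(leaves)) != len(leaves):
            raise ValueError("hierarchy labels not unique")
        for frac in (self.stressed_fraction, self.batch_gene_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.lfc_type < 0 or self.lfc_subtype < 0:
            raise ValueError("marker lfc must be >= 0")

    def leaf_labels(self) -> list[str]:
        return [f"{t}.{s}" for t, subs in self.hierarchy.items() for s in subs]

    def n_marker_genes(self) -> int:
        n_types = len(self.hierarchy)
        n_leaves = len(self.leaf_labels())
        return (
            n_types * self.n_markers_type
            + n_leaves * self.n_markers_subtype
            + (self.n_stress_markers if self.stressed_fraction > 0 else 0)
        )


def default_spatial_spec() -> SpatialSpec:
    """Four SST+ clusters with distinct laminar preferences plus background."""
    clusters = [
        SpatialCluster("SST_L23", 250, {1: 0.05, 2: 0.40, 3: 0.35, 4: 0.10, 5: 0.07, 6: 0.03}),
        SpatialCluster("SST_L4", 200, {1: 0.02, 2: 0.08, 3: 0.15, 4: 0.55, 5: 0.15, 6: 0.05}),
        SpatialCluster("SST_L5", 250, {1: 0.01, 2: 0.04, 3: 0.05, 4: 0.15, 5: 0.55, 6: 0.20}),
        SpatialCluster("SST_L6", 200, {1: 0.01, 2: 0.02, 3: 0.04, 4: 0.08, 5: 0.25, 6: 0.60}),
        SpatialCluster("Pyr", 300, {1: 0.1, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2, 6: 0.1}, is_sst=False),
    ]
    return SpatialSpec(clusters=clusters)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_counts(spec: SimSpec) -> tuple[CountMatrix, CellMetadata]:
    """Draw the planted-hierarchy dataset; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_marker_genes() > spec.n_genes:
        raise ValueError(
            f"marker genes required ({spec.n_marker_genes()}) exceed n_genes ({spec.n_genes})"
        )

    leaves = spec.leaf_labels()
    types = list(spec.hierarchy)
    n_cells = spec.n_cells_per_cluster * len(leaves)
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]

    # disjoint marker blocks, deterministic layout
    cursor = 0
    type_markers: dict[str, np.ndarray] = {}
    for t in types:
        type_markers[t] = np.arange(cursor, cursor + spec.n_markers_type)
        cursor += spec.n_markers_type
    leaf_markers: dict[str, np.ndarray] = {}
    for leaf in leaves:
        leaf_markers[leaf] = np.arange(cursor, cursor + spec.n_markers_subtype)
        cursor += spec.n_markers_subtype
    stress_idx = np.arange(cursor, cursor + spec.n_stress_markers) if spec.stressed_fraction > 0 else np.array([], dtype=int)
    cursor += stress_idx.size

    base = rng.gamma(spec.baseline_shape, spec.baseline_scale, size=spec.n_genes)
    # canonical markers are well expressed
    marker_all = np.concatenate([*type_markers.values(), *leaf_markers.values()]) if leaves else np.array([], int)
    base[marker_all] = spec.marker_baseline_mean * rng.uniform(0.7, 1.3, size=marker_all.size)
    if stress_idx.size:
        base[stress_idx] = spec.marker_baseline_mean * rng.uniform(0.7, 1.3, size=stress_idx.size)

    truth = np.repeat(leaves, spec.n_cells_per_cluster)
    truth_type = np.array([lab.split(".")[0] for lab in truth])
    stage = np.array([spec.stages[i % len(spec.stages)] for i in range(n_cells)])
    stressed = rng.random(n_cells) < spec.stressed_fraction

    # per-stage batch shift on a random gene subset
    batch_genes = {
        st: rng.choice(spec.n_genes, size=int(spec.batch_gene_fraction * spec.n_genes), replace=False)
        for st in spec.stages
    }

    lib = np.exp(rng.normal(0.0, spec.library_sigma, size=n_cells))
    lib[stressed] *= spec.stress_library_factor

    counts = np.empty((n_cells, spec.n_genes), dtype=np.int64)
    log_lfc = np.zeros((n_cells, spec.n_genes))
    for i, leaf in enumerate(truth):
        t = truth_type[i]
        log_lfc[i, type_markers[t]] = spec.lfc_type
        log_lfc[i, leaf_markers[leaf]] = spec.lfc_subtype
        if stressed[i] and stress_idx.size:
            log_lfc[i, stress_idx] = spec.stress_lfc
        if spec.batch_shift:
            log_lfc[i, batch_genes[stage[i]]] += spec.batch_shift
    mean = base[None, :] * np.exp(log_lfc) * lib[:, None]
    counts = _nb_draw(rng, mean, spec.dispersion)

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    flags = _flag_genes(gene_ids, stress_genes=[gene_ids[j] for j in stress_idx])
    cm = CountMatrix(sp.csr_matrix(counts), cell_ids, gene_ids, flags)

    pct_mito = rng.beta(2, 40, size=n_cells)
    pct_aligned = rng.beta(60, 6, size=n_cells)
    if stressed.any():
        k = int(stressed.sum())
        pct_mito[stressed] = rng.beta(8, 12, size=k)
        pct_aligned[stressed] = rng.beta(20, 10, size=k)

    meta = CellMetadata(
        pd.DataFrame(
            {
                "total_umi": cm.total_umi().astype(int),
                "n_genes": cm.genes_per_cell().astype(int),
                "pct_aligned": pct_aligned,
                "pct_mito": pct_mito,
                "stage": stage,
                "truth_label": truth,
                "truth_type": truth_type,
                "truth_stressed": stressed,
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
    )
    return cm, meta


def simulate_trajectory(spec: SimSpec) -> tuple[CountMatrix, CellMetadata]:
    """Branching maturation trajectory with latent time t in [0, 1].

    A shared maturation gene set changes identically on all branches;
    branch-specific sets change monotonically in t on their own branch only.
    """
    ts = spec.trajectory
    if ts.n_branches < 1:
        raise ValueError("need >= 1 branch")
    rng = np.random.default_rng(spec.seed + 1)

    n = ts.n_cells
    t = rng.uniform(0, 1, size=n)
    branch = rng.integers(0, ts.n_branches, size=n)

    n_genes = ts.n_shared_genes + ts.n_branches * ts.genes_per_branch + ts.n_noise_genes
    gene_ids = [f"tg{i:04d}" for i in range(n_genes)]
    shared = np.arange(ts.n_shared_genes)
    branch_blocks = [
        np.arange(
            ts.n_shared_genes + b * ts.genes_per_branch,
            ts.n_shared_genes + (b + 1) * ts.genes_per_branch,
        )
        for b in range(ts.n_branches)
    ]

    base = np.full(n_genes, ts.baseline_mean)
    base[ts.n_shared_genes + ts.n_branches * ts.genes_per_branch:] = 1.0

    # the shared program mixes genes switching on with progenitor genes
    # switching off; branch programs only switch on, so all branches meet
    # at the root state
    def shared_program(tvals: np.ndarray, block: np.ndarray) -> np.ndarray:
        up = (np.arange(block.size) % 2) == 0
        out = np.empty((tvals.size, block.size))
        out[:, up] = ts.effect * tvals[:, None]
        out[:, ~up] = ts.effect * (1.0 - tvals[:, None])
        return out

    log_lfc = np.zeros((n, n_genes))
    log_lfc[:, shared] = shared_program(t, shared)
    # fate programs engage early and then saturate (monotone, concave in t)
    for b, block in enumerate(branch_blocks):
        mask = branch == b
        log_lfc[np.ix_(mask, block)] = ts.effect * np.sqrt(t[mask, None])

    lib = np.exp(rng.normal(0.0, ts.library_sigma, size=n))
    mean = base[None, :] * np.exp(log_lfc) * lib[:, None]
    counts = _nb_draw(rng, mean, ts.dispersion)

    cell_ids = [f"tcell{i:05d}" for i in range(n)]
    cm = CountMatrix(sp.csr_matrix(counts), cell_ids, gene_ids)
    meta = CellMetadata(
        pd.DataFrame(
            {
                "total_umi": cm.total_umi().astype(int),
                "n_genes": cm.genes_per_cell().astype(int),
                "pct_aligned": np.full(n, 0.9),
                "pct_mito": np.full(n, 0.02),
                "stage": pd.cut(t, [0, 1 / 3, 2 / 3, 1.0], labels=list(spec.stages)[:3], include_lowest=True).astype(str),
                "truth_time": t,
                "truth_branch": [f"br{b}" for b in branch],
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
    )
    return cm, meta


def simulate_spatial(spec: SimSpec) -> pd.DataFrame:
    """Spatial cell table: x, y (microns), layer 1..6, truth cluster, panel counts.

    Layer bands are stacked along y (layer 1 at the top).  Gate genes are
    expressed only in SST+ clusters; background cells carry
    ``background_gate_mean`` (0 by default).
    """
    ss = spec.spatial or default_spatial_spec()
    rng = np.random.default_rng(spec.seed + 2)
    for cl in ss.clusters:
        tot = sum(cl.layer_probs.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-8):
            raise ValueError(f"layer probabilities of {cl.name} sum to {tot}, not 1")

    # every population carries a marker block, including the non-neuronal
    # background (glial / excitatory genes are always present in real panels)
    n_markers = (len(ss.clusters) + 1) * ss.n_markers_per_cluster
    n_named = len(ss.gate_genes) + n_markers
    if n_named > ss.panel_size:
        raise ValueError("panel too small for gate + marker genes")
    all_groups = ss.clusters + [
        SpatialCluster("background", ss.n_background, {k: 1 / 6 for k in range(1, 7)}, is_sst=False)
    ]
    panel = list(ss.gate_genes)
    marker_blocks = {}
    for cl in all_groups:
        block = [f"{cl.name}_mk{j}" for j in range(ss.n_markers_per_cluster)]
        marker_blocks[cl.name] = block
        panel.extend(block)
    panel.extend(f"panel{j:02d}" for j in range(ss.panel_size - len(panel)))

    rows = []
    height = 1000.0 / 6  # microns per layer band
    for cl in all_groups:
        layers = np.array(sorted(cl.layer_probs))
        probs = np.array([cl.layer_probs[k] for k in layers])
        drawn = rng.choice(layers, size=cl.n_cells, p=probs)
        x = rng.uniform(0, 1000.0, size=cl.n_cells)
        y = (drawn - 1) * height + rng.uniform(0, height, size=cl.n_cells)
        mean = np.full((cl.n_cells, len(panel)), ss.baseline_mean)
        gate_cols = np.arange(len(ss.gate_genes))
        # interneuron gate genes are off outside the SST+ populations
        mean[:, gate_cols] = ss.gate_mean if cl.is_sst else ss.background_gate_mean
        if cl.name in marker_blocks:
            cols = [panel.index(g) for g in marker_blocks[cl.name]]
            mean[:, cols] = ss.marker_mean
        efficiency = np.exp(rng.normal(0.0, ss.efficiency_sigma, size=cl.n_cells))
        counts = _nb_draw(rng, mean * efficiency[:, None], ss.dispersion)
        for i in range(cl.n_cells):
            rows.append(
                {
                    "x": x[i],
                    "y": y[i],
                    "layer": int(drawn[i]),
                    "truth_cluster": cl.name,
                    "is_sst": cl.is_sst,
                    **{g: int(counts[i, j]) for j, g in enumerate(panel)},
                }
            )
    df = pd.DataFrame(rows)
    df.index = pd.Index([f"scell{i:05d}" for i in range(len(df))], name="cell_id")
    return df


def null_spec(n_cells: int = 300, n_genes: int = 1000, seed: int = 0) -> SimSpec:
    """Single homogeneous population: one leaf, zero marker effects."""
    return SimSpec(
        hierarchy={"A": ["1"]},
        n_cells_per_cluster=n_cells,
        n_genes=n_genes,
        n_markers_type=0,
        n_markers_subtype=0,
        lfc_type=0.0,
        lfc_subtype=0.0,
        stressed_fraction=0.0,
        seed=seed,
    )


def flat_spec(
    n_clusters: int = 3,
    n_cells: int = 200,
    n_genes: int = 2000,
    n_markers: int = 20,
    lfc: float = math.log(4.0),
    seed: int = 0,
) -> SimSpec:
    """Flat (single-level) planted clusters: one subtype per type."""
    names = [chr(ord("A") + i) for i in range(n_clusters)]
    return SimSpec(
        hierarchy={nm: ["1"] for nm in names},
        n_cells_per_cluster=n_cells,
        n_genes=n_genes,
        n_markers_type=n_markers,
        n_markers_subtype=0,
        lfc_type=lfc,
        lfc_subtype=0.0,
        stressed_fraction=0.0,
        seed=seed,
    )
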