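"""Pipeline configuration: every tunable threshold with its default value.

A single top-level seed is fanned out deterministically to the stages
(simulation, fold splits, random forests) so a run is reproducible from one
config file.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class PipelineConfig:
    # reproducibility
    seed: int = 0

    # QC (adaptive thresholds are mean - 2 sd, computed per dataset)
    min_cells_per_gene: int = 10
    min_genes_per_cell: int = 700
    max_pct_mito: float = 0.10
    qc_sd_multiplier: float = 2.0
    mito_prefixes: tuple = ("mt-",)
    ribo_prefixes: tuple = ("Rps", "Rpl")
    y_chromosome_genes: tuple = ()
    stress_marker_genes: tuple = ()

    # normalization / features / scaling
    scale_factor: float = 1000.0
    n_variable_features: int = 2000
    scale_clip: float = 10.0
    n_pcs: int = 15

    # differential expression
    de_alpha: float = 0.01
    de_lfc_min: float = math.log(1.5)
    de_exact_max_group: int = 8
    marker_top_n: int = 10

    # iterative clustering
    k_min: int = 2
    k_max: int = 20
    descore_min: float = 60.0
    cluster_size_min: int = 50
    recurse_size_min: int = 100
    cluster_lfc_min: float = math.log(2.0)
    cluster_metric: str = "correlation"  # or "euclidean_pca"

    # validation (pairwise random forest)
    n_folds: int = 5
    n_trees: int = 1000
    n_iterations: int = 100
    rf_top_genes: int = 10

    # alignment
    auroc_threshold: float = 0.75
    spatial_auroc_threshold: float = 0.80
    stress_descore_cut: float = 10.0
    ambiguity_rel_diff: float = 0.10

    # gene modules / trajectory
    module_rho_min: float = 0.3
    module_min_partners: int = 3
    module_min_detect_frac: float = 0.05
    module_abs_correlation: bool = False
    n_diffusion_components: int = 15
    knn: int = 15
    trunk_quantile: float = 0.05

    # spatial
    superficial_layers: tuple = (1, 2, 3, 4)
    deep_layers: tuple = (5, 6)

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        for name, lo, hi in (
            ("max_pct_mito", 0, 1),
            ("de_alpha", 0, 1),
            ("auroc_threshold", 0, 1),
            ("spatial_auroc_threshold", 0, 1),
            ("module_rho_min", -1, 1),
            ("trunk_quantile", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        return np.random.default_rng(self.stage_seed(stage))

    def stage_seed(self, stage: str) -> int:
        # crc32 is stable across processes (unlike hash() on str)
        return int(
            np.random.SeedSequence(
                [int(self.seed), zlib.crc32(stage.encode())]
            ).generate_state(1)[0]
            % (2**31)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(f.default, tuple):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
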