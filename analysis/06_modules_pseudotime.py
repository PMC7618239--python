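#!/usr/bin/env python
"""Gene modules, diffusion pseudotime and branch assignment.

On the trajectory cohort: filters genes by Spearman co-expression (>= 0.3
with at least 3 partners), builds modules by iterative hierarchical
clustering with validity filtering, selects the module varying most across
stages, computes the diffusion map and DPT from an early-stage root,
assigns three branches, and tests genes for trajectory association with
Moran's I on the diffusion embedding.
"""

import argparse
import json
from pathlib import Path

from scipy import stats

from sstdiv.io import read_10x_triplet, read_metadata
from sstdiv.qc import lognormalize
from sstdiv.trajectory import (
    assign_branches,
    compute_modules,
    correlation_filter_genes,
    diffusion_map,
    diffusion_pseudotime,
    morans_i,
    pick_root,
    prefilter_module_matrix,
    select_developmental_module,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/trajectory"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cm = read_10x_triplet(args.data_dir / "traj_counts")
    meta = read_metadata(args.data_dir / "traj_metadata.csv")

    cpm = prefilter_module_matrix(cm, min_genes_per_cell=300)
    kept = correlation_filter_genes(cpm)
    modules = compute_modules(cpm, genes=kept)
    with open(args.out_dir / "modules.json", "w") as fh:
        json.dump(modules.to_json_dict(), fh, indent=1)
    print(f"{len(kept)} correlated genes -> {len(modules.modules)} modules "
          f"({', '.join(str(len(m['genes'])) for m in modules.modules)} genes)")

    stages = meta.table.loc[cpm.index, "stage"].to_numpy()
    dev = select_developmental_module(cpm, modules, stages)
    print(f"developmental module: {dev['module_id']} ({len(dev['genes'])} genes, "
          f"Kruskal-Wallis H={dev['H']:.1f}, p={dev['p']:.2e})")

    norm = lognormalize(cm)
    gene_idx = norm.gene_index(dev["genes"])
    dm = diffusion_map(norm.values[:, gene_idx], cell_ids=cm.cell_ids)
    root = pick_root(dm, meta.table["stage"].to_numpy(), "E16.5")
    pt = diffusion_pseudotime(dm, root)
    branches = assign_branches(dm, pt, n_branches=3)

    out = meta.table.copy()
    out["pseudotime"] = pt.reindex(out.index)
    out["branch"] = branches.reindex(out.index)
    out.to_csv(args.out_dir / "pseudotime.csv", index_label="cell_id")
    rho = stats.spearmanr(out["pseudotime"], out["truth_time"]).statistic
    print(f"DPT vs latent time Spearman rho = {rho:.3f}; "
          f"branch sizes {branches.value_counts().to_dict()}")

    mi = morans_i(norm.values[:, gene_idx], dev["genes"], dm.components)
    mi.to_csv(args.out_dir / "morans_i.tsv", sep="\t")
    print(f"{int((mi['p_adj'] < 0.01).sum())}/{len(mi)} module genes trajectory-associated (Moran's I)")


if __name__ == "__main__":
    main()
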