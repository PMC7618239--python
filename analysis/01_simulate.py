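#!/usr/bin/env python
"""Generate the synthetic study cohorts all later stages consume.

Three datasets with planted ground truth are written under results/data/:
a developmental scRNA-seq cohort (3 types x 2 subtypes, 200 cells per
subtype, 2,000 genes, 5% stressed cells, three stages), a branching
maturation trajectory (3 branches, 500 cells), and a spatial panel table
(four SST+ clusters with laminar preferences plus background).
"""

import argparse
from pathlib import Path

from sstdiv.io import write_10x_triplet, write_metadata
from sstdiv.simulate import SimSpec, simulate_counts, simulate_spatial, simulate_trajectory


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    spec = SimSpec(seed=args.seed, stressed_fraction=0.05)
    cm, meta = simulate_counts(spec)
    write_10x_triplet(cm, args.out_dir / "dev_counts")
    write_metadata(meta, args.out_dir / "dev_metadata.csv")
    print(
        f"developmental cohort: {cm.n_cells} cells x {cm.n_genes} genes, "
        f"{meta.table['truth_stressed'].sum()} stressed, "
        f"{meta.table['truth_label'].nunique()} planted subtypes"
    )

    cmt, metat = simulate_trajectory(spec)
    write_10x_triplet(cmt, args.out_dir / "traj_counts")
    write_metadata(metat, args.out_dir / "traj_metadata.csv")
    print(f"trajectory cohort: {cmt.n_cells} cells x {cmt.n_genes} genes, 3 branches")

    tab = simulate_spatial(spec)
    tab.to_csv(args.out_dir / "spatial_table.csv")
    print(f"spatial table: {len(tab)} cells, {int(tab['is_sst'].sum())} SST+ planted")


if __name__ == "__main__":
    main()
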