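#!/usr/bin/env python
"""Spatial analysis: SST+ gating, laminar distributions, Fisher tests.

Gates the spatial table to clusters in which Sst, Gad1, Gad2 and Lhx6 are
all enriched, tabulates each cluster's laminar distribution, and compares
superficial (layers 1-4) vs deep (layers 5-6) placement between clusters
with the exact Fisher test.
"""

import argparse
import json
from itertools import combinations
from pathlib import Path

import pandas as pd

from sstdiv.spatial import (
    gate_sst_cells,
    laminar_distribution,
    superficial_deep_split,
    superficial_deep_test,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/spatial"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tab = pd.read_csv(args.data_dir / "spatial_table.csv", index_col="cell_id")
    gated = gate_sst_cells(tab)
    gated.to_csv(args.out_dir / "gated_cells.csv")
    tp = gated["is_sst"].sum()
    print(f"gated {len(gated)} cells ({tp} truly SST+) from {len(tab)} total")

    counts, fracs = laminar_distribution(gated)
    counts.to_csv(args.out_dir / "laminar_counts.tsv", sep="\t")
    fracs.round(3).to_csv(args.out_dir / "laminar_fractions.tsv", sep="\t")
    print("laminar fractions per cluster:")
    print(fracs.round(2).to_string())

    split = superficial_deep_split(gated)
    tests = {}
    for a, b in combinations(split.index, 2):
        res = superficial_deep_test(split.loc[a].to_dict(), split.loc[b].to_dict())
        tests[f"{a}_vs_{b}"] = res
        flag = "*" if res["p_value"] < 0.05 else " "
        print(f"  {a} vs {b}: OR={res['odds_ratio']:.2f}, p={res['p_value']:.2e} {flag}")
    with open(args.out_dir / "fisher_tests.json", "w") as fh:
        json.dump(tests, fh, indent=1)


if __name__ == "__main__":
    main()
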