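# sstdiv

Transcriptomic subtype discovery for cortical somatostatin-positive (SST+)
interneurons across development — a tested, reusable implementation of an
iterative clustering-and-validation workflow for single-cell RNA-seq and
spatial transcriptomics, exercised end-to-end on synthetic data with
planted ground truth.

## The problem and the approach

Developing cortical SST+ interneurons form subtypes that are hard to call
reliably: clusters must be distinct enough to be real, stable enough to be
reproducible, and mappable onto adult reference types and onto tissue.
The pipeline addresses this with five connected analyses:

1. **QC and normalization.** Genes detected in < 10 cells are dropped;
   cells are kept when unique genes > 700, mitochondrial content < 10%,
   and both the confidently-aligned-read fraction and ln(total UMI) exceed
   their dataset mean − 2 s.d.; mitochondrial, ribosomal and Y-chromosome
   genes are then removed.  Counts are normalized as
   `x_norm = ln(1 + S·x / x_tot)` with `S = 1000`.

2. **Iterative DEscore-guided clustering.**  Starting from all cells as one
   cluster: recompute the top 2,000 variance-stabilized variable genes,
   scale, cluster hierarchically (average linkage on 1 − Pearson
   correlation), cut the dendrogram at the `k ∈ [2, 20]` with the best mean
   silhouette, and score each candidate cluster with

   `DEscore = Σᵢ min(−log₁₀ pᵢ, 20)`

   over its one-vs-rest Wilcoxon DEGs (log-fold change > ln 2, Bonferroni
   p < 0.01).  Clusters with DEscore < 60 or fewer than 50 cells fail and
   are merged into their nearest qualifying cluster; qualifying clusters of
   ≥ 100 cells are recursed into.

3. **Random-forest validation.**  Iterated five-fold cross-validation
   trains a 1,000-tree random forest for every cluster pair on the two
   clusters' top-10 DEGs (recomputed per training split) and classifies the
   held-out cells.  A per-cell dominance analysis discounts identities that
   never win a pairwise comparison; surviving identities receive vote-share
   membership scores, giving **Core** (score 1), **Intermediate** (split,
   unique winner) and **Failed** (even split or nothing retained) cells.

4. **Cluster alignment.**  Correspondence between two labeled datasets is
   scored by neighbor-voting AUROC on a rank-standardized Spearman
   correlation network (MetaNeighbor-style); AUROC > 0.75 marks a strong
   match (> 0.8 for spatial panels).  Clusters are annotated by the marker
   set with the highest restricted DEscore; a stress-marker DEscore > 10
   discounts a cluster as stressed.

5. **Trajectory and space.**  Spearman-correlated gene modules
   (ρ ≥ 0.3 with ≥ 3 partners, iterative clustering with validity
   filtering) feed a diffusion map; diffusion pseudotime (DPT) from an
   early-stage root orders cells, and branches are assigned by nearest tip.
   Spatial panels are gated to clusters where Sst, Gad1, Gad2 and Lhx6 are
   all enriched, laminar distributions are tabulated, and superficial
   (layers 1–4) vs deep (layers 5–6) placement is compared with the exact
   Fisher test.

Because the deposited datasets are not required, the package ships a
first-class synthetic-data module (`sstdiv.simulate`) that plants a
two-level cluster hierarchy (negative-binomial counts, log-normal
libraries, a stressed contaminating population), a three-branch maturation
trajectory, and a spatial table with cluster-dependent laminar placement —
every downstream stage is tested against this planted truth.

## Worked example

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_qc_normalize.py
python analysis/03_cluster.py
```

prints

```
cells 1200 -> 1050, genes 2000 -> 1927
stressed fraction 0.038 -> 0.000 (QC removes the stressed population)
6 leaf clusters; ARI vs planted subtypes = 0.909
  leaf 0.0.0: 189 cells, dominant truth A.1 (177)
  ...
```

i.e. QC eliminates the planted stressed cells, and the recursion discovers
exactly the six planted subtypes (adjusted Rand index 0.91 against truth).
Continuing with `04_validate.py` (RF membership: 965 Core / 79
Intermediate / 6 Failed at 3 demo iterations), `05_align.py` (each leaf
matches its generating subtype in an independent replicate at AUROC ≈ 0.99,
with sibling subtypes as secondary matches ≈ 0.8), `06_modules_pseudotime.py`
(DPT vs latent time Spearman ρ = 0.994, three branches recovered) and
`07_spatial.py` (899 gated cells of which 897 truly SST+, laminar
fractions and Fisher contrasts per cluster) walks the whole workflow.

## Layout

- `src/sstdiv/` — the library: `io`, `config`, `containers`, `simulate`,
  `qc`, `de`, `cluster`, `validate`, `align`, `trajectory`, `spatial`.
- `analysis/` — numbered narrative drivers (simulate → qc → cluster →
  validate → align → modules/pseudotime → spatial) writing to `results/`.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — the model, parameter and design notes.
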