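"""Pairwise random-forest cross-validation of cluster identities.

Every iteration runs a stratified five-fold split; DEGs are recomputed on
the training folds only (no leakage), and for each unordered pair of
clusters a 1,000-tree random forest trained on the union of the two
clusters' top-10 DEG features predicts the held-out cells of those two
clusters.  Votes accumulated across iterations feed a per-cell dominance
reduction: an identity that receives zero votes in any of the cell's
pairwise comparisons while its opponent takes them all is discounted; the
membership score of each retained identity is its share of the retained
votes.  A cell with a single retained identity (score 1, rest 0) is Core; a
split with a unique winner is Intermediate; an even split, or no retained
identity, is a Failed classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .containers import NormalizedMatrix
from .de import filter_degs, wilcoxon_one_vs_rest

log = logging.getLogger("sstdiv")


@dataclass
class PairwiseAssignments:
    """Vote counts per cell per unordered cluster pair.

    ``votes[(a, b)]`` is a DataFrame indexed by cell id with columns [a, b];
    for CV assignments each row sums to the number of iterations in which
    that cell fell in the pair's test fold.
    """

    votes: dict = field(default_factory=dict)
    identities: list = field(default_factory=list)
    n_iterations: int = 0


@dataclass
class MembershipTable:
    """Per-cell membership scores with Core/Intermediate/Failed status."""

    scores: pd.DataFrame  # cells x identities, rows sum to 1 (or 0 if Failed w/o retained)
    status: pd.Series
    assigned: pd.Series  # identity or NaN for Failed

    def to_csv(self, path) -> None:
        out = self.scores.copy()
        out.insert(0, "status", self.status)
        out.insert(1, "assigned", self.assigned)
        out.to_csv(path, index_label="cell_id")


def _top_markers_per_cluster(norm, labels, clusters, top_n, lfc_min, alpha):
    markers = {}
    for c in clusters:
        res = wilcoxon_one_vs_rest(norm, labels, c)
        degs = filter_degs(res, lfc_min=lfc_min, alpha=alpha)
        if not degs:
            # fall back to the largest positive fold changes so the pair
            # classifier always has features
            t = res.table.sort_values("log_fold_change", ascending=False)
            degs = t.index[:top_n].tolist()
        markers[c] = degs[:top_n]
    return markers


def pairwise_rf_cv(
    norm: NormalizedMatrix,
    labels,
    n_folds: int = 5,
    n_trees: int = 1000,
    top_genes: int = 10,
    n_iterations: int = 100,
    lfc_min: float = np.log(1.5),
    alpha: float = 0.01,
    feature_values: np.ndarray | None = None,
    seed: int = 0,
) -> PairwiseAssignments:
    """Run the iterated five-fold pairwise random-forest procedure.

    ``feature_values`` (cells x genes, aligned with ``norm``) is the matrix
    the classifiers read — pass the batch-centered matrix when one exists;
    DEGs are always computed from ``norm`` itself.
    """
    labels = np.asarray(labels).astype(str)
    clusters = sorted(np.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    for c in clusters:
        if (labels == c).sum() < n_folds:
            raise ValueError(f"cluster {c!r} has fewer cells than n_folds={n_folds}")
    x = feature_values if feature_values is not None else norm.values
    x = np.asarray(x, dtype=float)
    cell_ids = np.asarray(norm.cell_ids)
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}

    pairs = list(combinations(clusters, 2))
    votes = {
        p: pd.DataFrame(
            0,
            index=cell_ids[np.isin(labels, p)],
            columns=list(p),
        )
        for p in pairs
    }
    root = np.random.SeedSequence([seed, 0xC1])
    iter_seeds = root.generate_state(n_iterations * 2).reshape(n_iterations, 2)

    for it in range(n_iterations):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(iter_seeds[it, 0] % (2**31))
        )
        for fold, (train_idx, test_idx) in enumerate(skf.split(x, labels)):
            train_norm = norm.subset_cells(train_idx)
            markers = _top_markers_per_cluster(
                train_norm, labels[train_idx], clusters, top_genes, lfc_min, alpha
            )
            for pi, (a, b) in enumerate(pairs):
                feat_genes = list(dict.fromkeys(markers[a] + markers[b]))
                cols = np.array([gene_pos[g] for g in feat_genes])
                tr = train_idx[np.isin(labels[train_idx], (a, b))]
                te = test_idx[np.isin(labels[test_idx], (a, b))]
                if te.size == 0:
                    continue
                rf = RandomForestClassifier(
                    n_estimators=n_trees,
                    random_state=int((iter_seeds[it, 1] + 31 * fold + pi) % (2**31)),
                    n_jobs=1,
                )
                rf.fit(x[np.ix_(tr, cols)], labels[tr])
                pred = rf.predict(x[np.ix_(te, cols)])
                vf = votes[(a, b)]
                for cid, p in zip(cell_ids[te], pred):
                    vf.at[cid, p] += 1
    return PairwiseAssignments(votes=votes, identities=clusters, n_iterations=n_iterations)


def dominance_and_membership(assignments: PairwiseAssignments) -> MembershipTable:
    """Reduce pairwise votes to per-cell membership scores and statuses."""
    idents = assignments.identities
    all_cells = sorted({c for vf in assignments.votes.values() for c in vf.index})
    totals = pd.DataFrame(0.0, index=all_cells, columns=idents)
    dominated = pd.DataFrame(False, index=all_cells, columns=idents)
    seen = pd.DataFrame(False, index=all_cells, columns=idents)

    for (a, b), vf in assignments.votes.items():
        va = vf[a].astype(float)
        vb = vf[b].astype(float)
        tot = va + vb
        cells = vf.index
        totals.loc[cells, a] += va
        totals.loc[cells, b] += vb
        seen.loc[cells, [a, b]] = True
        with np.errstate(invalid="ignore"):
            dominated.loc[cells, a] |= ((va == 0) & (tot > 0)).to_numpy()
            dominated.loc[cells, b] |= ((vb == 0) & (tot > 0)).to_numpy()

    retained = seen & ~dominated
    scores = totals.where(retained, 0.0)
    denom = scores.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = scores.div(denom.where(denom > 0), axis=0).fillna(0.0)

    status = pd.Series("Failed", index=scores.index, dtype=object)
    assigned = pd.Series(np.nan, index=scores.index, dtype=object)
    n_retained = retained.sum(axis=1)
    top = scores.max(axis=1)
    top_count = scores.apply(lambda r: int((r >= r.max() - 1e-12).sum()) if r.max() > 0 else 0, axis=1)

    core = (n_retained == 1) & (top >= 1.0 - 1e-12)
    inter = (n_retained > 1) & (top_count == 1)
    status[core] = "Core"
    status[inter] = "Intermediate"
    winners = scores.idxmax(axis=1)
    assigned[core | inter] = winners[core | inter]
    return MembershipTable(scores=scores, status=status, assigned=assigned)


def classify_external(
    train_norm: NormalizedMatrix,
    train_labels,
    test_norm: NormalizedMatrix,
    top_genes: int = 10,
    n_trees: int = 1000,
    n_rounds: int = 10,
    lfc_min: float = np.log(1.5),
    alpha: float = 0.01,
    seed: int = 0,
) -> MembershipTable:
    """Label transfer: the pairwise ensemble trained on all training data
    votes on every test cell; the same dominance reduction applies.

    Genes missing from the test set are imputed as zeros (with a warning);
    an error is raised if fewer than half of the required feature genes are
    present, or if every present feature is identically zero.
    """
    train_labels = np.asarray(train_labels).astype(str)
    clusters = sorted(np.unique(train_labels))
    markers = _top_markers_per_cluster(
        train_norm, train_labels, clusters, top_genes, lfc_min, alpha
    )
    required = sorted({g for m in markers.values() for g in m})
    test_pos = {g: i for i, g in enumerate(test_norm.gene_ids)}
    present = [g for g in required if g in test_pos]
    if len(present) < 0.5 * len(required):
        raise ValueError(
            f"only {len(present)}/{len(required)} required feature genes present in test set"
        )
    missing = sorted(set(required) - set(present))
    if missing:
        warnings.warn(f"imputing {len(missing)} missing feature genes as zero: {missing}")
    test_feat = np.zeros((test_norm.n_cells, len(required)))
    for j, g in enumerate(required):
        if g in test_pos:
            test_feat[:, j] = test_norm.values[:, test_pos[g]]
    if not np.any(test_feat != 0):
        raise ValueError("all required feature genes are zero in the test set")

    req_pos = {g: j for j, g in enumerate(required)}
    train_pos = {g: i for i, g in enumerate(train_norm.gene_ids)}
    xtr = train_norm.values
    pairs = list(combinations(clusters, 2))
    votes = {
        p: pd.DataFrame(0, index=list(test_norm.cell_ids), columns=list(p)) for p in pairs
    }
    root = np.random.SeedSequence([seed, 0xE7])
    seeds = root.generate_state(n_rounds)
    for r in range(n_rounds):
        for pi, (a, b) in enumerate(pairs):
            feat_genes = list(dict.fromkeys(markers[a] + markers[b]))
            tr = np.isin(train_labels, (a, b))
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int((seeds[r] + pi) % (2**31)),
                n_jobs=1,
            )
            cols_tr = [train_pos[g] for g in feat_genes]
            rf.fit(xtr[np.ix_(np.flatnonzero(tr), cols_tr)], train_labels[tr])
            pred = rf.predict(test_feat[:, [req_pos[g] for g in feat_genes]])
            vf = votes[(a, b)]
            for cid, p in zip(test_norm.cell_ids, pred):
                vf.at[cid, p] += 1
    pa = PairwiseAssignments(votes=votes, identities=clusters, n_iterations=n_rounds)
    return dominance_and_membership(pa)
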