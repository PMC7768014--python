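"""Ward.D2 clustering of individuals, bootstrap stability and Mantel tests.

Individuals are clustered from a precomputed distance matrix with the
Murtagh-Legendre ward.D2 agglomeration (Lance-Williams update on squared
dissimilarities; merge heights on the distance scale, non-decreasing).
The tree is typically cut at k = number of accessions, under the
hypothesis that the plants of a uniform accession cluster together; an
accession x cluster membership table then shows how far that holds.

Cluster stability is assessed by bootstrap: individuals are resampled with
replacement, the unique retained individuals are re-clustered, and each
original cluster is scored by its best-match Jaccard coefficient against
the bootstrap clusters (computed on the retained individuals), averaged
over replicates.  Clusters with mean Jaccard > 0.70 are flagged stable.

The Mantel test correlates two distance matrices over the n(n-1)/2
individual pairs, with one-sided permutation p-values under simultaneous
row/column permutations of one matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .distance import GroupedDistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    """Merge tree plus a flat cut at the requested k."""

    linkage: np.ndarray          # scipy (n-1, 4) linkage matrix, ward.D2 heights
    labels: np.ndarray           # cluster id (1..k) per individual
    k: int
    individual_ids: np.ndarray
    accessions: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    def to_newick(self, path: str | Path | None = None) -> str:
        tree = hierarchy.to_tree(self.linkage)
        names = [str(i) for i in self.individual_ids]

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6f}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        text = rec(tree, tree.dist) + ";"
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class StabilityReport:
    """Mean best-match Jaccard per original cluster over B bootstraps."""

    table: pd.DataFrame  # index cluster id; columns mean_jaccard, n_replicates, stable
    B: int
    seed: int | None

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def ward_cluster(d: GroupedDistanceMatrix, k: int) -> ClusteringResult:
    """Agglomerate by ward.D2 and cut into exactly k clusters."""
    n = d.n_individuals
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    if d.undefined_pairs.any():
        raise ValueError("distance matrix has undefined pairs; cannot cluster")
    z = hierarchy.linkage(d.condensed(), method="ward")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        # exact-tie heights can glue merges; force the cut by merge order
        labels = hierarchy.cut_tree(z, n_clusters=k).ravel() + 1
    assert len(np.unique(labels)) == k, "cut produced an empty cluster"
    return ClusteringResult(z, labels, k, d.individual_ids.copy(), d.accessions.copy())


def membership_table(c: ClusteringResult) -> tuple[pd.DataFrame, int]:
    """Accession x cluster percentage matrix; rows sum to 100.

    Also returns the number of accessions forming pure singleton clusters
    (all plants of the accession in one cluster containing nothing else).
    """
    df = pd.DataFrame({"accession": c.accessions, "cluster": c.labels})
    counts = df.groupby(["accession", "cluster"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=range(1, c.k + 1), fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    cluster_n_accessions = (counts > 0).sum(axis=0)
    pure = 0
    for acc in counts.index:
        row = counts.loc[acc]
        used = row[row > 0]
        if len(used) == 1 and cluster_n_accessions[used.index[0]] == 1:
            pure += 1
    return pct, pure


# ---------------------------------------------------------------------------
# Bootstrap stability
# ---------------------------------------------------------------------------

def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def bootstrap_stability(
    d: GroupedDistanceMatrix, k: int, B: int = 100, seed: int | None = 0
) -> StabilityReport:
    """Per-cluster mean best-match Jaccard over B bootstrap resamples."""
    if B < 1:
        raise ValueError("B must be >= 1")
    base = ward_cluster(d, k)
    originals = {cid: set(np.flatnonzero(base.labels == cid)) for cid in range(1, k + 1)}
    rng = np.random.default_rng(seed)
    n = d.n_individuals
    sums = {cid: 0.0 for cid in originals}
    counts = {cid: 0 for cid in originals}
    for _ in range(B):
        retained = np.unique(rng.integers(0, n, size=n))
        if retained.size < 3:
            continue
        sub = d.submatrix(retained)
        kk = min(k, retained.size)
        boot = ward_cluster(sub, max(kk, 2))
        boot_sets = [set(retained[np.flatnonzero(boot.labels == cid)])
                     for cid in range(1, boot.k + 1)]
        retained_set = set(retained.tolist())
        for cid, members in originals.items():
            present = members & retained_set
            if not present:
                continue
            best = max(_jaccard(present, bs) for bs in boot_sets)
            sums[cid] += best
            counts[cid] += 1
    rows = {
        cid: {
            "mean_jaccard": sums[cid] / counts[cid] if counts[cid] else np.nan,
            "n_replicates": counts[cid],
        }
        for cid in originals
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "cluster"
    table["stable"] = table["mean_jaccard"] > 0.70
    return StabilityReport(table, B=B, seed=seed)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    d1: GroupedDistanceMatrix | np.ndarray,
    d2: GroupedDistanceMatrix | np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """One-sided Mantel correlation between two distance matrices.

    r is the Pearson correlation over the off-diagonal upper-triangle
    pairs; p = (1 + #{r_perm >= r}) / (1 + n_perm) under simultaneous
    row/column permutations of the second matrix.  Matrices must describe
    the same individuals in the same order.  Returns (nan, nan) when either
    matrix has zero variance over pairs.
    """
    m1 = d1.values if isinstance(d1, GroupedDistanceMatrix) else np.asarray(d1, float)
    m2 = d2.values if isinstance(d2, GroupedDistanceMatrix) else np.asarray(d2, float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if (isinstance(d1, GroupedDistanceMatrix) and isinstance(d2, GroupedDistanceMatrix)
            and not np.array_equal(d1.individual_ids, d2.individual_ids)):
        raise ValueError("matrices must describe the same individuals in the same order")
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1, v2 = m1[iu], m2[iu]
    tol1 = 1e-12 * max(1.0, float(np.abs(v1).max()))
    tol2 = 1e-12 * max(1.0, float(np.abs(v2).max()))
    if np.std(v1) <= tol1 or np.std(v2) <= tol2:
        logger.warning("Mantel: zero variance over pairs; r undefined")
        return float("nan"), float("nan")
    z1 = (v1 - v1.mean()) / v1.std()
    z2 = (v2 - v2.mean()) / v2.std()
    r_obs = float(np.mean(z1 * z2))
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = m2[np.ix_(perm, perm)][iu]
        zp = (vp - vp.mean()) / vp.std()
        if np.mean(z1 * zp) >= r_obs:
            ge += 1
    p = (1 + ge) / (1 + n_perm)
    return r_obs, p
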