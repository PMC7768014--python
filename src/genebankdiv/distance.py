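"""Pairwise individual distances and within/between accession summaries.

Two metrics, both bounded in [0, 1]:

* modified Rogers distance (MRD) between diploid SNP genotypes,
  ``d(i, j) = sqrt( (1 / m_ij) * sum_l (p_il - p_jl)^2 )`` where
  ``p_il = dosage / 2`` is individual *i*'s alternate-allele frequency at
  locus *l* and ``m_ij`` counts the loci called in both individuals
  (pairwise-complete with per-pair renormalisation);
* Gower dissimilarity for mixed phenotypes: range-normalised absolute
  difference for quantitative traits (ranges taken over the whole table
  once), 0/1 mismatch for qualitative traits, averaged over the traits
  observed in both individuals.

Summaries report, per accession, the mean distance over pairs inside the
accession and the mean over member-outsider pairs, mirroring the layout of
per-accession diversity tables, plus an overlap coefficient between the
within-pair and between-pair distance distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PhenotypeTable, QUANTITATIVE

logger = logging.getLogger(__name__)


@dataclass
class GroupedDistanceMatrix:
    """Symmetric pairwise distances with accession grouping.

    ``n_compared[i, j]`` counts loci (or traits) actually compared for the
    pair; pairs with no overlap are undefined (NaN distance, count 0).
    """

    values: np.ndarray
    n_compared: np.ndarray
    individual_ids: np.ndarray
    accessions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_compared = np.asarray(self.n_compared)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.n_compared.shape != (n, n):
            raise ValueError("distance and comparison-count matrices must be square")
        if len(self.individual_ids) != n or len(self.accessions) != n:
            raise ValueError("ids/accessions do not match matrix size")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        off = ~np.eye(n, dtype=bool)
        vals = self.values[off]
        if np.nanmin(vals, initial=0.0) < -1e-12 or np.nanmax(vals, initial=0.0) > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def undefined_pairs(self) -> np.ndarray:
        """Boolean mask of off-diagonal pairs with nothing compared."""
        off = ~np.eye(self.n_individuals, dtype=bool)
        return off & (self.n_compared < 1)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(self.n_individuals, k=1)
        return self.values[iu]

    def submatrix(self, idx: np.ndarray) -> "GroupedDistanceMatrix":
        idx = np.asarray(idx)
        return GroupedDistanceMatrix(
            self.values[np.ix_(idx, idx)], self.n_compared[np.ix_(idx, idx)],
            self.individual_ids[idx], self.accessions[idx],
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.individual_ids,
                     columns=self.individual_ids).to_csv(path)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_individuals}\n")
            for i, name in enumerate(self.individual_ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name} {row}\n")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mrd_pairwise(g: GenotypeMatrix) -> GroupedDistanceMatrix:
    """Modified Rogers distances between all pairs of individuals."""
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    p = g.genotypes.astype(float) / 2.0
    valid = (g.genotypes != MISSING).astype(float)
    a = np.where(valid > 0, p, 0.0)
    a2 = a * a
    # sum over shared loci of (p_i - p_j)^2, via masked expansion
    num = a2 @ valid.T + valid @ a2.T - 2.0 * (a @ a.T)
    m = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(num, 0.0) / m)
    d[m < 1] = np.nan
    np.fill_diagonal(d, 0.0)
    d = np.minimum(d, 1.0)
    if np.isnan(d[~np.eye(len(d), dtype=bool)]).any():
        logger.warning("MRD: some pairs share no called loci and are undefined")
    return GroupedDistanceMatrix(d, m.astype(int), g.individual_ids.copy(), g.accessions.copy())


def gower_pairwise(p: PhenotypeTable) -> GroupedDistanceMatrix:
    """Gower dissimilarities between all pairs of individuals."""
    if p.n_individuals < 2:
        raise ValueError("need at least two individuals")
    n = p.n_individuals
    num = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)
    for name in p.trait_names:
        col = p.data[name]
        if p.kinds[name] == QUANTITATIVE:
            x = col.to_numpy(dtype=float)
            finite = np.isfinite(x)
            if finite.sum() < 1:
                continue
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0:
                logger.warning("Gower: trait %r has zero range, skipped", name)
                continue
            diff = np.abs(x[:, None] - x[None, :]) / rng
            ok = finite[:, None] & finite[None, :]
        else:
            labels = col.astype(object).to_numpy()
            known = pd.notna(labels)
            diff = (labels[:, None] != labels[None, :]).astype(float)
            ok = known[:, None] & known[None, :]
        num += np.where(ok, np.nan_to_num(diff), 0.0)
        cnt += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / cnt
    d[cnt < 1] = np.nan
    np.fill_diagonal(d, 0.0)
    if np.isnan(d[~np.eye(n, dtype=bool)]).any():
        logger.warning("Gower: some pairs share no observed traits and are undefined")
    return GroupedDistanceMatrix(d, cnt, p.individual_ids, p.accessions.copy())


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def accession_distance_summary(d: GroupedDistanceMatrix) -> pd.DataFrame:
    """Per-accession mean within and mean member-outsider distances.

    Returns one row per accession (columns ``within_mean``, ``between_mean``,
    ``n_within_pairs``, ``n_between_pairs``) plus ``overall mean`` and
    ``overall range`` rows over the defined per-accession values, matching
    the familiar summary-table layout.  Singleton accessions have undefined
    within means (NaN).
    """
    accs = pd.unique(d.accessions)
    rows = {}
    for acc in accs:
        inside = np.flatnonzero(d.accessions == acc)
        outside = np.flatnonzero(d.accessions != acc)
        if inside.size >= 2:
            iu = np.triu_indices(inside.size, k=1)
            within_vals = d.values[np.ix_(inside, inside)][iu]
            within = float(np.nanmean(within_vals))
            n_within = int(np.isfinite(within_vals).sum())
        else:
            within, n_within = np.nan, 0
        if outside.size >= 1:
            between_vals = d.values[np.ix_(inside, outside)].ravel()
            between = float(np.nanmean(between_vals))
            n_between = int(np.isfinite(between_vals).sum())
        else:
            between, n_between = np.nan, 0
        rows[acc] = {
            "within_mean": within, "between_mean": between,
            "n_within_pairs": n_within, "n_between_pairs": n_between,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "accession"
    w, b = table["within_mean"], table["between_mean"]
    table.loc["overall mean"] = [w.mean(), b.mean(), table["n_within_pairs"].sum(),
                                 table["n_between_pairs"].sum()]
    table.loc["overall range"] = [
        f"{w.min():.3f}-{w.max():.3f}" if w.notna().any() else "",
        f"{b.min():.3f}-{b.max():.3f}" if b.notna().any() else "",
        "", "",
    ]
    return table


def within_between_pairs(d: GroupedDistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All defined within-accession and between-accession pair distances."""
    iu = np.triu_indices(d.n_individuals, k=1)
    same = (d.accessions[:, None] == d.accessions[None, :])[iu]
    vals = d.values[iu]
    ok = np.isfinite(vals)
    return vals[ok & same], vals[ok & ~same]


def distance_density_overlap(
    d: GroupedDistanceMatrix | tuple[np.ndarray, np.ndarray], n_bins: int = 50
) -> float:
    """Overlap coefficient between within-pair and between-pair densities.

    Histogram densities are formed on a shared fixed grid over [0, 1] and
    the overlap is ``sum_bins min(f_within, f_between) * binwidth``: near 0
    means cleanly separated distributions (uniform accessions), near 1
    means merged distributions (heterogeneous accessions).
    """
    if isinstance(d, GroupedDistanceMatrix):
        within, between = within_between_pairs(d)
    else:
        within, between = (np.asarray(x, dtype=float) for x in d)
    if within.size == 0 or between.size == 0:
        raise ValueError("both within and between pair sets must be non-empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    fw, _ = np.histogram(np.clip(within, 0, 1), bins=edges, density=True)
    fb, _ = np.histogram(np.clip(between, 0, 1), bins=edges, density=True)
    width = 1.0 / n_bins
    return float(np.minimum(fw, fb).sum() * width)
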