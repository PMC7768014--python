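"""Three-level analysis of molecular variance (AMOVA) with permutation tests.

The total molecular variance among diploid individuals grouped into
populations (here: genebank accessions) is partitioned into

* among populations (``sigma_a``),
* among individuals within populations (``sigma_b``),
* within individuals (``sigma_w``),

following the Excoffier squared-distance framework: each individual is
expanded to two pseudo-gametes per locus (a heterozygote contributes one
reference and one alternate allele; phase is irrelevant because the
squared-difference metric is additive per locus), squared Euclidean
allele-mismatch distances feed the nested sums of squares, and variance
components are solved from the expected mean squares with unbalanced-design
coefficients.  Degrees of freedom are ``k - 1`` (among populations),
``N - k`` (among individuals within) and ``N`` (within individuals), with
``N`` individuals in ``k`` populations.

Phi fixation indices are reported both as named fields (``phi_st``,
``phi_is``, ``phi_it``) and row-wise in the conventional AMOVA table layout
(among-populations row: Phi_IT; among-individuals row: Phi_IS;
within-individuals row: Phi_ST).

Significance uses Monte-Carlo permutations (default 99): whole individuals
are permuted among populations for the among-population component; gametes
are permuted among individuals within populations for the
among-individuals component; and gametes are permuted among individuals
across populations (statistic Phi_IT) for the within-individuals row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

LEVELS = ("between_populations", "between_samples_within_populations", "within_samples")


@dataclass
class AmovaResult:
    """df / SS / MS / variance components / percentages / Phi / p-values."""

    table: pd.DataFrame
    phi_st: float
    phi_is: float
    phi_it: float
    n_permutations: int = 0
    seed: int | None = None
    degenerate: bool = False
    negative_components: bool = False

    def to_csv(self, path: str | Path) -> None:
        out = self.table.rename(columns={
            "df": "Df", "sum_sq": "Sum Sq", "mean_sq": "Mean Sq",
            "percent": "Variance %", "sigma": "Sigma", "phi": "Phi",
            "p_value": "P-value",
        })[["Df", "Sum Sq", "Mean Sq", "Variance %", "Sigma", "Phi", "P-value"]]
        out.to_csv(path)

    def percent_stack(self) -> pd.Series:
        """Percent of total variance per level (for stacked-bar exports)."""
        return self.table.loc[list(LEVELS), "percent"]


# ---------------------------------------------------------------------------
# Pseudo-gamete expansion
# ---------------------------------------------------------------------------

def _pseudo_gametes(g: GenotypeMatrix, pops: np.ndarray) -> np.ndarray:
    """(2N, n_loci) allele matrix; two consecutive rows per individual.

    Codes map to gamete alleles (0,0) / (0,1) / (1,1).  A missing call
    contributes the within-population mean allele frequency at that locus
    to both pseudo-gametes (mean substitution, logged); loci with no calls
    in a population fall back to the overall frequency, then to 0.5.
    """
    n, m = g.genotypes.shape
    x = np.empty((2 * n, m))
    a1 = np.where(g.genotypes == 2, 1.0, 0.0)
    a2 = np.where(g.genotypes >= 1, 1.0, 0.0)
    miss = g.genotypes == MISSING
    if miss.any():
        logger.info("AMOVA: %d missing calls mean-substituted", int(miss.sum()))
        called = ~miss
        overall_p = np.where(
            called.sum(axis=0) > 0,
            np.where(called, g.genotypes, 0).sum(axis=0) / np.maximum(2 * called.sum(axis=0), 1),
            0.5,
        )
        for pop in pd.unique(pops):
            rows = np.flatnonzero(pops == pop)
            sub, c = g.genotypes[rows], called[rows]
            n_called = c.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n_called > 0,
                             np.where(c, sub, 0).sum(axis=0) / np.maximum(2 * n_called, 1),
                             overall_p)
            fill = np.broadcast_to(p, (rows.size, m))
            sel = miss[rows]
            for arr in (a1, a2):
                block = arr[rows]
                block[sel] = fill[sel]
                arr[rows] = block
    x[0::2] = a1
    x[1::2] = a2
    return x


# ---------------------------------------------------------------------------
# Sums of squares and components
# ---------------------------------------------------------------------------

def _sums_of_squares(x: np.ndarray, pop_of_ind: np.ndarray) -> tuple[float, float, float]:
    """(SS_total, SS_within_pops, SS_within_individuals) for gamete rows x."""
    M = x.shape[0]
    q = np.einsum("ij,ij->i", x, x)
    total_sum = x.sum(axis=0)
    ss_total = q.sum() - total_sum @ total_sum / M
    y = x[0::2] + x[1::2]  # per-individual gamete sums
    ss_wp = q.sum()
    for pop in pd.unique(pop_of_ind):
        rows = np.flatnonzero(pop_of_ind == pop)
        s = y[rows].sum(axis=0)
        ss_wp -= s @ s / (2 * rows.size)
    diff = x[0::2] - x[1::2]
    ss_wi = 0.5 * np.einsum("ij,ij->", diff, diff)
    return float(ss_total), float(ss_wp), float(ss_wi)


def _components(ss_total, ss_wp, ss_wi, pop_sizes: np.ndarray) -> dict:
    k = pop_sizes.size
    n_ind = int(pop_sizes.sum())
    m_gam = 2 * n_ind
    df_a, df_b, df_w = k - 1, n_ind - k, n_ind
    ss_ai = ss_wp - ss_wi
    ss_ap = ss_total - ss_wp
    ms_w = ss_wi / df_w
    ms_b = ss_ai / df_b if df_b > 0 else np.nan
    ms_a = ss_ap / df_a
    sigma_w = ms_w
    sigma_b = (ms_b - sigma_w) / 2.0 if df_b > 0 else 0.0
    m_p = 2 * pop_sizes.astype(float)
    n_c = (m_gam - (m_p ** 2).sum() / m_gam) / df_a
    sigma_a = (ms_a - ms_b) / n_c if df_b > 0 else (ms_a - ms_w) / n_c
    return {
        "df": (df_a, df_b, df_w),
        "ss": (ss_ap, ss_ai, ss_wi, ss_total),
        "ms": (ms_a, ms_b, ms_w),
        "sigma": (sigma_a, sigma_b, sigma_w),
    }


def _phi(sigma_a: float, sigma_b: float, sigma_w: float) -> tuple[float, float, float]:
    total = sigma_a + sigma_b + sigma_w
    phi_st = sigma_a / total if total > 0 else np.nan
    phi_is = sigma_b / (sigma_b + sigma_w) if (sigma_b + sigma_w) > 0 else np.nan
    phi_it = (sigma_a + sigma_b) / total if total > 0 else np.nan
    return phi_st, phi_is, phi_it


def _prepare(g: GenotypeMatrix, grouping, singletons: str):
    pops = np.asarray(grouping if grouping is not None else g.accessions, dtype=object)
    if len(pops) != g.n_individuals:
        raise ValueError("grouping length does not match individuals")
    sizes = pd.Series(pops).value_counts()
    if (sizes < 2).any():
        small = list(sizes[sizes < 2].index)
        if singletons == "drop":
            keep = ~np.isin(pops, small)
            logger.warning("AMOVA: dropping singleton populations %s", small)
            g = g.select_individuals(np.flatnonzero(keep))
            pops = pops[keep]
        else:
            raise ValueError(f"populations with a single individual: {small}")
    if len(pd.unique(pops)) < 2:
        raise ValueError("AMOVA needs at least two populations of size >= 2")
    return g, pops


def amova_decompose(
    g: GenotypeMatrix, grouping=None, singletons: str = "error"
) -> AmovaResult:
    """Nested variance decomposition without permutation p-values.

    ``grouping`` defaults to the accession labels.  Negative variance
    components are reported as-is with a warning flag; when the total
    component sum is <= 0 the result is flagged degenerate and percentages
    are undefined.
    """
    g, pops = _prepare(g, grouping, singletons)
    x = _pseudo_gametes(g, pops)
    sizes = pd.Series(pops).value_counts().to_numpy()
    ss = _sums_of_squares(x, pops)
    comp = _components(*ss, pop_sizes=sizes)
    return _assemble(comp, ss)


def _assemble(comp: dict, ss: tuple, p_values=None, n_perm=0, seed=None) -> AmovaResult:
    sigma_a, sigma_b, sigma_w = comp["sigma"]
    total_sigma = sigma_a + sigma_b + sigma_w
    degenerate = not np.isfinite(total_sigma) or total_sigma <= 0 or ss[0] == 0
    negative = min(comp["sigma"]) < 0
    if negative:
        logger.warning("AMOVA: negative variance component(s) reported as-is")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (np.array(comp["sigma"]) / total_sigma * 100.0
               if not degenerate else np.full(3, np.nan))
    phi_st, phi_is, phi_it = _phi(sigma_a, sigma_b, sigma_w)
    df_a, df_b, df_w = comp["df"]
    ss_ap, ss_ai, ss_wi, ss_total = comp["ss"]
    ms_a, ms_b, ms_w = comp["ms"]
    pv = p_values or {}
    table = pd.DataFrame(
        {
            "df": [df_a, df_b, df_w, df_a + df_b + df_w],
            "sum_sq": [ss_ap, ss_ai, ss_wi, ss_total],
            "mean_sq": [ms_a, ms_b, ms_w, ss_total / (df_a + df_b + df_w)],
            "percent": [*pct, 100.0 if not degenerate else np.nan],
            "sigma": [sigma_a, sigma_b, sigma_w, total_sigma],
            "phi": [phi_it, phi_is, phi_st, np.nan],
            "p_value": [pv.get(l, np.nan) for l in LEVELS] + [np.nan],
        },
        index=[*LEVELS, "total"],
    )
    return AmovaResult(table, phi_st, phi_is, phi_it, n_permutations=n_perm,
                       seed=seed, degenerate=degenerate, negative_components=negative)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def amova_permutation_test(
    g: GenotypeMatrix,
    grouping=None,
    n_perm: int = 99,
    seed: int | None = 0,
    singletons: str = "error",
) -> AmovaResult:
    """AMOVA with Monte-Carlo permutation p-values per level.

    ``p = (1 + #{permuted statistic >= observed}) / (1 + n_perm)``, so the
    smallest attainable p with 99 permutations is 0.01.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g, pops = _prepare(g, grouping, singletons)
    x = _pseudo_gametes(g, pops)
    sizes = pd.Series(pops).value_counts().to_numpy()
    ss = _sums_of_squares(x, pops)
    comp = _components(*ss, pop_sizes=sizes)
    sigma_a, sigma_b, sigma_w = comp["sigma"]
    _, _, phi_it_obs = _phi(sigma_a, sigma_b, sigma_w)

    rng = np.random.default_rng(seed)
    n_ind = len(pops)
    ge = {level: 0 for level in LEVELS}
    for _ in range(n_perm):
        # among populations: whole individuals permuted across populations
        perm_pops = pops[rng.permutation(n_ind)]
        sizes_p = pd.Series(perm_pops).value_counts().to_numpy()
        c = _components(*_sums_of_squares(x, perm_pops), pop_sizes=sizes_p)
        if c["sigma"][0] >= sigma_a:
            ge["between_populations"] += 1

        # among individuals within populations: gametes permuted within pops
        x_within = x.copy()
        for pop in pd.unique(pops):
            rows = np.flatnonzero(pops == pop)
            gam = np.concatenate([[2 * i, 2 * i + 1] for i in rows])
            x_within[gam] = x[gam[rng.permutation(gam.size)]]
        c = _components(*_sums_of_squares(x_within, pops), pop_sizes=sizes)
        if c["sigma"][1] >= sigma_b:
            ge["between_samples_within_populations"] += 1

        # within individuals: gametes permuted across everything, Phi_IT
        x_all = x[rng.permutation(2 * n_ind)]
        c = _components(*_sums_of_squares(x_all, pops), pop_sizes=sizes)
        phi_it_p = _phi(*c["sigma"])[2]
        if np.isnan(phi_it_obs) or (np.isfinite(phi_it_p) and phi_it_p >= phi_it_obs):
            ge["within_samples"] += 1

    p_values = {level: (1 + ge[level]) / (1 + n_perm) for level in LEVELS}
    return _assemble(comp, ss, p_values=p_values, n_perm=n_perm, seed=seed)
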