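"""Per-accession diversity statistics from SNP dosage data.

Observed heterozygosity (fraction of heterozygous calls), Nei gene
diversity (expected heterozygosity 1 - p^2 - q^2 from within-accession
allele frequencies), Shannon diversity H' in bits, and the rare-allele
inventory (loci whose within-accession minor-allele frequency falls in
(0, 0.05]).

Shannon H' for biallelic SNPs is ambiguous about aggregation, so two modes
are provided and tagged in the output: ``allele_mean`` averages the
per-locus allele entropy -sum_a p_a log2 p_a over loci (bounded by 1 bit
per biallelic locus), while ``multilocus_genotype`` takes the entropy of
the frequency distribution of distinct multilocus genotype strings among
the accession's plants (bounded by log2 n).  Neither is claimed to
reproduce any particular published aggregation.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, allele_frequencies


def _accession_freqs(g: GenotypeMatrix, accession: str) -> tuple[np.ndarray, np.ndarray]:
    """(alt frequency, called-individual count) per locus within an accession."""
    rows = g.individuals_of(accession)
    sub = g.genotypes[rows]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
    return p, n_called


def heterozygosity(
    g: GenotypeMatrix, accession: str, unbiased: bool = False
) -> tuple[float, float]:
    """(H_obs, H_exp) for one accession.

    H_obs is the fraction of non-missing calls that are heterozygous,
    averaged over loci with calls.  H_exp is the mean over those loci of
    1 - p^2 - q^2 from within-accession allele frequencies; ``unbiased``
    applies Nei's small-sample correction 2n/(2n-1) per locus.
    """
    rows = g.individuals_of(accession)
    sub = g.genotypes[rows]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    ok = n_called > 0
    if not ok.any():
        raise ValueError(f"accession {accession!r} has no genotype calls")
    h_obs_l = np.where(ok, (sub == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    p, _ = _accession_freqs(g, accession)
    h_exp_l = 2.0 * p * (1.0 - p)
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = 2 * n_called / np.maximum(2 * n_called - 1, 1)
        h_exp_l = h_exp_l * np.where(n_called > 0, corr, np.nan)
    return float(np.nanmean(h_obs_l)), float(np.nanmean(h_exp_l))


def shannon_diversity(
    g: GenotypeMatrix,
    accession: str,
    mode: Literal["allele_mean", "multilocus_genotype"] = "allele_mean",
) -> float:
    """Shannon diversity H' (base 2) of one accession; see module docstring."""
    if mode == "allele_mean":
        p, n_called = _accession_freqs(g, accession)
        ok = np.isfinite(p)
        if not ok.any():
            raise ValueError(f"accession {accession!r} has no genotype calls")
        p = p[ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            h = -(np.where(p > 0, p * np.log2(p), 0.0)
                  + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
        return float(np.mean(h))
    if mode == "multilocus_genotype":
        rows = g.individuals_of(accession)
        strings = ["".join("." if v == MISSING else str(v) for v in row)
                   for row in g.genotypes[rows]]
        counts = pd.Series(strings).value_counts().to_numpy(dtype=float)
        freqs = counts / counts.sum()
        return float(-(freqs * np.log2(freqs)).sum())
    raise ValueError(f"unknown Shannon mode {mode!r}")


def rare_allele_count(
    g: GenotypeMatrix, accession: str, threshold: float = 0.05
) -> dict:
    """Loci whose within-accession minor-allele frequency is in (0, threshold].

    Monomorphic loci (MAF = 0) are excluded; loci with undefined
    frequencies (no calls) are excluded and counted separately.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("threshold must lie in (0, 0.5]")
    p, _ = _accession_freqs(g, accession)
    maf = np.minimum(p, 1.0 - p)
    defined = np.isfinite(maf)
    rare = defined & (maf > 0) & (maf <= threshold)
    return {
        "count": int(rare.sum()),
        "n_undefined": int((~defined).sum()),
        "threshold": threshold,
    }


def polymorphic_count(g: GenotypeMatrix, accession: str) -> int:
    p, _ = _accession_freqs(g, accession)
    return int(((p > 0) & (p < 1)).sum())


def diversity_table(
    g: GenotypeMatrix,
    shannon_mode: Literal["allele_mean", "multilocus_genotype"] = "allele_mean",
    rare_threshold: float = 0.05,
    unbiased: bool = False,
) -> pd.DataFrame:
    """Per-accession diversity summary (one row per accession).

    Columns: observed and expected heterozygosity, Shannon H' (with the mode
    recorded), rare-allele count and polymorphic-locus count.
    """
    rows = {}
    for acc in g.accession_names:
        h_obs, h_exp = heterozygosity(g, acc, unbiased=unbiased)
        rows[acc] = {
            "h_obs": h_obs,
            "h_exp": h_exp,
            "shannon": shannon_diversity(g, acc, mode=shannon_mode),
            "shannon_mode": shannon_mode,
            "n_rare_alleles": rare_allele_count(g, acc, rare_threshold)["count"],
            "n_polymorphic": polymorphic_count(g, acc),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "accession"
    return table
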