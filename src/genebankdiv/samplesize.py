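"""Allele-retention probabilities and regeneration sample sizes (Crossa).

During genebank regeneration, small samples lose rare alleles to genetic
drift.  For the rarest biallelic SNP in an accession, with allele
frequencies p1 and p2 = 1 - p1, the probability that a sample of n gametes
contains at least one copy of each allele is

    P(n) = 1 - (1 - p1)^n - (1 - p2)^n .

The minimum regeneration sample size is the smallest integer n with
P(n) >= confidence (default 0.95), evaluated at the accession's rarest
nonzero minor-allele frequency.  n is reported on the gamete scale
("seeds", as these tables conventionally print it); an optional diploid
view ceil(n/2) supports comparison with FAO-style individual counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, allele_frequencies
from .diversity import rare_allele_count


def retention_probability(p1: float, n: int) -> float:
    """P(both alleles of a biallelic locus appear in n sampled gametes).

    Uses the inclusion-exclusion form P = 1 - (1-p1)^n - (1-p2)^n with
    p2 = 1 - p1; for n = 1 this is 0 (one gamete cannot carry both
    alleles) and for tiny n with extreme p1 it can be slightly negative,
    which is reported verbatim.
    """
    if not 0.0 < p1 < 1.0:
        raise ValueError("p1 must lie in (0, 1)")
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    p2 = 1.0 - p1
    return 1.0 - (1.0 - p1) ** n - (1.0 - p2) ** n


def min_sample_size(p_min: float, confidence: float = 0.95) -> int:
    """Smallest gamete count n with retention_probability(p_min, n) >= confidence.

    A closed-form guess n ~ ln(1 - confidence) / ln(1 - p_min) seeds a
    local integer scan verified against the exact formula.
    """
    if not 0.0 < p_min <= 0.5:
        raise ValueError("p_min must lie in (0, 0.5]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    guess = max(1, math.ceil(math.log(1.0 - confidence) / math.log(1.0 - p_min)))
    n = guess
    while n > 1 and retention_probability(p_min, n - 1) >= confidence:
        n -= 1
    while retention_probability(p_min, n) < confidence:
        n += 1
    return n


def min_diploid_individuals(p_min: float, confidence: float = 0.95) -> int:
    """Diploid-individual view: ceil(n_gametes / 2) at two gametes per plant."""
    return math.ceil(min_sample_size(p_min, confidence) / 2)


@dataclass
class SampleSizeResult:
    """Per-accession rarest allele frequency and minimum regeneration size."""

    table: pd.DataFrame  # index accession; p_min, n_min, n_diploid, n_rare_alleles
    confidence: float

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def accession_sample_sizes(
    g: GenotypeMatrix, confidence: float = 0.95, rare_threshold: float = 0.05
) -> SampleSizeResult:
    """Minimum sample size per accession from its rarest SNP allele.

    p_min is the smallest folded minor-allele frequency in (0, 0.5] over
    all loci within the accession (frequencies computed on called
    gametes); accessions monomorphic at every locus are flagged with
    undefined p_min and no n_min.
    """
    freqs = allele_frequencies(g, scope="per_accession")
    rows = {}
    for acc in g.accession_names:
        p = freqs[acc].to_numpy(dtype=float)
        maf = np.minimum(p, 1.0 - p)
        maf = maf[np.isfinite(maf) & (maf > 0)]
        rare = rare_allele_count(g, acc, threshold=rare_threshold)
        if maf.size == 0:
            rows[acc] = {"p_min": np.nan, "n_min": np.nan, "n_diploid": np.nan,
                         "n_rare_alleles": rare["count"], "monomorphic": True}
            continue
        p_min = float(maf.min())
        n_min = min_sample_size(p_min, confidence)
        rows[acc] = {
            "p_min": p_min,
            "n_min": n_min,
            "n_diploid": math.ceil(n_min / 2),
            "n_rare_alleles": rare["count"],
            "monomorphic": False,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "accession"
    return SampleSizeResult(table, confidence)


def sample_size_curve(p_grid, confidence: float = 0.95) -> pd.DataFrame:
    """Minimum sample size over a grid of allele frequencies.

    The curve is monotone non-increasing in p and grows superlinearly once
    the rare-allele frequency drops below ~0.1, which is why accessions
    carrying very rare variants need disproportionately large regeneration
    samples.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if ((p_grid <= 0) | (p_grid > 0.5)).any():
        raise ValueError("grid frequencies must lie in (0, 0.5]")
    return pd.DataFrame({
        "p": p_grid,
        "n_min": [min_sample_size(float(p), confidence) for p in p_grid],
    })
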