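"""Mixed-mating synthetic collections for diversity-analysis testing.

Generates accession collections with the statistical structure the
downstream analyses assume: differentiated accessions (Balding-Nichols
founder frequencies around a shared ancestral frequency), within-accession
structure governed by the outcrossing rate ``t`` (each offspring is produced
by selfing with probability ``s = 1 - t``, otherwise from two random
parents), and mixed quantitative/qualitative phenotypes with configurable
heritability.

The defaults describe a genebank study of landrace accessions: 36
accessions of 15 diploid plants each, thousands of biallelic loci spread
over ~10 chromosomes.  The three crops anchoring the outcrossing rates are
pearl millet (t ~ 0.85), pigeonpea (t ~ 0.30) and sorghum (t ~ 0.18).

Loci are unlinked; every statistic computed downstream is single-locus or a
sum over loci, so linkage would not change any expectation we test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PhenotypeTable, QUANTITATIVE, QUALITATIVE


@dataclass
class PhenotypeConfig:
    """Trait block: additive causal loci plus Gaussian noise.

    ``heritability`` is the fraction of trait variance explained by the
    additive genetic values (narrow-sense h^2).  Qualitative traits are
    liabilities thresholded into ``n_classes`` groups at quantiles.
    """

    n_quantitative: int = 5
    n_qualitative: int = 3
    n_causal_loci: int = 25
    heritability: float = 0.6
    n_classes: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if not 2 <= self.n_classes <= 5:
            raise ValueError("qualitative traits use 2-5 classes")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic genebank collection.

    Defaults emulate a sorghum-like study: 36 accessions x 15 plants,
    5,000 DArTSeq-scale biallelic loci over 10 chromosomes, outcrossing
    rate 0.18, founder differentiation F_ST 0.30, accessions evolved for 30
    non-overlapping generations at effective size 100.
    """

    n_accessions: int = 36
    plants_per_accession: int = 15
    n_loci: int = 5000
    n_chromosomes: int = 10
    chromosome_length_bp: int = 60_000_000
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    fst_target: float = 0.30
    outcrossing_rate: float = 0.18
    generations: int = 30
    effective_size: int = 100
    missing_rate: float = 0.05
    seed: int = 0
    phenotypes: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    swap_fraction: float = 0.0  # fraction of plants relabelled across accessions

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.n_loci < 1:
            raise ValueError("need at least one accession and one locus")
        for name, v, lo, hi in (
            ("fst_target", self.fst_target, 0.0, 1.0 - 1e-12),
            ("outcrossing_rate", self.outcrossing_rate, 0.0, 1.0),
            ("missing_rate", self.missing_rate, 0.0, 1.0 - 1e-12),
            ("swap_fraction", self.swap_fraction, 0.0, 1.0),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name} out of range: {v}")
        if self.generations < 0 or self.effective_size < 2:
            raise ValueError("generations >= 0 and effective_size >= 2 required")
        if self.plants_per_accession > self.effective_size:
            raise ValueError("cannot sample more plants than the accession holds")
        lo, hi = self.founder_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("founder frequency range must lie inside (0, 1)")
        if isinstance(self.phenotypes, dict):
            self.phenotypes = PhenotypeConfig(**self.phenotypes)


def sorghum_like(**overrides) -> SimulationConfig:
    """Often-selfing crop: t = 0.18, 15 plants per accession."""
    return SimulationConfig(**{"outcrossing_rate": 0.18, "plants_per_accession": 15, **overrides})


def pigeonpea_like(**overrides) -> SimulationConfig:
    """Intermediate outcrosser: t = 0.30, 15 plants per accession."""
    return SimulationConfig(**{"outcrossing_rate": 0.30, "plants_per_accession": 15, **overrides})


def pearl_millet_like(**overrides) -> SimulationConfig:
    """Highly cross-pollinated crop: t = 0.85, 25 plants per accession."""
    return SimulationConfig(**{"outcrossing_rate": 0.85, "plants_per_accession": 25, **overrides})


def expected_equilibrium_inbreeding(t: float) -> float:
    """Equilibrium inbreeding coefficient under mixed mating.

    With selfing rate ``s = 1 - t`` the recursion F' = s (1 + F) / 2 has the
    fixed point F* = s / (2 - s): 0 under full outcrossing, 1 under full
    selfing.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("outcrossing rate must lie in [0, 1]")
    s = 1.0 - t
    return s / (2.0 - s)


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def _gametes(pop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of a dosage-coded population (binary alleles)."""
    het = pop == 1
    g = (pop == 2).astype(np.int8)
    g[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return g


def _evolve_accession(
    founder_freq: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Found at Hardy-Weinberg, then G generations of mixed mating."""
    n, s = cfg.effective_size, 1.0 - cfg.outcrossing_rate
    pop = rng.binomial(2, founder_freq, size=(n, founder_freq.size)).astype(np.int8)
    for _ in range(cfg.generations):
        p1 = rng.integers(0, n, size=n)
        selfed = rng.random(n) < s
        p2 = np.where(selfed, p1, rng.integers(0, n, size=n))
        pop = _gametes(pop[p1], rng) + _gametes(pop[p2], rng)
    return pop


def _realized_inbreeding(pop: np.ndarray) -> float:
    """F-hat = 1 - sum(H_obs) / sum(H_exp) over polymorphic loci.

    H_exp uses the current population allele frequencies with the 2n/(2n-1)
    small-sample correction, so drift to intermediate frequencies does not
    bias the estimate.
    """
    n = pop.shape[0]
    p = pop.mean(axis=0) / 2.0
    h_obs = (pop == 1).mean(axis=0)
    h_exp = 2.0 * p * (1.0 - p) * (2 * n / (2 * n - 1))
    denom = h_exp.sum()
    if denom <= 0:
        return 1.0
    return float(1.0 - h_obs.sum() / denom)


def simulate_collection(cfg: SimulationConfig) -> tuple[GenotypeMatrix, dict]:
    """Simulate a genotyped collection; returns the matrix plus a truth record.

    Per locus, an ancestral frequency p is drawn uniformly from
    ``founder_freq_range``; each accession's founder frequency comes from a
    Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) law at F = ``fst_target``
    (all founders share p when F = 0).  Accessions then drift for
    ``generations`` generations of mixed mating at size ``effective_size``,
    and ``plants_per_accession`` plants are sampled without replacement.
    Missing calls are injected uniformly at ``missing_rate``.

    The truth record stores ancestral and founder frequencies and the
    realized inbreeding coefficient of each accession's full population.
    Bit-identical output for equal seeds; per-accession substreams are
    derived so that growing ``n_accessions`` leaves earlier accessions
    unchanged.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(2 + cfg.n_accessions)
    rng_loci = np.random.default_rng(streams[0])

    lo, hi = cfg.founder_freq_range
    ancestral = rng_loci.uniform(lo, hi, size=cfg.n_loci)
    chroms = np.array([f"chr{1 + i % cfg.n_chromosomes}" for i in range(cfg.n_loci)])
    positions = np.sort(
        rng_loci.integers(1, cfg.chromosome_length_bp + 1, size=cfg.n_loci)
    ) if cfg.n_chromosomes == 1 else _positions_by_chrom(chroms, cfg, rng_loci)
    loci = pd.DataFrame({
        "chromosome": chroms,
        "position": positions,
    }, index=pd.Index([f"L{i:06d}" for i in range(cfg.n_loci)], name="locus_id"))

    genotypes, ids, accs = [], [], []
    founder_freqs, inbreeding = {}, {}
    for a in range(cfg.n_accessions):
        rng = np.random.default_rng(streams[2 + a])
        name = f"ACC{a + 1:03d}"
        if cfg.fst_target > 0:
            f = cfg.fst_target
            alpha = ancestral * (1 - f) / f
            beta = (1 - ancestral) * (1 - f) / f
            founder = rng.beta(alpha, beta)
        else:
            founder = ancestral.copy()
        pop = _evolve_accession(founder, cfg, rng)
        inbreeding[name] = _realized_inbreeding(pop)
        take = rng.choice(cfg.effective_size, size=cfg.plants_per_accession, replace=False)
        sample = pop[take].copy()
        if cfg.missing_rate > 0:
            miss = rng.random(sample.shape) < cfg.missing_rate
            sample[miss] = MISSING
        genotypes.append(sample)
        ids.extend(f"{name}_P{j + 1:02d}" for j in range(cfg.plants_per_accession))
        accs.extend([name] * cfg.plants_per_accession)
        founder_freqs[name] = founder.tolist()

    accs = np.array(accs, dtype=object)
    if cfg.swap_fraction > 0 and cfg.n_accessions > 1:
        rng_swap = np.random.default_rng(streams[1].spawn(1)[0])
        n_swap = int(round(cfg.swap_fraction * len(accs)))
        pick = rng_swap.choice(len(accs), size=n_swap, replace=False)
        pool = list(pd.unique(accs))
        for i in pick:
            others = [x for x in pool if x != accs[i]]
            accs[i] = others[rng_swap.integers(0, len(others))]

    gm = GenotypeMatrix(np.vstack(genotypes), np.array(ids, dtype=object), accs, loci)
    truth = {
        "seed": cfg.seed,
        "ancestral_freq": ancestral.tolist(),
        "founder_freq": founder_freqs,
        "realized_inbreeding": inbreeding,
        "expected_equilibrium_inbreeding": expected_equilibrium_inbreeding(cfg.outcrossing_rate),
        "config": {**asdict(cfg), "founder_freq_range": list(cfg.founder_freq_range)},
    }
    return gm, truth


def _positions_by_chrom(chroms, cfg, rng) -> np.ndarray:
    pos = np.empty(len(chroms), dtype=np.int64)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        pos[idx] = np.sort(rng.integers(1, cfg.chromosome_length_bp + 1, size=idx.size))
    return pos


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    g: GenotypeMatrix, cfg: SimulationConfig | PhenotypeConfig, seed: int | None = None
) -> PhenotypeTable:
    """Additive quantitative traits plus thresholded qualitative traits.

    Each trait picks ``n_causal_loci`` loci and i.i.d. standard-normal
    effects; the genetic value is the dosage-weighted sum (missing dosage
    replaced by the locus mean).  Noise variance is set from the realized
    genetic variance so the trait's h^2 matches the configuration.  At
    h^2 = 0 the trait is pure noise; at h^2 = 1 it is noise-free.
    Qualitative traits threshold a liability at quantiles into
    ``n_classes`` classes.
    """
    if isinstance(cfg, SimulationConfig):
        pheno, base_seed = cfg.phenotypes, cfg.seed
    else:
        pheno, base_seed = cfg, 0
    if seed is None:
        seed = base_seed
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(2)[1])

    dosage = g.genotypes.astype(float)
    dosage[g.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(dosage), np.nan, dosage), axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    filled = np.where(np.isnan(dosage), col_mean, dosage)

    def liability() -> np.ndarray:
        m = min(pheno.n_causal_loci, g.n_loci)
        loci_idx = rng.choice(g.n_loci, size=m, replace=False)
        effects = rng.standard_normal(m)
        genic = filled[:, loci_idx] @ effects
        h2 = pheno.heritability
        if h2 == 0:
            return rng.standard_normal(g.n_individuals)
        var_g = genic.var()
        if var_g == 0:
            return genic + rng.standard_normal(g.n_individuals)
        noise_sd = np.sqrt(var_g * (1 - h2) / h2) if h2 < 1 else 0.0
        return genic + noise_sd * rng.standard_normal(g.n_individuals)

    data = {}
    kinds = {}
    for q in range(pheno.n_quantitative):
        name = f"quant_{q + 1}"
        data[name] = liability()
        kinds[name] = QUANTITATIVE
    for q in range(pheno.n_qualitative):
        name = f"qual_{q + 1}"
        y = liability()
        edges = np.quantile(y, np.linspace(0, 1, pheno.n_classes + 1)[1:-1])
        classes = np.searchsorted(edges, y, side="right")
        data[name] = pd.Categorical([f"class_{c + 1}" for c in classes])
        kinds[name] = QUALITATIVE

    df = pd.DataFrame(data, index=pd.Index(g.individual_ids, name="individual_id"))
    return PhenotypeTable(df, g.accessions.copy(), kinds)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
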