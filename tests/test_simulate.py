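"""Mixed-mating simulator: equilibria, Hardy-Weinberg, phenotype contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genebankdiv import (
    MISSING, PhenotypeConfig, SimulationConfig, expected_equilibrium_inbreeding,
    heterozygosity, simulate_collection, simulate_phenotypes,
)
from conftest import make_gm


@pytest.mark.parametrize("t, expected", [
    (1.0, 0.0),
    (0.0, 1.0),
    (0.18, 0.82 / 1.18),
])
def test_equilibrium_inbreeding_fixed_point(t, expected):
    f = expected_equilibrium_inbreeding(t)
    assert f == pytest.approx(expected, abs=1e-12)
    # fixed point of F' = s(1+F)/2
    s = 1 - t
    assert s * (1 + f) / 2 == pytest.approx(f, abs=1e-12)


def test_full_selfing_drives_heterozygosity_to_zero():
    cfg = SimulationConfig(n_accessions=2, plants_per_accession=10, n_loci=150,
                           n_chromosomes=2, outcrossing_rate=0.0, generations=40,
                           effective_size=30, missing_rate=0.0, seed=5)
    g, _ = simulate_collection(cfg)
    h_obs = np.mean([heterozygosity(g, a)[0] for a in g.accession_names])
    assert h_obs < 0.01


def test_random_mating_matches_hardy_weinberg_at_founder_freqs():
    """At t = 1 (one generation, large N), genotype counts fit HW chi-square.

    Rejection rate at alpha = 0.01 should stay below 5% of loci.
    """
    cfg = SimulationConfig(n_accessions=3, plants_per_accession=200, n_loci=200,
                           n_chromosomes=2, outcrossing_rate=1.0, generations=1,
                           effective_size=200, fst_target=0.0, missing_rate=0.0,
                           founder_freq_range=(0.2, 0.8), seed=9)
    g, truth = simulate_collection(cfg)
    rejected = total = 0
    for acc in g.accession_names:
        p = np.array(truth["founder_freq"][acc])
        sub = g.genotypes[g.individuals_of(acc)]
        n = sub.shape[0]
        for l in range(g.n_loci):
            obs = np.bincount(sub[:, l], minlength=3)
            q = p[l]
            exp = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
            chi2 = ((obs - exp) ** 2 / exp).sum()
            total += 1
            if chi2 > stats.chi2.ppf(0.99, df=2):
                rejected += 1
    assert rejected / total < 0.05


def test_same_seed_bit_identical():
    cfg = SimulationConfig(n_accessions=2, plants_per_accession=5, n_loci=50,
                           n_chromosomes=2, generations=3, effective_size=20, seed=3)
    g1, t1 = simulate_collection(cfg)
    g2, t2 = simulate_collection(cfg)
    np.testing.assert_array_equal(g1.genotypes, g2.genotypes)
    assert t1["realized_inbreeding"] == t2["realized_inbreeding"]
    p1 = simulate_phenotypes(g1, cfg)
    p2 = simulate_phenotypes(g2, cfg)
    pd.testing.assert_frame_equal(p1.data, p2.data)


def test_growing_accession_count_preserves_earlier_accessions():
    base = dict(plants_per_accession=5, n_loci=40, n_chromosomes=2,
                generations=3, effective_size=20, seed=8)
    g2, _ = simulate_collection(SimulationConfig(n_accessions=2, **base))
    g4, _ = simulate_collection(SimulationConfig(n_accessions=4, **base))
    np.testing.assert_array_equal(g4.genotypes[:10], g2.genotypes)


def test_founder_fst_recovers_target():
    """Weir-Cockerham-style F_ST over founder frequencies ~ target within 3 SE."""
    cfg = SimulationConfig(n_accessions=30, plants_per_accession=2, n_loci=400,
                           n_chromosomes=2, generations=0, effective_size=50,
                           fst_target=0.25, missing_rate=0.0, seed=17)
    _, truth = simulate_collection(cfg)
    anc = np.array(truth["ancestral_freq"])
    founders = np.array([truth["founder_freq"][a] for a in truth["founder_freq"]])
    # Balding-Nichols: Var(p_acc) = F p (1-p) per locus
    fst_hat = (founders.var(axis=0, ddof=1) / (anc * (1 - anc)))
    se = fst_hat.std(ddof=1) / np.sqrt(fst_hat.size)
    assert abs(fst_hat.mean() - 0.25) < 3 * se + 0.01


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _tiny_gm_with_duplicates():
    codes = [[0, 1, 2, 0], [0, 1, 2, 0], [2, 0, 1, 2], [1, 2, 0, 1]]
    return make_gm(codes, ["a", "a", "a", "a"])


def test_h2_one_is_noise_free():
    g = _tiny_gm_with_duplicates()
    cfg = PhenotypeConfig(n_quantitative=2, n_qualitative=0, n_causal_loci=4,
                          heritability=1.0)
    tab = simulate_phenotypes(g, cfg, seed=1)
    for col in tab.data.columns:
        assert tab.data[col].iloc[0] == tab.data[col].iloc[1]  # identical genotypes


def test_h2_zero_trait_uncorrelated_with_genotype():
    cfg = SimulationConfig(n_accessions=1, plants_per_accession=300, n_loci=100,
                           n_chromosomes=2, outcrossing_rate=1.0, generations=0,
                           effective_size=300, missing_rate=0.0, seed=12,
                           phenotypes=PhenotypeConfig(n_quantitative=3, n_qualitative=0,
                                                      heritability=0.0))
    g, _ = simulate_collection(cfg)
    tab = simulate_phenotypes(g, cfg)
    dosage_sum = g.genotypes.sum(axis=1).astype(float)
    n = g.n_individuals
    for col in tab.data.columns:
        r = np.corrcoef(tab.data[col], dosage_sum)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)


def test_qualitative_quantile_classes_balanced():
    cfg = SimulationConfig(n_accessions=1, plants_per_accession=300, n_loci=60,
                           n_chromosomes=2, outcrossing_rate=1.0, generations=0,
                           effective_size=300, missing_rate=0.0, seed=13,
                           phenotypes=PhenotypeConfig(n_quantitative=0, n_qualitative=1,
                                                      n_classes=3, heritability=0.5))
    g, _ = simulate_collection(cfg)
    tab = simulate_phenotypes(g, cfg)
    counts = tab.data["qual_1"].value_counts()
    assert len(counts) == 3
    assert all(abs(c - 100) <= 2 for c in counts)  # ties only


def test_degenerate_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_accessions=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_loci=0)
    with pytest.raises(ValueError):
        PhenotypeConfig(heritability=1.5)
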