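import numpy as np
import pandas as pd
import pytest

from genebankdiv import GenotypeMatrix, SimulationConfig, simulate_collection


def make_gm(codes, accessions, chrom=None, pos=None, **locus_cols) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix from a nested list of dosage codes."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    loci = pd.DataFrame({
        "chromosome": chrom if chrom is not None else ["chr1"] * m,
        "position": pos if pos is not None else list(range(1, m + 1)),
        **locus_cols,
    }, index=pd.Index([f"L{j}" for j in range(m)], name="locus_id"))
    ids = np.array([f"ind{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(codes, ids, np.asarray(accessions, dtype=object), loci)


@pytest.fixture(scope="session")
def small_collection():
    """A 4-accession, 32-plant, 120-locus simulated collection with truth."""
    cfg = SimulationConfig(
        n_accessions=4, plants_per_accession=8, n_loci=120, n_chromosomes=3,
        outcrossing_rate=0.3, generations=8, effective_size=40,
        missing_rate=0.05, seed=42,
    )
    return simulate_collection(cfg)


@pytest.fixture(scope="session")
def small_genotypes(small_collection):
    return small_collection[0]
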