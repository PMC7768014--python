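"""Modified Rogers and Gower distances against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from genebankdiv import (
    MISSING, PhenotypeTable, accession_distance_summary,
    distance_density_overlap, gower_pairwise, mrd_pairwise,
    within_between_pairs,
)
from conftest import make_gm


def mrd_oracle(codes):
    """Naive double loop over pairs and loci (pairwise-complete)."""
    codes = np.asarray(codes, dtype=float)
    n = codes.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = m = 0.0
            for l in range(codes.shape[1]):
                if codes[i, l] != MISSING and codes[j, l] != MISSING:
                    m += 1
                    num += (codes[i, l] / 2 - codes[j, l] / 2) ** 2
            d[i, j] = np.sqrt(num / m) if m else np.nan
    np.fill_diagonal(d, 0.0)
    return d


@pytest.mark.parametrize("codes, expected", [
    ([[0], [2]], 1.0),                       # maximal at one locus
    ([[0], [1]], 0.5),                       # half-step
    ([[0, 0], [2, 1]], np.sqrt(0.625)),      # (1 + 0.25) / 2
])
def test_mrd_single_pair_values(codes, expected):
    d = mrd_pairwise(make_gm(codes, ["a", "a"]))
    assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)


def test_mrd_matches_bruteforce_with_missing():
    rng = np.random.default_rng(4)
    codes = rng.integers(0, 3, size=(10, 20))
    codes[rng.random(codes.shape) < 0.15] = MISSING
    g = make_gm(codes, ["a"] * 5 + ["b"] * 5)
    d = mrd_pairwise(g)
    np.testing.assert_allclose(d.values, mrd_oracle(codes), atol=1e-12)


def test_mrd_undefined_pair_flagged():
    codes = [[0, MISSING], [MISSING, 2], [1, 1]]
    d = mrd_pairwise(make_gm(codes, ["a", "a", "a"]))
    assert np.isnan(d.values[0, 1]) and d.undefined_pairs[0, 1]
    assert np.isfinite(d.values[0, 2])


def test_mrd_monomorphic_locus_rescaling():
    """Dropping a fully-called monomorphic locus rescales d by sqrt(m/(m-1))."""
    rng = np.random.default_rng(6)
    codes = rng.integers(0, 3, size=(6, 10))
    codes[:, 0] = 0  # monomorphic, fully called
    g_full = make_gm(codes, ["a"] * 6)
    g_drop = make_gm(codes[:, 1:], ["a"] * 6)
    d_full = mrd_pairwise(g_full).values
    d_drop = mrd_pairwise(g_drop).values
    np.testing.assert_allclose(d_full * np.sqrt(10 / 9), d_drop, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_mrd_bounds_and_triangle_inequality(seed):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=(6, 12))
    d = mrd_pairwise(make_gm(codes, ["a"] * 6)).values
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
    for i in range(6):
        for j in range(6):
            for k in range(6):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


# ---------------------------------------------------------------------------
# Gower
# ---------------------------------------------------------------------------

def _pheno(values: dict, kinds: dict, accs) -> PhenotypeTable:
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(len(accs))])
    return PhenotypeTable(df, np.asarray(accs, dtype=object), kinds)


def test_gower_worked_examples():
    """|2-7|/10 = 0.5 alone; with a matching qualitative trait, (0.5+0)/2."""
    tab = _pheno({"h": [2.0, 7.0, 12.0]}, {"h": "quantitative"}, ["a", "a", "a"])
    d = gower_pairwise(tab)
    assert d.values[0, 1] == pytest.approx(0.5)

    tab2 = _pheno({"h": [2.0, 7.0, 12.0], "c": ["x", "x", "y"]},
                  {"h": "quantitative", "c": "qualitative"}, ["a", "a", "a"])
    d2 = gower_pairwise(tab2)
    assert d2.values[0, 1] == pytest.approx(0.25)
    assert d2.values[0, 0] == 0.0


def test_gower_matches_bruteforce_mixed_missing():
    rng = np.random.default_rng(11)
    n = 8
    q1 = rng.normal(size=n)
    q2 = rng.normal(size=n)
    q1[2] = np.nan
    c1 = rng.choice(["r", "g", "b"], size=n).astype(object)
    c1[5] = np.nan
    tab = _pheno({"q1": q1, "q2": q2, "c1": c1},
                 {"q1": "quantitative", "q2": "quantitative", "c1": "qualitative"},
                 ["a"] * n)
    d = gower_pairwise(tab).values
    r1 = np.nanmax(q1) - np.nanmin(q1)
    r2 = np.nanmax(q2) - np.nanmin(q2)
    for i in range(n):
        for j in range(n):
            parts = []
            if np.isfinite(q1[i]) and np.isfinite(q1[j]):
                parts.append(abs(q1[i] - q1[j]) / r1)
            if np.isfinite(q2[i]) and np.isfinite(q2[j]):
                parts.append(abs(q2[i] - q2[j]) / r2)
            if isinstance(c1[i], str) and isinstance(c1[j], str):
                parts.append(float(c1[i] != c1[j]))
            expected = np.mean(parts) if parts else (0.0 if i == j else np.nan)
            if np.isnan(expected):
                assert np.isnan(d[i, j])
            else:
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


def test_gower_zero_range_trait_skipped():
    tab = _pheno({"flat": [3.0, 3.0], "c": ["x", "y"]},
                 {"flat": "quantitative", "c": "qualitative"}, ["a", "a"])
    d = gower_pairwise(tab)
    assert d.values[0, 1] == 1.0  # only the qualitative mismatch counts


# ---------------------------------------------------------------------------
# Summaries and density overlap
# ---------------------------------------------------------------------------

def test_accession_summary_means_and_exclusions():
    # accession 'a' of 3 with pairwise {0.1, 0.2, 0.3} -> within mean 0.2
    vals = np.zeros((4, 4))
    vals[0, 1] = vals[1, 0] = 0.1
    vals[0, 2] = vals[2, 0] = 0.2
    vals[1, 2] = vals[2, 1] = 0.3
    for i in range(3):
        vals[i, 3] = vals[3, i] = 0.9
    from genebankdiv import GroupedDistanceMatrix
    d = GroupedDistanceMatrix(vals, np.full((4, 4), 5),
                              np.array([f"i{k}" for k in range(4)], dtype=object),
                              np.array(["a", "a", "a", "b"], dtype=object))
    s = accession_distance_summary(d)
    assert s.loc["a", "within_mean"] == pytest.approx(0.2)
    assert s.loc["a", "between_mean"] == pytest.approx(0.9)
    assert np.isnan(s.loc["b", "within_mean"])  # singleton accession
    assert s.loc["b", "between_mean"] == pytest.approx(0.9)


def test_fixed_opposite_accessions_within_zero_between_one():
    g = make_gm([[0, 0], [0, 0], [2, 2], [2, 2]], ["a", "a", "b", "b"])
    s = accession_distance_summary(mrd_pairwise(g))
    assert s.loc["a", "within_mean"] == 0.0
    assert s.loc["a", "between_mean"] == 1.0


def test_overlap_boundary_cases():
    within = np.full(200, 0.1)
    between = np.full(200, 0.9)
    assert distance_density_overlap((within, between)) == 0.0
    same = np.random.default_rng(0).uniform(0, 1, 500)
    assert distance_density_overlap((same, same)) == pytest.approx(1.0, abs=0.02)


def test_overlap_matches_quadrature_oracle():
    """Truncated-normal samples vs numeric integration of min(f1, f2)."""
    rng = np.random.default_rng(21)
    a1 = stats.truncnorm((0 - 0.2) / 0.05, (1 - 0.2) / 0.05, loc=0.2, scale=0.05)
    a2 = stats.truncnorm((0 - 0.25) / 0.05, (1 - 0.25) / 0.05, loc=0.25, scale=0.05)
    within = a1.rvs(10_000, random_state=rng)
    between = a2.rvs(10_000, random_state=rng)
    observed = distance_density_overlap((within, between), n_bins=50)
    grid = np.linspace(0, 1, 4001)
    expected = integrate.trapezoid(np.minimum(a1.pdf(grid), a2.pdf(grid)), grid)
    assert observed == pytest.approx(expected, abs=0.03)
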