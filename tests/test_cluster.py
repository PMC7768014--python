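"""Ward.D2 clustering, bootstrap stability and the Mantel test."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from genebankdiv import (
    GroupedDistanceMatrix, bootstrap_stability, mantel_test,
    membership_table, mrd_pairwise, ward_cluster,
)
from conftest import make_gm


def _gdm(points, accs):
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    d = d / max(d.max(), 1e-9)
    n = len(points)
    return GroupedDistanceMatrix(d, np.full((n, n), 1),
                                 np.array([f"i{k}" for k in range(n)], dtype=object),
                                 np.asarray(accs, dtype=object))


def ward_d2_oracle(d):
    """From-scratch Lance-Williams agglomeration on squared dissimilarities.

    Returns merge heights on the distance scale (sqrt of the criterion),
    non-decreasing, as the ward.D2 variant defines them.
    """
    d2 = d.astype(float) ** 2
    active = list(range(len(d)))
    sizes = {i: 1 for i in active}
    store = {(min(i, j), max(i, j)): d2[i, j] for i in active for j in active if i < j}
    heights = []
    nxt = len(d)
    while len(active) > 1:
        (i, j), best = min(store.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(best))
        ni, nj = sizes[i], sizes[j]
        new = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = store[(min(i, k), max(i, k))]
            djk = store[(min(j, k), max(j, k))]
            new[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * best) / (ni + nj + nk)
        active = [a for a in active if a not in (i, j)]
        store = {(a, b): v for (a, b), v in store.items()
                 if a not in (i, j) and b not in (i, j)}
        for k, v in new.items():
            store[(min(k, nxt), max(k, nxt))] = v
        sizes[nxt] = ni + nj
        active.append(nxt)
        nxt += 1
    return np.array(heights)


def test_two_tight_pairs_recovered():
    pts = np.array([[0, 0], [0.01, 0], [5, 5], [5, 5.01]])
    c = ward_cluster(_gdm(pts, ["a"] * 4), k=2)
    assert c.labels[0] == c.labels[1] and c.labels[2] == c.labels[3]
    assert c.labels[0] != c.labels[2]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_ward_heights_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(6, 3))
    d = _gdm(pts, ["a"] * 6)
    c = ward_cluster(d, k=2)
    np.testing.assert_allclose(np.sort(c.heights), np.sort(ward_d2_oracle(d.values)),
                               atol=1e-10)


def test_ward_heights_monotone_and_k_equals_n(small_genotypes):
    d = mrd_pairwise(small_genotypes)
    c = ward_cluster(d, k=4)
    assert (np.diff(c.heights) >= -1e-12).all()
    c_n = ward_cluster(d, k=d.n_individuals)
    assert len(np.unique(c_n.labels)) == d.n_individuals


def test_ward_rejects_undefined_pairs():
    vals = np.zeros((3, 3))
    counts = np.ones((3, 3), dtype=int)
    counts[0, 1] = counts[1, 0] = 0
    vals[0, 1] = vals[1, 0] = np.nan
    vals[0, 2] = vals[2, 0] = vals[1, 2] = vals[2, 1] = 0.5
    d = GroupedDistanceMatrix(vals, counts, np.array(["a", "b", "c"], dtype=object),
                              np.array(["x", "x", "x"], dtype=object))
    with pytest.raises(ValueError, match="undefined"):
        ward_cluster(d, 2)


def test_membership_rows_sum_to_100_and_split_fractions():
    """An accession split 58/139 across two clusters -> 29.4% / 70.6%."""
    labels_acc = ["accX"] * 197 + ["accY"] * 50
    rng = np.random.default_rng(1)
    pts = np.concatenate([
        rng.normal(0, 0.05, size=(58, 2)),          # accX part 1
        rng.normal([3, 0], 0.05, size=(139, 2)),     # accX part 2
        rng.normal([0, 5], 0.05, size=(50, 2)),      # accY
    ])
    d = _gdm(pts, labels_acc)
    c = ward_cluster(d, k=3)
    table, pure = membership_table(c)
    np.testing.assert_allclose(table.sum(axis=1), 100.0, atol=1e-9)
    row = np.sort(table.loc["accX"][table.loc["accX"] > 0].to_numpy())
    np.testing.assert_allclose(row, [100 * 58 / 197, 100 * 139 / 197], atol=1e-6)
    assert pure == 1  # accY forms a pure singleton cluster


def test_pure_accession_count_identity_case(small_genotypes):
    d = mrd_pairwise(small_genotypes)
    c = ward_cluster(d, k=4)
    table, pure = membership_table(c)
    assert 0 <= pure <= 4
    np.testing.assert_allclose(table.sum(axis=1), 100.0, atol=1e-9)


# ---------------------------------------------------------------------------
# Bootstrap stability
# ---------------------------------------------------------------------------

def test_stability_separated_vs_noise_ordering():
    rng = np.random.default_rng(5)
    separated = np.concatenate([rng.normal(c, 0.05, size=(15, 2))
                                for c in ([0, 0], [4, 0], [0, 4], [4, 4])])
    noise = rng.normal(size=(60, 2))
    d_sep = _gdm(separated, ["a"] * 60)
    d_noise = _gdm(noise, ["a"] * 60)
    rep_sep = bootstrap_stability(d_sep, k=4, B=30, seed=2)
    rep_noise = bootstrap_stability(d_noise, k=4, B=30, seed=2)
    assert (rep_sep.table["mean_jaccard"] >= 0.95).all()
    assert rep_noise.table["mean_jaccard"].mean() < rep_sep.table["mean_jaccard"].mean()
    # determinism
    rep_again = bootstrap_stability(d_sep, k=4, B=30, seed=2)
    assert rep_sep.table.equals(rep_again.table)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def test_mantel_identity_and_zero_variance():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(12, 3))
    d = _gdm(pts, ["a"] * 12)
    r, p = mantel_test(d, d, n_perm=99, seed=1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(0.01)

    const = np.full((12, 12), 0.4)
    np.fill_diagonal(const, 0.0)
    r2, p2 = mantel_test(d.values, const, n_perm=9, seed=1)
    assert np.isnan(r2) and np.isnan(p2)


def test_mantel_r_matches_skbio():
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel
    rng = np.random.default_rng(14)
    a = _gdm(rng.normal(size=(15, 2)), ["a"] * 15)
    b_pts = rng.normal(size=(15, 2))
    b = _gdm(0.7 * rng.normal(size=(15, 2)) + 0.3 * b_pts, ["a"] * 15)
    r_ours, _ = mantel_test(a, b, n_perm=9, seed=0)
    r_ref, _, _ = skbio_mantel(DistanceMatrix(a.values), DistanceMatrix(b.values),
                               method="pearson", permutations=0)
    assert r_ours == pytest.approx(float(r_ref), abs=1e-12)


def test_mantel_invariant_to_monotone_affine_transform():
    rng = np.random.default_rng(15)
    a = _gdm(rng.normal(size=(10, 2)), ["a"] * 10)
    b = _gdm(rng.normal(size=(10, 2)), ["a"] * 10)
    r1, p1 = mantel_test(a.values, b.values, n_perm=99, seed=3)
    r2, p2 = mantel_test(a.values, 0.2 + 0.5 * b.values, n_perm=99, seed=3)
    assert r1 == pytest.approx(r2, abs=1e-12)
    assert p1 == p2


def test_mantel_dimension_mismatch():
    with pytest.raises(ValueError):
        mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))
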