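"""Mantel family, distance-decay, diffslope, PERMANOVA.

The brute-force oracles (exhaustive enumeration over all sample
relabelings / membership reshuffles) live here in the test suite, not in
the library, and are compared against the vectorized permutation
machinery.
"""

import itertools

import numpy as np
import pytest

from soilbeta.distances import DistanceMatrix
from soilbeta.matrix_stats import (
    decay_fit,
    decay_pairs,
    diffslope,
    mantel,
    partial_mantel,
    permanova,
)


def rand_dm(n, rng, kind="community"):
    M = rng.random((n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return DistanceMatrix(M, [f"s{i}" for i in range(n)], kind)


# ---------------------------------------------------------------------------
# exhaustive oracles
# ---------------------------------------------------------------------------

def exact_mantel_p(A, B, tail="greater"):
    n = A.n
    iu = np.triu_indices(n, 1)
    b = B.values[iu]

    def r_of(perm):
        Ap = A.values[np.ix_(perm, perm)]
        return np.corrcoef(Ap[iu], b)[0, 1]

    obs = r_of(tuple(range(n)))
    stats = np.array([r_of(p) for p in itertools.permutations(range(n))])
    if tail == "greater":
        return np.mean(stats >= obs - 1e-12)
    return np.mean(np.abs(stats) >= abs(obs) - 1e-12)


def exact_partial_mantel_p(A, B, C):
    n = A.n
    iu = np.triu_indices(n, 1)
    b, c = B.values[iu], C.values[iu]

    def resid(v, w):
        beta = np.cov(v, w)[0, 1] / np.var(w)
        return v - beta * w

    rb = resid(b, c)

    def stat(perm):
        a = A.values[np.ix_(perm, perm)][iu]
        return np.corrcoef(resid(a, c), rb)[0, 1]

    obs = stat(tuple(range(n)))
    stats = np.array([stat(p) for p in itertools.permutations(range(n))])
    return np.mean(stats >= obs - 1e-12)


def exact_permanova_p(D, codes):
    n = D.n
    D2 = D.values**2
    uniq = sorted(set(codes))

    def F(labels):
        labels = np.asarray(labels)
        ss_t = D2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for g in uniq:
            idx = np.where(labels == g)[0]
            ss_w += D2[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].sum() / idx.size
        g_ = len(uniq)
        return ((ss_t - ss_w) / (g_ - 1)) / (ss_w / (n - g_))

    obs = F(codes)
    stats = np.array([F(p) for p in set(itertools.permutations(codes))])
    return np.mean(stats >= obs - 1e-12)


def exact_diffslope_p(x1, y1, x2, y2):
    def slope(x, y):
        return np.polyfit(x, y, 1)[0]

    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    n1 = len(x1)
    obs = slope(x1, y1) - slope(x2, y2)
    stats = []
    for comb in itertools.combinations(range(len(x)), n1):
        idx1 = list(comb)
        idx2 = [i for i in range(len(x)) if i not in comb]
        stats.append(slope(x[idx1], y[idx1]) - slope(x[idx2], y[idx2]))
    stats = np.array(stats)
    return np.mean(np.abs(stats) >= abs(obs) - 1e-12)


def binom_3se(p, n=999):
    return 3 * np.sqrt(max(p, 1e-3) * (1 - min(p, 0.999)) / n)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def test_mantel_statistic_trivial_cases(rng):
    A = rand_dm(6, rng)
    assert mantel(A, A, n_perm=19, seed=0).statistic == pytest.approx(1.0)
    B = DistanceMatrix(2.5 * A.values + 0.0, A.ids, "community")
    assert mantel(A, B, n_perm=19, seed=0).statistic == pytest.approx(1.0)


def test_mantel_similarity_matrices_flip_to_dissimilarity(rng):
    """Community similarity decaying with distance tests as positive r."""
    A = rand_dm(6, rng, kind="geographic")
    sim = DistanceMatrix(1 - A.values / A.values.max(), A.ids, "community", "similarity")
    r = mantel(sim, A, n_perm=19, seed=0).statistic
    assert r == pytest.approx(1.0)


@pytest.mark.parametrize("n", [4, 5])
def test_mantel_p_matches_exhaustive_enumeration(n, rng):
    A, B = rand_dm(n, rng), rand_dm(n, rng)
    pe = exact_mantel_p(A, B)
    pp = mantel(A, B, n_perm=999, seed=1, tail="greater").p_value
    assert abs(pp - pe) <= binom_3se(pe) + 2 / 1000


def test_partial_mantel_p_matches_exhaustive_enumeration(rng):
    A, B, C = (rand_dm(5, rng) for _ in range(3))
    pe = exact_partial_mantel_p(A, B, C)
    pp = partial_mantel(A, B, C, n_perm=999, seed=2, tail="greater").p_value
    assert abs(pp - pe) <= binom_3se(pe) + 2 / 1000


def test_mantel_invariant_to_joint_relabeling(rng):
    A, B = rand_dm(7, rng), rand_dm(7, rng)
    r = mantel(A, B, n_perm=9, seed=0).statistic
    perm = rng.permutation(7)
    Ap = DistanceMatrix(A.values[np.ix_(perm, perm)], [A.ids[i] for i in perm], "community")
    Bp = DistanceMatrix(B.values[np.ix_(perm, perm)], [B.ids[i] for i in perm], "community")
    assert mantel(Ap, Bp, n_perm=9, seed=0).statistic == pytest.approx(r)


def test_mantel_agrees_with_skbio(rng):
    from skbio.stats.distance import DistanceMatrix as SkDM
    from skbio.stats.distance import mantel as sk_mantel

    A, B = rand_dm(8, rng), rand_dm(8, rng)
    r_sk = sk_mantel(SkDM(A.values, A.ids), SkDM(B.values, B.ids), permutations=0)[0]
    assert mantel(A, B, n_perm=9, seed=0).statistic == pytest.approx(r_sk, abs=1e-12)


def test_mantel_rejects_mismatched_or_degenerate(rng):
    A = rand_dm(5, rng)
    B = rand_dm(5, rng)
    B.ids[0] = "other"
    with pytest.raises(ValueError, match="aligned"):
        mantel(A, B)
    flat = DistanceMatrix(np.ones((5, 5)) - np.eye(5), A.ids, "community")
    with pytest.raises(ValueError, match="variance"):
        mantel(A, flat)


def test_partial_mantel_controls_irrelevant_matrix(rng):
    A = rand_dm(8, rng)
    C = DistanceMatrix(0.5 + 0.01 * rand_dm(8, rng).values, A.ids, "community")
    res = partial_mantel(A, A, C, n_perm=99, seed=0)
    assert res.statistic > 0.99


def test_partial_mantel_full_control_is_null(rng):
    """partial r of independent A vs B given C ~ B averages ~0 over replicates."""
    stats = []
    for i in range(200):
        r = np.random.default_rng(i)
        A, B = rand_dm(7, r), rand_dm(7, r)
        noise = rand_dm(7, r).values * 1e-3
        C = DistanceMatrix(B.values + noise, B.ids, "community")
        stats.append(partial_mantel(A, B, C, n_perm=9, seed=i).statistic)
    m = np.mean(stats)
    se = np.std(stats) / np.sqrt(len(stats))
    assert abs(m) <= 3 * se + 0.02


def test_partial_mantel_rejects_identical_control(rng):
    A, B = rand_dm(6, rng), rand_dm(6, rng)
    with pytest.raises(ValueError, match="partial correlation undefined"):
        partial_mantel(A, B, B, n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# decay
# ---------------------------------------------------------------------------

def test_two_point_decay_slope_is_minus_one_per_decade():
    geo = DistanceMatrix(np.array([[0.0, 1.0, 10.0],
                                   [1.0, 0.0, 9.0],
                                   [10.0, 9.0, 0.0]]), list("abc"), "geographic")
    # similarity 1 at d=1, 0 at d=10; the third pair lies on the same line
    sim_vals = {(0, 1): 1.0, (0, 2): 0.0, (1, 2): 1 - np.log10(9)}
    S = np.zeros((3, 3))
    for (i, j), v in sim_vals.items():
        S[i, j] = S[j, i] = v
    np.fill_diagonal(S, 1)
    sim = DistanceMatrix(1 - S, list("abc"), "community").to_similarity()
    x, y = decay_pairs(sim, geo)
    slope = np.polyfit(x, y, 1)[0]
    assert slope == pytest.approx(-1.0, abs=1e-9)


def test_decay_fit_null_slope_and_uniform_p():
    slopes, ps = [], []
    for i in range(200):
        r = np.random.default_rng(1000 + i)
        pts = r.uniform(0, 100, (7, 2))
        geo_v = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        geo = DistanceMatrix(geo_v, [f"s{k}" for k in range(7)], "geographic")
        sim = DistanceMatrix(1 - rand_dm(7, r).values, geo.ids, "community", "similarity")
        fit = decay_fit(sim, geo, n_perm=49, seed=i)
        slopes.append(fit.slope)
        ps.append(fit.mantel_p)
    assert abs(np.mean(slopes)) <= 3 * np.std(slopes) / np.sqrt(200)
    # p-values roughly uniform: mean near 0.5, tail mass near nominal
    assert 0.42 <= np.mean(ps) <= 0.58
    assert np.mean(np.array(ps) <= 0.1) <= 0.2


def test_decay_fit_significance_gates_trend_line(rng):
    geo_v = np.abs(np.subtract.outer(np.arange(1.0, 9.0), np.arange(1.0, 9.0)))
    geo = DistanceMatrix(geo_v, [f"s{i}" for i in range(8)], "geographic")
    sim = DistanceMatrix(1 - geo_v / 10, geo.ids, "community", "similarity")
    fit = decay_fit(sim, geo, log10_distance=False, n_perm=199, seed=0)
    assert fit.significant and fit.mantel_p < 0.05
    noise = DistanceMatrix(1 - rand_dm(8, rng).values, geo.ids, "community", "similarity")
    fit2 = decay_fit(noise, geo, log10_distance=False, n_perm=199, seed=0)
    assert fit2.significant == (fit2.mantel_p < 0.05)


# ---------------------------------------------------------------------------
# diffslope
# ---------------------------------------------------------------------------

def test_diffslope_identical_datasets_null(rng):
    x = rng.uniform(0, 2, 20)
    y = 0.5 - 0.1 * x + rng.normal(0, 0.01, 20)
    res = diffslope((x, y), (x, y), n_perm=199, seed=0)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value > 0.5


def test_diffslope_matches_exhaustive_enumeration(rng):
    x1, y1 = rng.uniform(0, 1, 4), rng.uniform(0, 1, 4)
    x2, y2 = rng.uniform(0, 1, 4), rng.uniform(0, 1, 4)
    pe = exact_diffslope_p(x1, y1, x2, y2)
    pp = diffslope((x1, y1), (x2, y2), n_perm=999, seed=3).p_value
    assert abs(pp - pe) <= binom_3se(pe) + 2 / 1000


def test_diffslope_power_on_distinct_slopes():
    """Slopes -0.05 vs 0.00 at n=78 pairs: detected in >=95% of runs."""
    hits = 0
    runs = 100
    for i in range(runs):
        r = np.random.default_rng(i)
        x1 = r.uniform(-1, 2.2, 78)
        x2 = r.uniform(-1, 2.2, 78)
        y1 = 0.4 - 0.05 * x1 + r.normal(0, 0.02, 78)
        y2 = 0.4 + 0.00 * x2 + r.normal(0, 0.02, 78)
        p = diffslope((x1, y1), (x2, y2), n_perm=199, seed=i).p_value
        hits += p <= 0.05
    assert hits >= 0.95 * runs


def test_diffslope_needs_three_pairs():
    with pytest.raises(ValueError):
        diffslope(([1, 2], [1, 2]), ([1, 2, 3], [1, 2, 3]))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def test_permanova_perfect_separation():
    n = 8
    M = np.ones((n, n))
    M[:4, :4] = 0
    M[4:, 4:] = 0
    np.fill_diagonal(M, 0)
    D = DistanceMatrix(M, [f"s{i}" for i in range(n)], "community")
    res = permanova(D, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
    # only label permutations recreating the same partition tie with the
    # observed F; everything else scores strictly lower
    assert res.p_value <= 0.05
    assert res.extra["R2"] > 0.9


def test_permanova_p_matches_exhaustive_enumeration(rng):
    D = rand_dm(5, rng)
    codes = ["a", "a", "b", "b", "b"]
    pe = exact_permanova_p(D, codes)
    pp = permanova(D, codes, n_perm=999, seed=4).p_value
    assert abs(pp - pe) <= binom_3se(pe) + 2 / 1000


def test_permanova_f_matches_skbio(rng):
    from skbio.stats.distance import DistanceMatrix as SkDM
    from skbio.stats.distance import permanova as sk_permanova

    D = rand_dm(9, rng)
    g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    mine = permanova(D, g, n_perm=9, seed=0)
    sk = sk_permanova(SkDM(D.values, D.ids), grouping=g, permutations=9)
    assert mine.statistic == pytest.approx(sk["test statistic"], rel=1e-10)


def test_permanova_r2_bounds_and_null_p(rng):
    """On genuine (Euclidean-embeddable) distances the sum-of-squares
    partition keeps R^2 in [0, 1]; null p is uniform on average."""
    ps = []
    for i in range(200):
        r = np.random.default_rng(i)
        pts = r.normal(size=(9, 3))
        D = DistanceMatrix(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)),
                           [f"s{k}" for k in range(9)], "community")
        res = permanova(D, ["a"] * 4 + ["b"] * 5, n_perm=49, seed=i)
        assert 0.0 <= res.extra["R2"] <= 1.0
        ps.append(res.p_value)
    assert 0.4 <= np.mean(ps) <= 0.6


def test_permanova_rejects_singleton_group(rng):
    D = rand_dm(5, rng)
    with pytest.raises(ValueError, match="fewer than 2"):
        permanova(D, ["a", "b", "b", "b", "b"])


def test_permutation_p_reproducible(rng):
    A, B = rand_dm(8, rng), rand_dm(8, rng)
    p1 = mantel(A, B, n_perm=99, seed=11).p_value
    p2 = mantel(A, B, n_perm=99, seed=11).p_value
    assert p1 == p2
    assert mantel(A, B, n_perm=99, seed=12).p_value != p1 or True  # seeds differ freely
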