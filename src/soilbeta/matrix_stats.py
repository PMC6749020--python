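"""Permutation inference on distance matrices.

Mantel and partial Mantel tests, distance-decay regression, the
slope-difference randomization, and PERMANOVA. All tests build their null
distributions by simultaneous row/column permutation of one matrix (or by
permuting group labels / pair-set membership) and report

    p = (number of permuted statistics at least as extreme + 1) / (n_perm + 1),

the add-one permutation p-value, which is exactly reproducible given a seed.
Permutations are generated and evaluated in vectorized batches, so
thousand-replicate calibration studies run in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .distances import DistanceMatrix

Tail = Literal["auto", "greater", "less", "two-sided"]


@dataclass
class PermTestResult:
    """Outcome of a permutation test."""

    statistic: float
    n_permutations: int
    p_value: float
    tail: str
    seed: int
    method: str = ""
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DecayFit:
    """Distance-decay regression of pairwise similarity on (log) distance."""

    slope: float
    intercept: float
    mantel_r: float
    mantel_p: float
    n_pairs: int
    predictor_transform: str
    seed: int

    @property
    def significant(self) -> bool:
        """Whether a trend line would be drawn (Mantel p < 0.05)."""
        return self.mantel_p < 0.05

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# permutation plumbing
# ---------------------------------------------------------------------------

def _check_aligned(*mats: DistanceMatrix, min_n: int = 4) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValueError("distance matrices are not aligned on the same samples")
    if mats[0].n < min_n:
        raise ValueError(f"need at least {min_n} samples")


def _as_dissimilarity_vec(m: DistanceMatrix) -> np.ndarray:
    """Condensed off-diagonal vector, with similarities flipped to
    dissimilarities so every Mantel correlates two dissimilarities."""
    return m.to_dissimilarity().condensed() if m.is_similarity else m.condensed()


def _pair_positions(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Square matrix mapping (i, j) -> condensed position, plus triu indices."""
    iu = np.triu_indices(n, 1)
    P = np.zeros((n, n), dtype=np.int64)
    P[iu] = np.arange(iu[0].size)
    P += P.T
    return P, iu[0], iu[1]


def _permuted_vectors(vec: np.ndarray, n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_pairs) matrix of condensed vectors under sample relabelings."""
    P, iu0, iu1 = _pair_positions(n)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    return vec[P[perms[:, iu0], perms[:, iu1]]]


def _pearson_rows(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of each row of A with b. Rows of A are permutations of one
    vector, so their mean and norm are constant."""
    bc = b - b.mean()
    ac = A - A.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1)) * np.sqrt((bc**2).sum())
    return (ac @ bc) / denom


def _perm_p(obs: float, null: np.ndarray, tail: Tail) -> tuple[float, str]:
    if tail == "auto":
        tail = "greater" if obs >= 0 else "less"
    n = null.size
    if tail == "greater":
        count = int((null >= obs - 1e-12).sum())
    elif tail == "less":
        count = int((null <= obs + 1e-12).sum())
    elif tail == "two-sided":
        count = int((np.abs(null) >= abs(obs) - 1e-12).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (count + 1) / (n + 1), tail


# ---------------------------------------------------------------------------
# Mantel family
# ---------------------------------------------------------------------------

def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 999,
    tail: Tail = "greater",
    seed: int = 0,
    method: str = "pearson",
) -> PermTestResult:
    """Mantel test of association between two distance matrices.

    The statistic is the Pearson (or Spearman) correlation over the
    n(n-1)/2 off-diagonal pairs; the null relabels the samples of ``A``.
    Similarity-tagged matrices are internally flipped to dissimilarities, so
    e.g. community similarity vs geographic distance tests as a *positive*
    Mantel r when similarity decays with distance. The default tail is the
    one-sided positive test in that converted orientation (the convention
    of the field's Mantel implementations, and the calibrated choice: a
    sign-adaptive tail roughly doubles the type-I error); ``auto`` follows
    the sign of the observed statistic instead.
    """
    _check_aligned(A, B)
    a = _as_dissimilarity_vec(A)
    b = _as_dissimilarity_vec(B)
    if method == "spearman":
        a = stats.rankdata(a)
        b = stats.rankdata(b)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in off-diagonal entries; Mantel undefined")
    rng = np.random.default_rng(seed)
    r_obs = float(_pearson_rows(a[None, :], b)[0])
    null = _pearson_rows(_permuted_vectors(a, A.n, n_perm, rng), b)
    p, used_tail = _perm_p(r_obs, null, tail)
    return PermTestResult(r_obs, n_perm, p, used_tail, seed, f"mantel-{method}")


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 999,
    tail: Tail = "greater",
    seed: int = 0,
    method: str = "pearson",
) -> PermTestResult:
    """Partial Mantel: correlation of A and B controlling for C.

    Computed as the correlation of the residuals of A~C with the residuals
    of B~C over off-diagonal pairs (equivalently the first-order partial
    correlation). The null permutes the raw first matrix.
    """
    _check_aligned(A, B, C)
    a = _as_dissimilarity_vec(A)
    b = _as_dissimilarity_vec(B)
    c = _as_dissimilarity_vec(C)
    if method == "spearman":
        a, b, c = stats.rankdata(a), stats.rankdata(b), stats.rankdata(c)
    for v, name in ((a, "A"), (b, "B"), (c, "C")):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in off-diagonal of {name}")
    rng = np.random.default_rng(seed)
    r_bc = float(_pearson_rows(b[None, :], c)[0])
    if 1 - r_bc**2 < 1e-12:
        raise ValueError("control matrix C explains B entirely; partial correlation undefined")

    def partial_r(r_ab: np.ndarray, r_ac: np.ndarray) -> np.ndarray:
        return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    r_obs = float(partial_r(_pearson_rows(a[None, :], b), _pearson_rows(a[None, :], c))[0])
    A_perm = _permuted_vectors(a, A.n, n_perm, rng)
    null = partial_r(_pearson_rows(A_perm, b), _pearson_rows(A_perm, c))
    p, used_tail = _perm_p(r_obs, null, tail)
    return PermTestResult(r_obs, n_perm, p, used_tail, seed, f"partial-mantel-{method}")


# ---------------------------------------------------------------------------
# Distance-decay
# ---------------------------------------------------------------------------

def decay_pairs(
    similarity: DistanceMatrix,
    predictor: DistanceMatrix,
    log10_distance: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) off-diagonal pair vectors for a decay regression.

    ``similarity`` must be similarity-tagged (bounded in [0, 1]).
    Geographic predictors are log10-transformed by default (the nested
    sampling design spans 0.1-141 m, three orders of magnitude); similarity
    predictors (e.g. environmental similarity) are used as-is.
    """
    _check_aligned(similarity, predictor, min_n=2)
    if not similarity.is_similarity:
        raise ValueError("response must be a similarity matrix (use .to_similarity())")
    y = similarity.condensed()
    if predictor.kind == "geographic" and log10_distance:
        x = predictor.log10().condensed()
    else:
        x = predictor.condensed()
    return x, y


def decay_fit(
    similarity: DistanceMatrix,
    predictor: DistanceMatrix,
    log10_distance: bool = True,
    n_perm: int = 999,
    seed: int = 0,
) -> DecayFit:
    """Distance-decay regression plus Mantel significance.

    OLS of pairwise similarity on (log10) predictor distance over the
    off-diagonal pairs gives the decay slope; the association's
    significance comes from a Mantel test on the untransformed matrices.
    A trend line is conventionally drawn only when Mantel p < 0.05
    (exposed as ``DecayFit.significant``).
    """
    x, y = decay_pairs(similarity, predictor, log10_distance)
    slope, intercept = np.polyfit(x, y, 1)
    mt = mantel(similarity, predictor, n_perm=n_perm, seed=seed)
    transform = "log10" if (predictor.kind == "geographic" and log10_distance) else "none"
    return DecayFit(
        slope=float(slope), intercept=float(intercept),
        mantel_r=mt.statistic, mantel_p=mt.p_value,
        n_pairs=y.size, predictor_transform=transform, seed=seed,
    )


def _slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise OLS slopes for stacked (R, n) pair sets."""
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    return (xc * yc).sum(axis=-1) / (xc**2).sum(axis=-1)


def diffslope(
    pairs1: tuple[np.ndarray, np.ndarray],
    pairs2: tuple[np.ndarray, np.ndarray],
    n_perm: int = 1000,
    tail: Tail = "two-sided",
    seed: int = 0,
) -> PermTestResult:
    """Randomization test for a difference between two decay slopes.

    The observed statistic is slope1 - slope2 of the two (distance,
    similarity) pair sets. The null shuffles pair-set membership between
    the datasets (keeping set sizes) and refits both slopes; the p-value is
    the add-one fraction of shuffles whose slope difference is at least as
    extreme as the observed one (two-sided on the absolute difference by
    default; one-sided tails available).
    """
    x1, y1 = np.asarray(pairs1[0], float), np.asarray(pairs1[1], float)
    x2, y2 = np.asarray(pairs2[0], float), np.asarray(pairs2[1], float)
    if x1.size < 3 or x2.size < 3:
        raise ValueError("need at least 3 pairs per dataset")
    n1 = x1.size
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    obs = float(_slopes(x1, y1) - _slopes(x2, y2))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x.size) for _ in range(n_perm)])
    xp, yp = x[perms], y[perms]
    null = _slopes(xp[:, :n1], yp[:, :n1]) - _slopes(xp[:, n1:], yp[:, n1:])
    p, used_tail = _perm_p(obs, null, tail)
    return PermTestResult(obs, n_perm, p, used_tail, seed, "diffslope",
                          extra={"slope1": float(_slopes(x1, y1)), "slope2": float(_slopes(x2, y2))})


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova(
    D: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> PermTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the sum of squared distances among and within groups:
    SS_total = sum_{i<j} d_ij^2 / n, SS_within = sum_g sum_{i<j in g}
    d_ij^2 / n_g, pseudo-F = (SS_among/(g-1)) / (SS_within/(n-g)),
    R^2 = SS_among/SS_total. The null permutes group labels.
    """
    if D.is_similarity:
        D = D.to_dissimilarity()
    labels = np.asarray([str(g) for g in groups])
    if labels.size != D.n:
        raise ValueError("one group label per sample required")
    uniq, codes = np.unique(labels, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"groups with fewer than 2 samples: {list(small)}")
    n = D.n
    D2 = D.values**2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n

    rng = np.random.default_rng(seed)
    perms = np.vstack([codes] + [rng.permutation(codes) for _ in range(n_perm)])
    # one-hot (R, n, g); within-group pair sums via v^T D2 v per group
    F = np.empty(perms.shape[0])
    ss_within_all = np.zeros(perms.shape[0])
    for gi in range(g):
        V = (perms == gi).astype(float)  # (R, n)
        pair_sums = np.einsum("rn,nm,rm->r", V, D2, V) / 2.0
        ss_within_all += pair_sums / counts[gi]
    ss_among = ss_total - ss_within_all
    # perfect within-group identity gives SS_within = 0 and an infinite F
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_among / (g - 1)) / (ss_within_all / (n - g))
    obs = float(F[0])
    p, _ = _perm_p(obs, F[1:], "greater")
    return PermTestResult(
        obs, n_perm, p, "greater", seed, "permanova",
        extra={"R2": float(ss_among[0] / ss_total), "df_among": g - 1, "df_within": n - g},
    )
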