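"""Within-group similarity summaries and classical group comparisons.

Mean pairwise community similarity (1 - Canberra) per land type, one-way
ANOVA across land types, Tukey HSD post hoc contrasts, and the two-tailed
pooled-variance Student t-test for RNA vs DNA contrasts.

A caveat these classical tests inherit from their inputs: pairwise
similarities are not independent observations (each sample participates in
n-1 pairs). The classical tests are reproduced verbatim because they are
the field's convention for these summaries, and a Mantel-style permutation
alternative (:func:`permutation_gap_test`, which permutes *samples*, the
exchangeable unit) is provided as a robustness line; pipeline reports carry
both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix
from .matrix_stats import PermTestResult, _perm_p


@dataclass
class SimilaritySummary:
    """Mean +/- SEM of within-group pairwise similarity."""

    group: str
    mean: float
    sem: float
    n_pairs: int
    pairs: np.ndarray = field(repr=False)


@dataclass
class GroupComparison:
    """ANOVA + Tukey HSD over within-group similarity pair vectors."""

    summaries: dict[str, SimilaritySummary]
    F: float
    df_among: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # columns group_a, group_b, diff, p_adj

    def to_dict(self) -> dict:
        return {
            "groups": {
                g: {"mean": s.mean, "sem": s.sem, "n_pairs": s.n_pairs}
                for g, s in self.summaries.items()
            },
            "F": self.F, "df": [self.df_among, self.df_within], "p": self.p,
            "tukey": self.tukey.to_dict(orient="records"),
        }


def within_group_pairs(D: DistanceMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    """Off-diagonal similarity values among the given samples."""
    sub = D.subset(sample_ids).to_similarity()
    return sub.condensed()


def mean_pairwise_similarity(D: DistanceMatrix, sample_ids: Sequence[str],
                             group: str = "") -> SimilaritySummary:
    """Mean +/- SEM of 1 - d over the within-group off-diagonal pairs."""
    if len(sample_ids) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")
    pairs = within_group_pairs(D, sample_ids)
    return SimilaritySummary(
        group=group, mean=float(pairs.mean()),
        sem=float(pairs.std(ddof=1) / np.sqrt(pairs.size)) if pairs.size > 1 else 0.0,
        n_pairs=pairs.size, pairs=pairs,
    )


def anova_oneway(groups: Mapping[str, np.ndarray]) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA on pooled pair vectors; returns F, (df1, df2), p."""
    vecs = [np.asarray(v, float) for v in groups.values()]
    if len(vecs) < 2:
        raise ValueError("need at least two groups")
    if any(v.size < 2 for v in vecs):
        raise ValueError("every group needs at least 2 values")
    F, p = stats.f_oneway(*vecs)
    df1 = len(vecs) - 1
    df2 = sum(v.size for v in vecs) - len(vecs)
    return float(F), (df1, df2), float(p)


def tukey_hsd(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for every group pair."""
    names = list(groups)
    vecs = [np.asarray(groups[g], float) for g in names]
    if len(vecs) < 2:
        raise ValueError("need at least two groups")
    res = stats.tukey_hsd(*vecs)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "diff": float(vecs[i].mean() - vecs[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


def compare_groups(D: DistanceMatrix, groups: Mapping[str, Sequence[str]]) -> GroupComparison:
    """Full comparison: per-group similarity summaries, ANOVA, Tukey HSD."""
    summaries = {
        g: mean_pairwise_similarity(D, ids, group=g) for g, ids in groups.items()
    }
    vecs = {g: s.pairs for g, s in summaries.items()}
    F, (df1, df2), p = anova_oneway(vecs)
    return GroupComparison(summaries, F, df1, df2, p, tukey_hsd(vecs))


def t_test_two_tailed(vec1: Sequence[float], vec2: Sequence[float]) -> tuple[float, int, float]:
    """Two-tailed pooled-variance Student t-test; returns t, df, p.

    Degenerate zero-variance input: equal means give t = 0, p = 1;
    unequal means with zero pooled variance are an error.
    """
    a = np.asarray(vec1, float)
    b = np.asarray(vec2, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each vector needs at least 2 values")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def permutation_gap_test(
    D: DistanceMatrix,
    ids1: Sequence[str],
    ids2: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermTestResult:
    """Sample-level permutation alternative to the classical tests.

    Statistic: difference in mean within-group pairwise similarity between
    two sample groups. The null permutes *sample* group membership and
    recomputes both means, respecting the non-independence of pairs.
    """
    all_ids = list(ids1) + list(ids2)
    sub = D.subset(all_ids).to_similarity()
    n1 = len(ids1)
    S = sub.values
    rng = np.random.default_rng(seed)

    def gap(order: np.ndarray) -> float:
        g1, g2 = order[:n1], order[n1:]
        m1 = S[np.ix_(g1, g1)][np.triu_indices(n1, 1)].mean()
        m2 = S[np.ix_(g2, g2)][np.triu_indices(len(g2), 1)].mean()
        return m1 - m2

    idx = np.arange(len(all_ids))
    obs = gap(idx)
    null = np.array([gap(rng.permutation(idx)) for _ in range(n_perm)])
    p, used_tail = _perm_p(obs, null, "two-sided")
    return PermTestResult(float(obs), n_perm, p, used_tail, seed, "similarity-gap-permutation")
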