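"""Negative-binomial Wald differential abundance for two-group designs.

A compact reimplementation of the DESeq2-style criterion used to define
"bloomer" taxa: median-of-ratios size factors, per-taxon negative-binomial
GLM with log link and group design, Cox-Reid adjusted maximum-likelihood
dispersion moderated toward a mean-dispersion trend, a Wald z on the log2
fold change, and Benjamini-Hochberg adjustment across taxa.

Deliberate simplifications relative to the full DESeq2 machinery: no
empirical-Bayes fold-change shrinkage, no Cook's-distance outlier
replacement, and dispersion moderation by a fixed-weight log-space average
with the fitted trend rather than a MAP estimate. The criterion that the
downstream mechanism analyses consume — positive log2 fold change with
adjusted p < 0.05 — is unchanged.

Input must be raw integer counts (rarefaction-averaged tables are refused):
the NB sampling model describes sequencing counts, not averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)


@dataclass
class DiffAbundResult:
    """Per-taxon Wald test results plus fitted normalization/dispersion."""

    table: pd.DataFrame  # taxon, baseMean, log2FoldChange, lfcSE, stat, pvalue, padj
    size_factors: pd.Series
    dispersions: pd.Series
    excluded_taxa: list[str]
    reference_level: str
    contrast_level: str

    def significant(self, alpha: float = 0.05, positive_only: bool = False) -> pd.Index:
        t = self.table
        mask = t["padj"] < alpha
        if positive_only:
            mask &= t["log2FoldChange"] > 0
        return t.index[mask]

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors, geometric-mean normalized.

    Reference taxa are those with a nonzero count in every sample; each
    sample's factor is the median ratio of its counts to the per-taxon
    geometric means. If no taxon is nonzero everywhere, geometric means are
    taken over positive counts only (logged fallback).
    """
    Y = counts.to_numpy(float)
    if Y.shape[1] == 0:
        raise ValueError("no taxa")
    all_pos = (Y > 0).all(axis=0)
    with np.errstate(divide="ignore"):
        logY = np.where(Y > 0, np.log(Y), np.nan)
    if all_pos.any():
        geo = np.exp(np.nanmean(logY[:, all_pos], axis=0))
        ratios = Y[:, all_pos] / geo
        s = np.median(ratios, axis=1)
    else:
        logger.warning("no taxon nonzero in every sample; using positive-count fallback")
        geo = np.exp(np.nanmean(logY, axis=0))
        ok = np.isfinite(geo) & (geo > 0)
        s = np.array([
            np.median(Y[j, ok][Y[j, ok] > 0] / geo[ok][Y[j, ok] > 0]) for j in range(Y.shape[0])
        ])
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("could not estimate positive size factors for all samples")
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.index, name="size_factor")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# NB likelihood machinery (taxa x samples arrays, vectorized over taxa)
# ---------------------------------------------------------------------------

def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood, stable down to the dispersion floor.

    Uses sum_{k<y} log(1 + k*alpha) = y*log(alpha) + lgamma(y + 1/alpha)
    - lgamma(1/alpha) for moderate alpha and its quadratic series for tiny
    alpha, where the lgamma form loses precision to cancellation.
    """
    a = alpha[:, None]
    small = a < 1e-3
    with np.errstate(invalid="ignore", divide="ignore"):
        r = 1.0 / a
        exact = Y * np.log(a) + gammaln(Y + r) - gammaln(r)
    s1 = Y * (Y - 1) / 2.0
    s2 = (Y - 1) * Y * (2 * Y - 1) / 6.0
    series = a * s1 - (a**2) * s2 / 2.0
    rising = np.where(small, series, np.nan_to_num(exact))
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogmu = np.where(Y > 0, Y * np.log(mu), 0.0)
    ll = rising + ylogmu - (Y + 1.0 / a) * np.log1p(a * mu) - gammaln(Y + 1)
    return ll.sum(axis=1)


def _fit_group_means(
    Y: np.ndarray, s: np.ndarray, alpha: np.ndarray, gmask: np.ndarray,
    n_iter: int = 30, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon NB MLE of the log mean for one sample group.

    Model mu_ij = s_j * exp(b_i); Newton iterations on the score
    U = sum_j (y - mu)/(1 + alpha*mu). Returns (b, expected information).
    """
    y = Y[:, gmask]
    sg = s[gmask]
    a = alpha[:, None]
    b = np.log((y.sum(axis=1) + 0.5) / sg.sum())
    for _ in range(n_iter):
        mu = sg * np.exp(b)[:, None]
        U = ((y - mu) / (1 + a * mu)).sum(axis=1)
        J = (mu * (1 + a * y) / (1 + a * mu) ** 2).sum(axis=1)
        step = np.clip(U / np.maximum(J, 1e-12), -3.0, 3.0)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    mu = sg * np.exp(b)[:, None]
    info = (mu / (1 + a * mu)).sum(axis=1)
    return b, info


def _profile_objective(
    Y: np.ndarray, s: np.ndarray, alpha: np.ndarray, masks: list[np.ndarray]
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood at the given dispersions."""
    mu = np.zeros_like(Y)
    cr = np.zeros(Y.shape[0])
    for gmask in masks:
        b, info = _fit_group_means(Y, s, alpha, gmask, n_iter=12)
        mu[:, gmask] = s[gmask] * np.exp(b)[:, None]
        cr += np.log(np.maximum(info, 1e-300))
    return _nb_loglik(Y, mu, alpha) - 0.5 * cr


def _ml_dispersion(
    Y: np.ndarray, s: np.ndarray, masks: list[np.ndarray],
    floor: float, ceiling: float = 20.0,
) -> np.ndarray:
    """Per-taxon CR-adjusted ML dispersion by grid + golden-section search."""
    m = Y.shape[0]
    lo, hi = np.log(floor), np.log(ceiling)
    grid = np.linspace(lo, hi, 25)
    best_ll = np.full(m, -np.inf)
    best_t = np.full(m, lo)
    for t in grid:
        ll = _profile_objective(Y, s, np.full(m, np.exp(t)), masks)
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_t[better] = t
    width = grid[1] - grid[0]
    a = np.maximum(best_t - width, lo)
    b = np.minimum(best_t + width, hi)
    invphi = (np.sqrt(5.0) - 1) / 2
    for _ in range(22):
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1 = _profile_objective(Y, s, np.exp(x1), masks)
        f2 = _profile_objective(Y, s, np.exp(x2), masks)
        take1 = f1 >= f2
        b = np.where(take1, x2, b)
        a = np.where(take1, a, x1)
    return np.exp((a + b) / 2)


def _dispersion_trend(base_mean: np.ndarray, alpha_ml: np.ndarray, floor: float) -> np.ndarray:
    """Fit alpha_tr(mu) = a0 + a1/mu on interior ML estimates (two rounds of
    reweighted least squares); fall back to the median when degenerate."""
    interior = (alpha_ml > 2 * floor) & (alpha_ml < 19.0) & (base_mean > 0)
    if interior.sum() < 10:
        med = float(np.median(alpha_ml[alpha_ml > 0])) if (alpha_ml > 0).any() else floor
        return np.full_like(alpha_ml, max(med, floor))
    X = np.column_stack([np.ones(interior.sum()), 1.0 / base_mean[interior]])
    y = alpha_ml[interior]
    w = np.ones_like(y)
    coef = np.array([np.median(y), 0.0])
    for _ in range(3):
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
        coef = np.maximum(coef, [1e-6, 0.0])
        fitted = X @ coef
        w = 1.0 / np.maximum(fitted, 1e-6) ** 2
    tr = coef[0] + coef[1] / np.maximum(base_mean, 1e-12)
    return np.maximum(tr, floor)


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def nb_wald(
    counts: pd.DataFrame,
    groups: Sequence,
    reference: str | None = None,
    alpha_floor: float = 1e-8,
    shrink_weight: float = 0.5,
    min_sample_depth: int | None = None,
    min_mean_filter: float | None = None,
) -> DiffAbundResult:
    """Two-group NB-GLM Wald test per taxon.

    Parameters
    ----------
    counts
        Raw integer counts, samples x taxa.
    groups
        Two-level labels aligned to the rows of ``counts``. The
        alphabetically first level is the reference unless ``reference``
        names one explicitly; log2 fold changes are contrast vs reference.
    alpha_floor
        Lower bound for the dispersion.
    shrink_weight
        Weight of the fitted mean-dispersion trend in the log-space
        moderation of the per-taxon ML dispersion (0 = pure ML, 1 = pure
        trend).
    min_sample_depth
        Optional minimum library size; shallower samples are excluded
        before fitting (the "low abundance samples excluded" filter).
    min_mean_filter
        Optional independent filter: taxa with base mean below this are
        excluded before BH adjustment.
    """
    arr = counts.to_numpy()
    if not np.allclose(arr, np.rint(arr), atol=1e-9):
        raise ValueError("nb_wald requires raw integer counts, not rarefaction averages")
    labels = pd.Series([str(g) for g in groups], index=counts.index)
    if min_sample_depth is not None:
        keep = counts.sum(axis=1) >= min_sample_depth
        if not keep.all():
            logger.warning("excluding %d low-depth sample(s) before NB fit", int((~keep).sum()))
        counts, labels = counts.loc[keep], labels.loc[keep]
    levels = sorted(pd.unique(labels))  # alphabetical reference, as in DESeq2
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if reference is not None:
        if str(reference) not in levels:
            raise ValueError(f"reference {reference!r} not among groups {levels}")
        levels = [str(reference)] + [lv for lv in levels if lv != str(reference)]
    masks = [(labels == lv).to_numpy() for lv in levels]
    if any(mk.sum() < 2 for mk in masks):
        raise ValueError("each group needs at least 2 samples")

    nonzero = counts.sum(axis=0) > 0
    excluded = list(counts.columns[~nonzero])
    if excluded:
        logger.info("excluding %d all-zero taxa", len(excluded))
    counts_nz = counts.loc[:, nonzero]

    s = size_factors(counts_nz)
    Y = counts_nz.to_numpy(float).T  # taxa x samples
    sv = s.to_numpy()
    base_mean = (Y / sv).mean(axis=1)

    if min_mean_filter is not None:
        keep_taxa = base_mean >= min_mean_filter
        excluded += list(counts_nz.columns[~keep_taxa])
        counts_nz = counts_nz.loc[:, keep_taxa]
        Y, base_mean = Y[keep_taxa], base_mean[keep_taxa]

    alpha_ml = _ml_dispersion(Y, sv, masks, alpha_floor)
    alpha_tr = _dispersion_trend(base_mean, alpha_ml, alpha_floor)
    log_mod = (1 - shrink_weight) * np.log(alpha_ml) + shrink_weight * np.log(alpha_tr)
    alpha = np.maximum(np.exp(log_mod), alpha_floor)

    b_ref, info_ref = _fit_group_means(Y, sv, alpha, masks[0])
    b_con, info_con = _fit_group_means(Y, sv, alpha, masks[1])
    delta = b_con - b_ref
    se_nat = np.sqrt(1.0 / np.maximum(info_ref, 1e-300) + 1.0 / np.maximum(info_con, 1e-300))
    z = delta / se_nat
    from scipy.stats import norm

    pvalue = 2.0 * norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": delta / _LN2,
            "lfcSE": se_nat / _LN2,
            "stat": z,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=counts_nz.columns,
    )
    return DiffAbundResult(
        table=table,
        size_factors=s,
        dispersions=pd.Series(alpha, index=counts_nz.columns, name="dispersion"),
        excluded_taxa=excluded,
        reference_level=levels[0],
        contrast_level=levels[1],
    )
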