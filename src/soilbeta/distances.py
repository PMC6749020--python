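"""Pairwise dissimilarity: Canberra (community), Gower (environment),
Euclidean geographic distance, and collinear-variable pruning.

The Canberra dialect used here averages over the taxa that are not
double-zero for a pair, so distances lie in [0, 1] and 1 - d is a bounded
community similarity. The textbook unaveraged sum is available behind a
flag for cross-checking against other software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CommunityTable, EnvTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix with labels and a semantic tag.

    ``kind`` is one of ``community``, ``environment``, ``geographic``;
    ``transform`` records whether entries are raw dissimilarities
    (``none``), similarities (``similarity``), or log10 distances
    (``log10``). Similarity conversion is only defined for kinds bounded in
    [0, 1] (community and environment, not geographic).
    """

    values: np.ndarray
    ids: list[str]
    kind: str
    transform: str = "none"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("size does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        self.values = (v + v.T) / 2.0
        self.ids = list(map(str, self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_similarity(self) -> bool:
        return self.transform == "similarity"

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries in scipy condensed order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def to_similarity(self) -> "DistanceMatrix":
        if self.is_similarity:
            return self
        if self.kind == "geographic":
            raise ValueError("geographic distance is unbounded; no similarity form")
        return DistanceMatrix(1.0 - self.values, self.ids, self.kind, "similarity")

    def to_dissimilarity(self) -> "DistanceMatrix":
        if not self.is_similarity:
            return self
        return DistanceMatrix(1.0 - self.values, self.ids, self.kind, "none")

    def log10(self) -> "DistanceMatrix":
        """log10-transform off-diagonal entries (geographic decay predictor)."""
        off = ~np.eye(self.n, dtype=bool)
        if (self.values[off] <= 0).any():
            raise ValueError("zero or negative off-diagonal distances; cannot log-transform")
        out = np.zeros_like(self.values)
        out[off] = np.log10(self.values[off])
        return DistanceMatrix(out, self.ids, self.kind, "log10")

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = [self.ids.index(str(i)) for i in ids]
        return DistanceMatrix(self.values[np.ix_(pos, pos)], [self.ids[p] for p in pos],
                              self.kind, self.transform)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str, transform: str = "none") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index.astype(str)), kind, transform)


# ---------------------------------------------------------------------------
# Community: Canberra
# ---------------------------------------------------------------------------

def canberra(table: CommunityTable, averaged: bool = True) -> DistanceMatrix:
    """Pairwise Canberra distance between samples.

    d(i, j) = (1/NZ) * sum_k |x_ik - x_jk| / (x_ik + x_jk), summed over the
    NZ taxa where x_ik + x_jk > 0 (double zeros carry no information and are
    excluded). With ``averaged=False`` the raw sum is returned instead.
    """
    X = table.counts.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if (X < 0).any():
        raise ValueError("negative abundances")
    diff = np.abs(X[:, None, :] - X[None, :, :])
    tot = X[:, None, :] + X[None, :, :]
    nz = tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(nz, diff / np.where(nz, tot, 1.0), 0.0)
    nnz = nz.sum(axis=2)
    iu = np.triu_indices(n, 1)
    if (nnz[iu] == 0).any():
        bad = np.argwhere((nnz == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"samples {table.sample_ids[bad[0]]!r} and {table.sample_ids[bad[1]]!r} "
            "share no nonzero taxon; Canberra undefined"
        )
    d = terms.sum(axis=2)
    if averaged:
        d = d / np.maximum(nnz, 1)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, table.sample_ids, "community", "none")


def community_similarity(table: CommunityTable) -> DistanceMatrix:
    """1 - averaged Canberra distance: the bounded community similarity."""
    return canberra(table).to_similarity()


# ---------------------------------------------------------------------------
# Environment: Gower
# ---------------------------------------------------------------------------

def gower_similarity(env: EnvTable) -> DistanceMatrix:
    """Pairwise 1 - Gower dissimilarity on the environment table.

    Numeric variables contribute range-normalized Manhattan components
    |x_iv - x_jv| / range_v; categorical (object/category dtype) variables
    contribute simple matching (0 if equal, 1 otherwise). Variables with
    zero range are dropped with a warning. The returned matrix is tagged as
    a similarity in [0, 1].
    """
    df = env.values
    n = df.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    comps = []
    for col in df.columns:
        v = df[col]
        if pd.api.types.is_numeric_dtype(v):
            x = v.to_numpy(float)
            rng = x.max() - x.min()
            if rng <= 0:
                logger.warning("dropping zero-range variable %r from Gower", col)
                continue
            comps.append(np.abs(x[:, None] - x[None, :]) / rng)
        else:
            x = v.to_numpy()
            comps.append((x[:, None] != x[None, :]).astype(float))
    if not comps:
        raise ValueError("all variables have zero range; Gower undefined")
    diss = np.mean(comps, axis=0)
    np.fill_diagonal(diss, 0.0)
    return DistanceMatrix(1.0 - diss, list(df.index.astype(str)), "environment", "similarity")


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def geographic(metadata: pd.DataFrame | CommunityTable) -> DistanceMatrix:
    """Euclidean distance in meters from the x, y sample coordinates."""
    if isinstance(metadata, CommunityTable):
        xy = metadata.coordinates()
        ids = metadata.sample_ids
    else:
        xy = metadata[["x", "y"]].to_numpy(float)
        ids = list(metadata.index.astype(str))
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    n = d.shape[0]
    if ((d + np.eye(n)) == 0).any():
        logger.warning("duplicate coordinates present; log-distance transforms will fail")
    return DistanceMatrix(d, ids, "geographic", "none")


# ---------------------------------------------------------------------------
# Environmental variable pruning
# ---------------------------------------------------------------------------

def prune_correlated(
    env: EnvTable, r2_threshold: float = 0.6, p_threshold: float = 0.05
) -> tuple[EnvTable, list[dict]]:
    """Greedily drop one member of each highly collinear variable pair.

    While any pair has Pearson R^2 above ``r2_threshold`` with
    p below ``p_threshold``, the member with the larger mean absolute
    correlation to all remaining variables is removed. Returns the reduced
    table and a log of removals (variable, partner, r, p).
    """
    df = env.values.copy()
    removals: list[dict] = []
    while df.shape[1] >= 2:
        cols = list(df.columns)
        k = len(cols)
        rmat = np.eye(k)
        pmat = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                r, p = stats.pearsonr(df[cols[i]], df[cols[j]])
                rmat[i, j] = rmat[j, i] = r
                pmat[i, j] = pmat[j, i] = p
        viol = (rmat**2 > r2_threshold) & (pmat < p_threshold) & ~np.eye(k, dtype=bool)
        if not viol.any():
            break
        # worst offending pair: largest R^2 among violations
        r2 = np.where(viol, rmat**2, -1.0)
        i, j = np.unravel_index(np.argmax(r2), r2.shape)
        mean_abs = np.abs(rmat - np.eye(k)).sum(axis=1) / (k - 1)
        drop = i if mean_abs[i] >= mean_abs[j] else j
        keep = j if drop == i else i
        removals.append({
            "removed": cols[drop], "partner": cols[keep],
            "r": float(rmat[i, j]), "p": float(pmat[i, j]),
        })
        logger.info("pruning %r (r=%.3f with %r)", cols[drop], rmat[i, j], cols[keep])
        df = df.drop(columns=[cols[drop]])
    return EnvTable(df), removals
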