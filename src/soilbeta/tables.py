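"""Community and environment tables: data model, I/O, rarefaction, richness.

The central object is :class:`CommunityTable`, a samples x taxa count matrix
with per-sample metadata (site, molecule, plot coordinates in meters). Raw
tables hold integer sequence counts; rarefaction-averaged tables hold
fractional counts whose rows sum to the rarefaction depth. Downstream
beta-diversity analyses consume either, while the negative-binomial
differential-abundance module requires raw integer counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_METADATA = ("site", "molecule", "x", "y")


@dataclass
class CommunityTable:
    """Samples x taxa abundance matrix with aligned sample metadata.

    Parameters
    ----------
    counts
        Non-negative matrix, samples as rows, taxa as columns. Integer for
        raw tables; fractional after rarefaction averaging.
    metadata
        One row per sample with at least ``site``, ``molecule`` (RNA|DNA) and
        plot coordinates ``x``, ``y`` in meters.
    rarefaction_depth
        Set on tables produced by :func:`rarefy_once` /
        :func:`rarefaction_average`; ``None`` for raw tables.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    rarefaction_depth: float | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float) if self.rarefaction_depth else self.counts
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(
                f"samples missing from metadata: {', '.join(map(str, missing))}"
            )
        absent = [c for c in REQUIRED_METADATA if c not in self.metadata.columns]
        if absent:
            raise ValueError(f"metadata lacks required columns: {absent}")
        # keep metadata aligned and restricted to the count table's samples
        self.metadata = self.metadata.loc[self.counts.index]

    # -- basic views -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of x, y positions in meters."""
        return self.metadata[["x", "y"]].to_numpy(float)

    def subset_samples(self, ids: Sequence[str]) -> "CommunityTable":
        return CommunityTable(
            self.counts.loc[list(ids)], self.metadata.loc[list(ids)],
            self.rarefaction_depth,
        )

    def drop_taxa(self, taxa: Iterable[str]) -> "CommunityTable":
        keep = self.counts.columns.difference(pd.Index(taxa), sort=False)
        return CommunityTable(self.counts[keep], self.metadata, None)

    def detected(self, threshold: float = 0.0) -> pd.DataFrame:
        """Boolean samples x taxa detection mask (abundance > threshold)."""
        return self.counts > threshold

    def detected_taxa(self, threshold: float = 0.0) -> pd.Index:
        """Taxa detected in at least one sample."""
        mask = self.detected(threshold).any(axis=0)
        return self.counts.columns[mask]


@dataclass
class EnvTable:
    """Samples x numeric soil variables (e.g. organic matter %, P, pH, K,
    CEC, nitrate-N, S)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValueError(
                "missing values in environment table; impute or drop before loading"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TaxonomyMap:
    """taxon_id -> ranked lineage (phylum at minimum)."""

    lineages: pd.DataFrame  # index taxon_id, columns ranks

    def rank(self, rank: str) -> pd.Series:
        if rank not in self.lineages.columns:
            raise KeyError(f"rank {rank!r} not in taxonomy (has {list(self.lineages.columns)})")
        return self.lineages[rank]


# ---------------------------------------------------------------------------
# I/O: classic tab-separated OTU table (taxa rows x sample columns) and BIOM
# ---------------------------------------------------------------------------

def read_community(
    path: str | Path,
    metadata_path: str | Path,
    format: str = "classic-tsv",
) -> CommunityTable:
    """Load an OTU table plus a sample metadata TSV into a CommunityTable.

    ``classic-tsv`` is the taxa-rows x sample-columns layout with a
    ``#OTU ID`` header column; ``biom`` is BIOM 2.1 (HDF5) or BIOM 1.0 JSON.
    Samples present in the counts but absent from metadata raise an error
    naming the sample.
    """
    path = Path(path)
    if format == "classic-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        counts = df.T  # samples x taxa
    elif format == "biom":
        import biom

        table = biom.load_table(str(path))
        counts = pd.DataFrame(
            table.matrix_data.toarray().T,
            index=table.ids("sample"),
            columns=table.ids("observation"),
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index.name = None
    counts.columns.name = None
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise ValueError(f"non-numeric entries in {path}")
    meta = read_metadata(metadata_path)
    return CommunityTable(counts, meta)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"site": str, "molecule": str})
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    return meta


def write_community(
    table: CommunityTable,
    path: str | Path,
    metadata_path: str | Path | None = None,
    format: str = "classic-tsv",
) -> None:
    """Write counts (and optionally metadata) in a supported format.

    Writers are bit-stable for fixed inputs.
    """
    path = Path(path)
    if format == "classic-tsv":
        table.counts.T.rename_axis("#OTU ID").to_csv(path, sep="\t")
    elif format == "biom":
        import biom

        btab = biom.Table(
            table.counts.to_numpy().T,
            observation_ids=table.taxon_ids,
            sample_ids=table.sample_ids,
        )
        with biom.util.biom_open(str(path), "w") as fh:
            btab.to_hdf5(fh, generated_by="soilbeta")
    else:
        raise ValueError(f"unknown format {format!r}")
    if metadata_path is not None:
        meta = table.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


def read_env(path: str | Path, dropna: bool = False) -> EnvTable:
    """Load a soil-chemistry TSV (sample_id column + numeric variables)."""
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    df.index = df.index.astype(str)
    if dropna:
        df = df.dropna(axis=0)
    return EnvTable(df.astype(float))


def write_env(env: EnvTable, path: str | Path) -> None:
    out = env.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _require_integer_counts(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-9):
        raise ValueError("rarefaction requires raw integer counts")
    return rounded.astype(np.int64)


def _drop_shallow(table: CommunityTable, depth: int) -> CommunityTable:
    sums = table.counts.sum(axis=1)
    shallow = sums.index[sums < depth]
    if len(shallow):
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(shallow), depth, ", ".join(map(str, shallow)),
        )
        table = table.subset_samples([s for s in table.sample_ids if s not in set(shallow)])
    if table.n_samples == 0:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    return table


def rarefy_once(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample each sample to ``depth`` counts without replacement.

    Samples with fewer than ``depth`` total counts are dropped with a logged
    warning. Each retained row of the result sums exactly to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    table = _drop_shallow(table, depth)
    arr = _require_integer_counts(table.counts)
    rng = np.random.default_rng(seed)
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        out[i] = rng.multivariate_hypergeometric(arr[i], depth)
    res = pd.DataFrame(out.astype(float), index=table.counts.index, columns=table.counts.columns)
    return CommunityTable(res, table.metadata, rarefaction_depth=float(depth))


def rarefaction_average(
    table: CommunityTable, depth: int, n_reps: int = 100, seed: int = 0
) -> CommunityTable:
    """Entrywise mean of ``n_reps`` independent rarefactions at ``depth``.

    This is the sampling-effort equalization applied before every
    beta-diversity computation; averaging damps the single-draw noise while
    keeping every row sum at the depth. Deterministic given ``seed``.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    table = _drop_shallow(table, depth)
    arr = _require_integer_counts(table.counts)
    rng = np.random.default_rng(seed)
    acc = np.zeros(arr.shape, dtype=float)
    for _ in range(n_reps):
        for i in range(arr.shape[0]):
            acc[i] += rng.multivariate_hypergeometric(arr[i], depth)
    acc /= n_reps
    res = pd.DataFrame(acc, index=table.counts.index, columns=table.counts.columns)
    return CommunityTable(res, table.metadata, rarefaction_depth=float(depth))


# ---------------------------------------------------------------------------
# Richness and taxonomic aggregation
# ---------------------------------------------------------------------------

def richness(table: CommunityTable, detection_threshold: float = 0.0) -> pd.Series:
    """Per-sample count of taxa with abundance above the detection threshold."""
    return (table.counts > detection_threshold).sum(axis=1).rename("richness")


def aggregate_taxonomy(
    table: CommunityTable,
    taxonomy: TaxonomyMap,
    rank: str,
    relative: bool = False,
) -> CommunityTable:
    """Sum columns by taxonomic rank label (e.g. phylum).

    Taxa absent from the map are routed to ``Unassigned`` and counted in a
    warning. With ``relative=True`` rows are divided by their sums.
    """
    labels = taxonomy.rank(rank)
    mapped = labels.reindex(table.counts.columns)
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped == table.n_taxa:
        raise ValueError("no taxon in the table is present in the taxonomy map")
    if n_unmapped:
        warnings.warn(f"{n_unmapped} taxa unmapped at rank {rank!r}; routed to 'Unassigned'")
        mapped = mapped.fillna("Unassigned")
    agg = table.counts.T.groupby(mapped).sum().T
    if relative:
        agg = agg.div(agg.sum(axis=1), axis=0)
    return CommunityTable(agg, table.metadata, table.rarefaction_depth if not relative else None)


def align_taxa(tables: Sequence[CommunityTable]) -> list[CommunityTable]:
    """Outer-join taxon universes across tables, filling absences with zero.

    Newcomer identification and cross-site differential abundance require a
    shared taxon universe; this is the canonical way to establish one.
    """
    universe = tables[0].counts.columns
    for t in tables[1:]:
        universe = universe.union(t.counts.columns, sort=False)
    return [
        CommunityTable(
            t.counts.reindex(columns=universe, fill_value=0.0 if t.rarefaction_depth else 0),
            t.metadata,
            t.rarefaction_depth,
        )
        for t in tables
    ]


def concat_samples(tables: Sequence[CommunityTable]) -> CommunityTable:
    """Stack tables sample-wise on a shared (outer-joined) taxon universe."""
    aligned = align_taxa(tables)
    counts = pd.concat([t.counts for t in aligned], axis=0)
    meta = pd.concat([t.metadata for t in aligned], axis=0)
    depth = aligned[0].rarefaction_depth
    if any(t.rarefaction_depth != depth for t in aligned):
        depth = None
    return CommunityTable(counts, meta, depth)
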