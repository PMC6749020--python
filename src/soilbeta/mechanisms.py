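"""Homogenization mechanism attribution: newcomers, bloomers, and
removal-and-recompute analyses.

Two candidate mechanisms can raise pairwise community similarity after land
conversion:

* **newcomers** — taxa detected in a converted site but in no forest
  sample (biotic invasion);
* **bloomers** — resident taxa whose relative abundance significantly
  increased in the converted site (positive log2 fold change, adjusted
  p < 0.05; range expansion).

Each candidate set is removed from the converted site's raw count table,
sampling extent is re-equalized by rarefaction averaging, and pairwise
similarity plus distance-decay are recomputed. A mechanism "contributes"
when removal significantly lowers mean pairwise similarity (Tukey HSD,
before vs after) and leaves the community no longer significantly more
similar than the forest baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diffabund import nb_wald
from .distances import canberra, geographic
from .group_stats import SimilaritySummary, mean_pairwise_similarity, tukey_hsd
from .matrix_stats import DecayFit, decay_fit
from .tables import CommunityTable, align_taxa, concat_samples, rarefaction_average

logger = logging.getLogger(__name__)


@dataclass
class TaxonSet:
    """A candidate mechanism's taxa with context."""

    taxa: list[str]
    provenance: str  # newcomer | bloomer
    reference_site: str
    target_site: str
    mean_rel_abund: float          # summed share of the target community
    occurrence_reference: pd.Series = field(repr=False, default=None)
    occurrence_target: pd.Series = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.taxa)


@dataclass
class RemovalResult:
    """Before/after state of a removal-and-recompute analysis."""

    before: SimilaritySummary
    after: SimilaritySummary
    decay_before: DecayFit
    decay_after: DecayFit
    depth_used: int
    removed: int


@dataclass
class MechanismOutcome:
    taxon_set: TaxonSet
    removal: RemovalResult
    forest_similarity: SimilaritySummary
    p_before_vs_after: float
    p_after_vs_forest: float
    contributes: bool

    def to_dict(self) -> dict:
        return {
            "provenance": self.taxon_set.provenance,
            "n_taxa_removed": len(self.taxon_set),
            "mean_rel_abund": self.taxon_set.mean_rel_abund,
            "occurrence_mean_reference": (
                float(self.taxon_set.occurrence_reference.mean())
                if len(self.taxon_set) else float("nan")
            ),
            "occurrence_mean_target": (
                float(self.taxon_set.occurrence_target.mean())
                if len(self.taxon_set) else float("nan")
            ),
            "similarity_forest": {"mean": self.forest_similarity.mean,
                                  "sem": self.forest_similarity.sem},
            "similarity_before": {"mean": self.removal.before.mean,
                                  "sem": self.removal.before.sem},
            "similarity_after": {"mean": self.removal.after.mean,
                                 "sem": self.removal.after.sem},
            "decay_before": self.removal.decay_before.to_dict(),
            "decay_after": self.removal.decay_after.to_dict(),
            "p_before_vs_after": self.p_before_vs_after,
            "p_after_vs_forest": self.p_after_vs_forest,
            "contributes": self.contributes,
        }


@dataclass
class MechanismReport:
    """Per molecule x mechanism verdicts plus every supporting number."""

    target_site: str
    outcomes: dict[tuple[str, str], MechanismOutcome]  # (molecule, provenance)
    depth: int
    n_reps: int
    seed: int

    def verdict(self, molecule: str, provenance: str) -> bool:
        return self.outcomes[(molecule, provenance)].contributes

    def to_dict(self) -> dict:
        return {
            "target_site": self.target_site,
            "depth": self.depth,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "outcomes": {
                f"{mol}:{prov}": o.to_dict() for (mol, prov), o in self.outcomes.items()
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (mol, prov), o in self.outcomes.items():
            rows.append({
                "molecule": mol, "mechanism": prov,
                "n_removed": len(o.taxon_set),
                "similarity_before": o.removal.before.mean,
                "similarity_after": o.removal.after.mean,
                "similarity_forest": o.forest_similarity.mean,
                "p_before_vs_after": o.p_before_vs_after,
                "p_after_vs_forest": o.p_after_vs_forest,
                "contributes": o.contributes,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Candidate sets
# ---------------------------------------------------------------------------

def identify_newcomers(
    target: CommunityTable,
    reference: CommunityTable,
    detection_threshold: float = 0.0,
) -> TaxonSet:
    """Taxa detected in the target site but in no reference sample.

    Both tables should be rarefaction-averaged on the same taxon universe;
    a taxon is detected where its averaged count exceeds the threshold
    (default: drawn in at least one rarefaction of one sample).
    """
    if target.n_samples == 0 or reference.n_samples == 0:
        raise ValueError("empty community table")
    tgt, ref = align_taxa([target, reference])
    in_target = set(tgt.detected_taxa(detection_threshold))
    in_reference = set(ref.detected_taxa(detection_threshold))
    new = sorted(in_target - in_reference)
    return _with_context(new, "newcomer", ref, tgt, detection_threshold)


def identify_bloomers(
    forest: CommunityTable,
    target: CommunityTable,
    alpha: float = 0.05,
    detection_threshold: float = 0.0,
    target_avg: CommunityTable | None = None,
    reference_avg: CommunityTable | None = None,
    **nb_kwargs,
) -> TaxonSet:
    """Taxa significantly enriched in the target site relative to forest.

    Runs the NB Wald test on the raw counts (forest as the reference
    level) and keeps taxa with positive log2 fold change and BH-adjusted
    p below ``alpha``. Occurrence/abundance context is computed on the
    averaged tables when provided, else on the raw ones.
    """
    combined = concat_samples([forest, target])
    site = combined.metadata["site"]
    forest_site = str(forest.metadata["site"].iloc[0])
    res = nb_wald(combined.counts, site, reference=forest_site, **nb_kwargs)
    hits = sorted(res.significant(alpha=alpha, positive_only=True))
    ref_ctx = reference_avg if reference_avg is not None else forest
    tgt_ctx = target_avg if target_avg is not None else target
    ref_ctx, tgt_ctx = align_taxa([ref_ctx, tgt_ctx])
    return _with_context(hits, "bloomer", ref_ctx, tgt_ctx, detection_threshold)


def _with_context(
    taxa: list[str],
    provenance: str,
    reference: CommunityTable,
    target: CommunityTable,
    detection_threshold: float,
) -> TaxonSet:
    present = [t for t in taxa if t in target.counts.columns]
    rel = target.counts.div(target.counts.sum(axis=1), axis=0)
    share = float(rel[present].sum(axis=1).mean()) if present else 0.0
    return TaxonSet(
        taxa=list(taxa),
        provenance=provenance,
        reference_site=str(reference.metadata["site"].iloc[0]),
        target_site=str(target.metadata["site"].iloc[0]),
        mean_rel_abund=share,
        occurrence_reference=occurrence_frequency(reference, taxa, detection_threshold),
        occurrence_target=occurrence_frequency(target, taxa, detection_threshold),
    )


def occurrence_frequency(
    table: CommunityTable,
    taxa: Sequence[str],
    detection_threshold: float = 0.0,
) -> pd.Series:
    """Fraction of the site's samples in which each taxon is detected."""
    taxa = [t for t in taxa]
    det = table.detected(detection_threshold)
    freq = det.reindex(columns=taxa, fill_value=False).mean(axis=0)
    return freq.rename("occurrence_frequency")


# ---------------------------------------------------------------------------
# Removal and recompute
# ---------------------------------------------------------------------------

def removal_analysis(
    table: CommunityTable,
    remove: TaxonSet | Sequence[str],
    depth: int,
    n_reps: int = 100,
    seed: int = 0,
    n_perm: int = 999,
) -> RemovalResult:
    """Remove a taxon set from a raw table and re-run the similarity suite.

    Both states are rarefaction-averaged (the removal state at a depth
    lowered to the post-removal minimum library size when necessary,
    logged) before computing mean pairwise 1 - Canberra similarity and the
    geographic distance-decay fit.
    """
    taxa = list(remove.taxa) if isinstance(remove, TaxonSet) else list(remove)
    before_avg = rarefaction_average(table, depth, n_reps, seed)
    kept_samples = before_avg.sample_ids

    stripped = table.subset_samples(kept_samples).drop_taxa(taxa)
    sums = stripped.counts.sum(axis=1)
    if (sums == 0).any():
        empty = list(sums.index[sums == 0])
        raise ValueError(f"removal empties sample(s): {empty}")
    depth_after = int(min(depth, sums.min()))
    if depth_after < depth:
        logger.warning(
            "removal leaves min library %d < depth %d; lowering depth", depth_after, depth
        )
    after_avg = rarefaction_average(stripped, depth_after, n_reps, seed)

    out = {}
    for tag, avg in (("before", before_avg), ("after", after_avg)):
        sim = canberra(avg).to_similarity()
        geo = geographic(avg)
        out[tag] = (
            mean_pairwise_similarity(sim, avg.sample_ids, group=tag),
            decay_fit(sim, geo, n_perm=n_perm, seed=seed),
        )
    return RemovalResult(
        before=out["before"][0], after=out["after"][0],
        decay_before=out["before"][1], decay_after=out["after"][1],
        depth_used=depth_after, removed=len(taxa),
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def _verdict(
    forest: SimilaritySummary,
    removal: RemovalResult,
    alpha: float,
) -> tuple[float, float, bool]:
    """Tukey HSD across forest / before / after pair vectors; a mechanism
    contributes iff removal significantly lowers similarity and the
    post-removal level is not significantly above the forest baseline."""
    tk = tukey_hsd({
        "forest": forest.pairs, "before": removal.before.pairs, "after": removal.after.pairs,
    })
    tk = tk.set_index(["group_a", "group_b"])

    def p_of(a: str, b: str) -> float:
        if (a, b) in tk.index:
            return float(tk.loc[(a, b), "p_adj"])
        return float(tk.loc[(b, a), "p_adj"])

    p_ba = p_of("before", "after")
    p_af = p_of("after", "forest")
    lowered = (p_ba < alpha) and (removal.after.mean < removal.before.mean)
    still_elevated = (p_af < alpha) and (removal.after.mean > forest.mean)
    return p_ba, p_af, lowered and not still_elevated


def mechanism_report(
    forest_tables: dict[str, CommunityTable],
    target_tables: dict[str, CommunityTable],
    depth: int,
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    n_perm: int = 999,
    detection_threshold: float = 0.0,
    nb_kwargs: dict | None = None,
) -> MechanismReport:
    """Run both mechanism branches for each molecule and assemble verdicts.

    ``forest_tables`` and ``target_tables`` map molecule ("RNA"/"DNA") to
    raw count tables. Bloomers are identified on raw counts; newcomers on
    the rarefaction-averaged detection rule; removals operate on raw
    counts and are re-rarefied.
    """
    nb_kwargs = dict(nb_kwargs or {})
    nb_kwargs.setdefault("min_sample_depth", depth)
    outcomes: dict[tuple[str, str], MechanismOutcome] = {}
    target_site = None
    for mol in forest_tables:
        forest_raw, target_raw = align_taxa([forest_tables[mol], target_tables[mol]])
        target_site = str(target_raw.metadata["site"].iloc[0])
        forest_avg = rarefaction_average(forest_raw, depth, n_reps, seed)
        target_avg = rarefaction_average(target_raw, depth, n_reps, seed + 1)
        forest_sim = canberra(forest_avg).to_similarity()
        forest_summary = mean_pairwise_similarity(
            forest_sim, forest_avg.sample_ids, group="forest"
        )
        newcomers = identify_newcomers(target_avg, forest_avg, detection_threshold)
        bloomers = identify_bloomers(
            forest_raw, target_raw, alpha=alpha,
            detection_threshold=detection_threshold,
            target_avg=target_avg, reference_avg=forest_avg, **nb_kwargs,
        )
        for tset in (newcomers, bloomers):
            removal = removal_analysis(
                target_raw, tset, depth, n_reps=n_reps, seed=seed + 2, n_perm=n_perm
            )
            p_ba, p_af, contributes = _verdict(forest_summary, removal, alpha)
            outcomes[(mol, tset.provenance)] = MechanismOutcome(
                taxon_set=tset, removal=removal, forest_similarity=forest_summary,
                p_before_vs_after=p_ba, p_after_vs_forest=p_af, contributes=contributes,
            )
    return MechanismReport(
        target_site=target_site or "", outcomes=outcomes,
        depth=depth, n_reps=n_reps, seed=seed,
    )
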