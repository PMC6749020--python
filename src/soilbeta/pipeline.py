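"""End-to-end orchestration: load or simulate, then run the full analysis.

Stage order: load/simulate -> prune collinear soil variables ->
rarefaction-average -> distance matrices -> PERMANOVA + richness ->
within-site similarity + ANOVA/Tukey/t-test -> distance-decay + Mantel /
partial Mantel + slope comparisons -> differential abundance -> mechanism
report. Every stochastic stage derives its seed from the master seed by a
fixed offset, and the JSON summary records seeds, depths and dropped
samples so any number is regenerable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import distances, group_stats, matrix_stats, mechanisms, synthetic, tables

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (master seed + offset feeds default_rng)
STAGE_SEEDS = {
    "simulate": 1,
    "rarefaction": 2,
    "mantel": 3,
    "permanova": 4,
    "diffslope": 5,
    "mechanisms": 6,
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``community_paths``/``metadata_path`` (real data) or
    ``scenario`` (synthetic) must be provided.
    """

    output_dir: str = "soilbeta_out"
    master_seed: int = 0
    rarefaction_depth: int = 3790
    rarefaction_reps: int = 100
    n_perm_mantel: int = 999
    n_perm_diffslope: int = 1000
    log10_distance: bool = True
    canberra_averaged: bool = True
    detection_threshold: float = 0.0
    diffabund_alpha: float = 0.05
    scenario: dict | None = None        # ScenarioConfig overrides for synthetic runs
    community_paths: dict | None = None  # {site: {molecule: path}}
    community_format: str = "classic-tsv"
    metadata_path: str | None = None
    env_path: str | None = None
    forest_site: str = "forest"
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        return int(self.master_seed * 101 + STAGE_SEEDS[stage])


def _load_sites(config: RunConfig) -> dict[str, synthetic.SiteData]:
    if config.scenario is not None:
        sc = synthetic.ScenarioConfig(**{**config.scenario, "seed": config.master_seed})
        return synthetic.simulate_study(sc, seed=config.stage_seed("simulate"))
    if not config.community_paths or not config.metadata_path:
        raise ValueError("config needs either a scenario or community_paths + metadata_path")
    env = tables.read_env(config.env_path) if config.env_path else None
    sites: dict[str, synthetic.SiteData] = {}
    for site, by_mol in config.community_paths.items():
        tabs = {}
        for mol, path in by_mol.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"community table not found: {path}")
            tabs[mol] = tables.read_community(path, config.metadata_path,
                                              format=config.community_format)
        site_env = None
        if env is not None:
            cores = sorted({s.rsplit("-", 1)[0] for t in tabs.values() for s in t.sample_ids})
            site_env = tables.EnvTable(env.values.loc[[c for c in cores if c in env.values.index]])
        sites[site] = synthetic.SiteData(site=site, env=site_env, tables=tabs)
    return sites


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the JSON-ready summary dict.

    Writes ``summary.json``, per-site averaged tables, the differential
    abundance tables, the mechanism report, and a run log to
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger("soilbeta").addHandler(fh)
    summary: dict = {"config": dataclasses.asdict(config)}
    try:
        sites = _load_sites(config)
        molecules = sorted(next(iter(sites.values())).tables)
        depth, reps = config.rarefaction_depth, config.rarefaction_reps

        # --- environment pruning -----------------------------------------
        env_summary = {}
        pruned_env: dict[str, tables.EnvTable] = {}
        for site, data in sites.items():
            if data.env is None:
                continue
            pruned, removals = distances.prune_correlated(data.env)
            pruned_env[site] = pruned
            env_summary[site] = {
                "kept": pruned.variables,
                "removed": [r["removed"] for r in removals],
            }
        summary["environment_pruning"] = env_summary

        # --- rarefaction averaging ---------------------------------------
        avg: dict[tuple[str, str], tables.CommunityTable] = {}
        for site, data in sites.items():
            for mol, t in data.tables.items():
                a = tables.rarefaction_average(
                    t, depth, reps, seed=config.stage_seed("rarefaction")
                )
                avg[(site, mol)] = a
                tables.write_community(
                    a, out / f"avg_{site}_{mol}.tsv", format="classic-tsv"
                )
        summary["rarefaction"] = {
            "depth": depth, "reps": reps,
            "samples_retained": {f"{s}:{m}": avg[(s, m)].n_samples for (s, m) in avg},
        }

        # --- PERMANOVA + richness across land types ----------------------
        permanova_res = {}
        richness_res = {}
        for mol in molecules:
            pooled = tables.concat_samples([avg[(s, mol)] for s in sites])
            D = distances.canberra(pooled, averaged=config.canberra_averaged)
            pr = matrix_stats.permanova(
                D, pooled.metadata["site"], n_perm=config.n_perm_mantel,
                seed=config.stage_seed("permanova"),
            )
            permanova_res[mol] = pr.to_dict()
            rich = tables.richness(pooled, config.detection_threshold)
            by_site = {s: rich[pooled.metadata["site"] == s].to_numpy() for s in sites}
            F, df, p = group_stats.anova_oneway(by_site)
            richness_res[mol] = {
                "mean_by_site": {s: float(v.mean()) for s, v in by_site.items()},
                "anova": {"F": F, "df": list(df), "p": p},
                "tukey": group_stats.tukey_hsd(by_site).to_dict(orient="records"),
            }
        summary["permanova"] = permanova_res
        summary["richness"] = richness_res

        # --- similarity levels, decay, Mantel ----------------------------
        sim_levels = {}
        decay = {}
        for mol in molecules:
            groups = {}
            decay[mol] = {}
            for site in sites:
                a = avg[(site, mol)]
                sim = distances.canberra(a, averaged=config.canberra_averaged).to_similarity()
                groups[site] = group_stats.within_group_pairs(sim, a.sample_ids)
                geo = distances.geographic(a)
                fit = matrix_stats.decay_fit(
                    sim, geo, log10_distance=config.log10_distance,
                    n_perm=config.n_perm_mantel, seed=config.stage_seed("mantel"),
                )
                entry = {"geographic": fit.to_dict()}
                if site in pruned_env:
                    env_m = pruned_env[site]
                    aligned = data_env_for(sites[site], mol, env_m)
                    if aligned is not None and set(aligned.sample_ids) >= set(a.sample_ids):
                        env_sub = tables.EnvTable(aligned.values.loc[a.sample_ids])
                        esim = distances.gower_similarity(env_sub)
                        entry["environment"] = matrix_stats.decay_fit(
                            sim, esim, n_perm=config.n_perm_mantel,
                            seed=config.stage_seed("mantel"),
                        ).to_dict()
                        entry["partial_env_given_geo"] = matrix_stats.partial_mantel(
                            sim.to_dissimilarity(), esim.to_dissimilarity(), geo,
                            n_perm=config.n_perm_mantel, seed=config.stage_seed("mantel"),
                        ).to_dict()
                        entry["env_decay"] = matrix_stats.decay_fit(
                            esim, geo, log10_distance=config.log10_distance,
                            n_perm=config.n_perm_mantel, seed=config.stage_seed("mantel"),
                        ).to_dict()
                decay[mol][site] = entry
            F, df, p = group_stats.anova_oneway(groups)
            sim_levels[mol] = {
                "mean_by_site": {
                    s: {"mean": float(v.mean()),
                        "sem": float(v.std(ddof=1) / np.sqrt(v.size)),
                        "n_pairs": int(v.size)}
                    for s, v in groups.items()
                },
                "anova": {"F": F, "df": list(df), "p": p},
                "tukey": group_stats.tukey_hsd(groups).to_dict(orient="records"),
            }
            # slope comparisons vs forest
            fsite = config.forest_site
            for site in sites:
                if site == fsite:
                    continue
                af, at = avg[(fsite, mol)], avg[(site, mol)]
                simf = distances.canberra(af).to_similarity()
                simt = distances.canberra(at).to_similarity()
                pf = matrix_stats.decay_pairs(simf, distances.geographic(af),
                                              config.log10_distance)
                pt = matrix_stats.decay_pairs(simt, distances.geographic(at),
                                              config.log10_distance)
                ds = matrix_stats.diffslope(
                    pf, pt, n_perm=config.n_perm_diffslope,
                    seed=config.stage_seed("diffslope"),
                )
                decay[mol][site]["diffslope_vs_forest"] = ds.to_dict()
        summary["similarity"] = sim_levels
        summary["decay"] = decay

        # RNA vs DNA similarity contrast per site (paired t-test style)
        if set(molecules) >= {"RNA", "DNA"}:
            contrasts = {}
            for site in sites:
                aR = avg[(site, "RNA")]
                aD = avg[(site, "DNA")]
                vR = group_stats.within_group_pairs(
                    distances.canberra(aR).to_similarity(), aR.sample_ids)
                vD = group_stats.within_group_pairs(
                    distances.canberra(aD).to_similarity(), aD.sample_ids)
                t, df, p = group_stats.t_test_two_tailed(vR, vD)
                contrasts[site] = {"t": t, "df": df, "p": p,
                                   "mean_RNA": float(vR.mean()), "mean_DNA": float(vD.mean())}
            summary["rna_vs_dna"] = contrasts

        # --- mechanisms ---------------------------------------------------
        fsite = config.forest_site
        mech = {}
        for site in sites:
            if site == fsite:
                continue
            report = mechanisms.mechanism_report(
                sites[fsite].tables, sites[site].tables,
                depth=depth, n_reps=reps, seed=config.stage_seed("mechanisms"),
                alpha=config.diffabund_alpha, n_perm=config.n_perm_mantel,
                detection_threshold=config.detection_threshold,
            )
            mech[site] = report.to_dict()
            report.summary_frame().to_csv(out / f"mechanisms_{site}.tsv", sep="\t", index=False)
            for (mol, prov), o in report.outcomes.items():
                (out / f"removed_{site}_{mol}_{prov}.txt").write_text(
                    "\n".join(o.taxon_set.taxa) + "\n")
        summary["mechanisms"] = mech

        if config.make_figures:
            _decay_figures(avg, sites, config, out)

        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, default=float)
        return summary
    except Exception as exc:  # annotate with stage context
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        logging.getLogger("soilbeta").removeHandler(fh)
        fh.close()


def data_env_for(site_data: synthetic.SiteData, molecule: str,
                 env: tables.EnvTable) -> tables.EnvTable | None:
    """Re-label a (possibly pruned) core-level env table to one molecule's
    sample ids."""
    if env is None:
        return None
    t = site_data.tables[molecule]
    core = [s.rsplit("-", 1)[0] for s in t.sample_ids]
    if not set(core) <= set(env.values.index):
        return None
    values = env.values.loc[core].copy()
    values.index = t.sample_ids
    return tables.EnvTable(values)


def _decay_figures(avg, sites, config: RunConfig, out: Path) -> None:
    """Decay scatter per site/molecule; trend line only at Mantel p < 0.05."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    molecules = sorted(next(iter(sites.values())).tables)
    fig, axes = plt.subplots(len(molecules), len(sites),
                             figsize=(4 * len(sites), 3.5 * len(molecules)),
                             squeeze=False)
    for i, mol in enumerate(molecules):
        for j, site in enumerate(sites):
            a = avg[(site, mol)]
            sim = distances.canberra(a).to_similarity()
            geo = distances.geographic(a)
            x, y = matrix_stats.decay_pairs(sim, geo, config.log10_distance)
            fit = matrix_stats.decay_fit(sim, geo, config.log10_distance,
                                         n_perm=config.n_perm_mantel,
                                         seed=config.stage_seed("mantel"))
            ax = axes[i][j]
            ax.scatter(x, y, s=10, alpha=0.6)
            if fit.significant:
                xs = np.linspace(x.min(), x.max(), 10)
                ax.plot(xs, fit.intercept + fit.slope * xs, "k-")
            ax.set_title(f"{site} {mol} (r={fit.mantel_r:.2f}, p={fit.mantel_p:.3f})")
            ax.set_xlabel("log10 distance (m)" if config.log10_distance else "distance (m)")
            ax.set_ylabel("community similarity")
    fig.tight_layout()
    fig.savefig(out / "distance_decay.png", dpi=120)
    plt.close(fig)
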