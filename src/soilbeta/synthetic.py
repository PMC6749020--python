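"""Synthetic spatially explicit paired RNA/DNA soil communities.

Emulates the sampling design and statistical structure the analysis
pipeline assumes, so every stage is testable without field data:

* 13 samples per site at the corners of a 100 m quadrat with 10 m, 1 m and
  0.1 m quadrats nested at one corner;
* a spatially autocorrelated soil environment (Gaussian random field with
  exponential covariance) whose first variable is the niche axis; under
  land conversion the field gains independent per-sample variance, which
  destroys spatial structure while increasing total variance;
* log-normal taxon abundances filtered through Gaussian niche kernels on
  the environment axis;
* an RNA (active) layer restricted to the active taxon fraction with a
  sharpened environmental response, and a DNA layer mixing the live
  composition with a spatially flat relic/inactive pool;
* optional injected "newcomer" taxa (absent from the forest pool) and
  fold-amplified "bloomer" taxa in converted scenarios.

Counts are multinomial draws at per-sample sequencing depths, so raw
tables are integer and rows sum to their library size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .tables import CommunityTable, EnvTable

ENV_VAR_NAMES = ["pH", "om_pct", "P_ppm", "K_ppm", "CEC", "NO3_N", "S"]
REDUNDANT_VAR_NAMES = ["buffer_pH", "cation_sat_pct", "Ca_ppm", "Mg_ppm"]


@dataclass
class ScenarioConfig:
    """All knobs of the generator; defaults are the study conditions.

    Distances in meters; fractions in [0, 1]; folds >= 1. ``seed`` fixes
    the shared taxon pool, so scenarios built from one config draw their
    communities from the same regional species pool.
    """

    plot_size: float = 100.0
    quadrat_sizes: tuple[float, ...] = (10.0, 1.0, 0.1)
    n_taxa: int = 2000
    lognormal_sigma: float = 1.5
    n_niche_axes: int = 3
    niche_optimum_sd: float = 1.0
    niche_optimum_clip: float = 1.5
    niche_width_range: tuple[float, float] = (0.6, 1.2)
    responsiveness_beta: tuple[float, float] = (2.0, 1.0)
    env_ranges_m: tuple[float, ...] = (50.0,)
    env_nugget: float = 0.01
    n_env_vars: int = 7
    n_redundant_vars: int = 2
    env_axis_corr: float = 0.3
    disturbance: float = 6.0
    disturbance_axis: float = 2.0
    disturbance_shift: float = 7.0
    rna_active_fraction: float = 0.7
    rna_env_coupling: float = 2.0
    dna_relic_fraction: float = 0.4
    n_newcomers: int = 500
    injection_rel_abund: float = 0.02
    newcomer_occupancy: float = 0.25
    strong_n_newcomers: int = 200
    strong_injection_rel_abund: float = 0.25
    strong_newcomer_occupancy: float = 1.0
    n_bloomers: int = 50
    bloom_fold: float = 4.0
    bloom_occupancy_boost: float = 0.5
    depth_range: tuple[int, int] = (5000, 20000)
    shallow_fraction: float = 0.04
    rarefaction_depth: int = 3790
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rna_active_fraction", "dna_relic_fraction", "injection_rel_abund",
                     "newcomer_occupancy", "strong_newcomer_occupancy",
                     "bloom_occupancy_boost", "shallow_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bloom_fold < 1.0:
            raise ValueError("bloom_fold must be >= 1")
        if self.rna_env_coupling < 1.0:
            raise ValueError("rna_env_coupling must be >= 1")
        if list(self.quadrat_sizes) != sorted(self.quadrat_sizes, reverse=True):
            raise ValueError("quadrat sizes must be strictly decreasing")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Desk-scale configuration: same effect sizes (niche structure,
        coupling, relic fraction, bloom fold, injection share), smaller
        community and shallower sequencing so replicated studies run in
        seconds."""
        base = dict(
            n_taxa=250, n_newcomers=50, strong_n_newcomers=25, n_bloomers=25,
            depth_range=(1200, 2500), rarefaction_depth=800, seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TaxonPool:
    """Regional pool shared by every site simulated from one config."""

    taxon_ids: list[str]
    base_weights: np.ndarray      # log-normal heavy-tailed abundances
    optima: np.ndarray            # (taxa, axes) niche optima on the env axes
    widths: np.ndarray            # (taxa, axes) niche kernel widths
    responsiveness: np.ndarray    # in [0,1]: how strongly the niche kernel acts
    active: np.ndarray            # bool: contributes to the RNA layer
    relic_weights: np.ndarray     # spatially flat relic/inactive pool


@dataclass
class SiteData:
    """One simulated site: environment plus paired RNA/DNA count tables."""

    site: str
    env: EnvTable                      # indexed by core id
    tables: dict[str, CommunityTable]  # molecule -> table (ids suffixed -RNA/-DNA)

    def env_for(self, molecule: str) -> EnvTable:
        """Environment table re-labelled to match one molecule's samples."""
        t = self.tables[molecule]
        core = [s.rsplit("-", 1)[0] for s in t.sample_ids]
        values = self.env.values.loc[core].copy()
        values.index = t.sample_ids
        return EnvTable(values)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def nested_coords(config: ScenarioConfig | None = None) -> np.ndarray:
    """The 13 sampling points of one site: corners of the plot quadrat plus
    the three non-shared corners of each nested quadrat anchored at the
    origin corner."""
    config = config or ScenarioConfig()
    L = config.plot_size
    pts = [(0.0, 0.0), (L, 0.0), (0.0, L), (L, L)]
    for s in config.quadrat_sizes:
        pts.extend([(s, 0.0), (0.0, s), (s, s)])
    coords = np.array(pts)
    if len({tuple(p) for p in pts}) != len(pts):
        raise ValueError("degenerate quadrat sizes produce duplicate points")
    return coords


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

def simulate_environment(
    coords: np.ndarray,
    range_m: float | Sequence[float],
    nugget: float,
    n_vars: int,
    disturbance: float = 0.0,
    disturbance_axis: float | None = None,
    shift: float = 0.0,
    axis_corr: float = 0.6,
    seed: int = 0,
    n_redundant: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> EnvTable:
    """Gaussian-random-field soil variables on the sampling points.

    The first variable is the niche axis; the remaining variables mix the
    axis field (Pearson ``axis_corr``, the covariance structure of real
    soil chemistry suites) with their own independent GRFs. ``range_m``
    may be a single correlation range or a sequence: several equally
    weighted exponential components at log-spaced ranges give the nested
    (multi-scale) variogram of real soil, whose differences grow roughly
    linearly in log distance across the 0.1-141 m span of the sampling
    design. A nugget is added on the diagonal.

    Land conversion enters two ways: ``disturbance`` adds independent
    per-sample variance to every non-axis variable — nutrient patchiness
    from burning and planting that dissolves spatial structure while
    inflating total variance — while the axis receives the (typically
    smaller) ``disturbance_axis`` variance plus the directional mean
    ``shift``, the chronosequence chemistry change (rising pH, phosphorus)
    that pushes soils beyond the resident community's niche optima.
    ``n_redundant`` near-copies of the axis are appended to exercise
    collinearity pruning.
    """
    ranges = np.atleast_1d(np.asarray(range_m, dtype=float))
    if (ranges <= 0).any():
        raise ValueError("range must be positive")
    n = coords.shape[0]
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    C = sum(np.exp(-d / r) for r in ranges) / ranges.size + nugget * np.eye(n)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        C = C + 1e-8 * np.eye(n)
        L = np.linalg.cholesky(C)
    rng = np.random.default_rng(seed)
    own = L @ rng.standard_normal((n, n_vars))
    axis_field = own[:, 0]
    rho = float(np.clip(axis_corr, 0.0, 1.0))
    fields = np.empty_like(own)
    fields[:, 0] = axis_field
    fields[:, 1:] = rho * axis_field[:, None] + np.sqrt(1 - rho**2) * own[:, 1:]
    if disturbance_axis is None:
        disturbance_axis = disturbance
    if disturbance > 0:
        fields[:, 1:] += np.sqrt(disturbance) * rng.standard_normal((n, n_vars - 1))
    if disturbance_axis > 0:
        fields[:, 0] += np.sqrt(disturbance_axis) * rng.standard_normal(n)
    fields[:, 0] += shift
    cols = {}
    for k in range(n_vars):
        name = ENV_VAR_NAMES[k] if k < len(ENV_VAR_NAMES) else f"var{k}"
        cols[name] = fields[:, k]
    axis = fields[:, 0]
    for k in range(n_redundant):
        name = REDUNDANT_VAR_NAMES[k] if k < len(REDUNDANT_VAR_NAMES) else f"redundant{k}"
        cols[name] = 0.95 * axis + 0.15 * rng.standard_normal(n)
    ids = list(sample_ids) if sample_ids is not None else [f"s{i:02d}" for i in range(n)]
    return EnvTable(pd.DataFrame(cols, index=ids))


# ---------------------------------------------------------------------------
# Taxon pool and communities
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, sd: float, clip: float, shape) -> np.ndarray:
    """N(0, sd) redrawn into [-clip, clip] (no boundary atom)."""
    out = rng.normal(0.0, sd, shape)
    bad = np.abs(out) > clip
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > clip
    return out


def taxon_pool(config: ScenarioConfig) -> TaxonPool:
    """Draw the shared regional pool from the config seed."""
    rng = np.random.default_rng([config.seed, 101])
    m = config.n_taxa
    return TaxonPool(
        taxon_ids=[f"OTU{i:05d}" for i in range(m)],
        base_weights=rng.lognormal(0.0, config.lognormal_sigma, m),
        optima=_truncated_normal(rng, config.niche_optimum_sd,
                                 config.niche_optimum_clip,
                                 (m, config.n_niche_axes)),
        widths=rng.uniform(*config.niche_width_range, (m, config.n_niche_axes)),
        responsiveness=rng.beta(*config.responsiveness_beta, m),
        active=rng.random(m) < config.rna_active_fraction,
        relic_weights=rng.lognormal(0.0, config.lognormal_sigma, m),
    )


def _compositions(env_axes: np.ndarray, pool: TaxonPool, config: ScenarioConfig
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Expected RNA and DNA relative-abundance matrices (samples x taxa).

    Each taxon's weight mixes a flat component with its Gaussian niche
    kernel according to its responsiveness r: w = base * ((1-r) + r*k(e)).
    The kernel is a product over the niche axes (the first
    ``n_niche_axes`` environment variables), so community turnover
    integrates several soil gradients, as real multivariate niches do.
    The RNA (active) layer amplifies responsiveness — r' = 1-(1-r)^c with
    coupling c >= 1 — so the active community tracks the environment more
    tightly than the DNA-inferred one, which additionally carries the
    spatially flat relic pool.
    """
    env_axes = np.atleast_2d(env_axes)
    k_axes = pool.optima.shape[1]
    z = (env_axes[:, None, :k_axes] - pool.optima[None, :, :]) / pool.widths[None, :, :]
    kernel = np.exp(-0.5 * (z**2).sum(axis=2))
    r = pool.responsiveness[None, :]
    live_dna = pool.base_weights[None, :] * ((1 - r) + r * kernel)
    r_rna = 1.0 - (1.0 - r) ** config.rna_env_coupling
    rna = pool.base_weights[None, :] * ((1 - r_rna) + r_rna * kernel)
    rna = rna * pool.active[None, :]
    rna_sum = rna.sum(axis=1, keepdims=True)
    live_sum = live_dna.sum(axis=1, keepdims=True)
    if (rna_sum == 0).any() or (live_sum == 0).any():
        raise ValueError("degenerate all-zero expected composition")
    rna = rna / rna_sum
    live_dna = live_dna / live_sum
    relic = pool.relic_weights / pool.relic_weights.sum()
    dna = (1 - config.dna_relic_fraction) * live_dna + config.dna_relic_fraction * relic[None, :]
    return rna, dna


def _draw_depths(rng: np.random.Generator, n: int, config: ScenarioConfig) -> np.ndarray:
    lo, hi = config.depth_range
    depths = rng.integers(lo, hi + 1, n)
    shallow = rng.random(n) < config.shallow_fraction
    if shallow.any():
        depths[shallow] = rng.integers(
            max(1, int(0.2 * config.rarefaction_depth)),
            max(2, int(0.9 * config.rarefaction_depth)),
            int(shallow.sum()),
        )
    return depths


def simulate_community(
    env: EnvTable,
    config: ScenarioConfig,
    seed: int,
    pool: TaxonPool | None = None,
    site: str = "site",
    return_compositions: bool = False,
):
    """Draw paired RNA/DNA count tables for one site.

    The first ``n_niche_axes`` environment variables are the niche axes.
    Sample ids are the environment (core) ids suffixed with the molecule. With
    ``return_compositions=True`` the latent expected relative-abundance
    matrices are returned alongside the tables (the bloom mechanism acts
    on them).
    """
    pool = pool or taxon_pool(config)
    axes = env.values.iloc[:, : pool.optima.shape[1]].to_numpy(float)
    rna_p, dna_p = _compositions(axes, pool, config)
    rng = np.random.default_rng([seed, 202])
    coords = env.values.index
    tables: dict[str, CommunityTable] = {}
    comps = {"RNA": rna_p, "DNA": dna_p}
    for mol, P in (("RNA", rna_p), ("DNA", dna_p)):
        depths = _draw_depths(rng, len(coords), config)
        counts = np.vstack([
            rng.multinomial(depths[i], P[i]) for i in range(len(coords))
        ])
        ids = [f"{c}-{mol}" for c in coords]
        meta = pd.DataFrame(
            {
                "site": site,
                "molecule": mol,
                "x": np.nan,
                "y": np.nan,
            },
            index=pd.Index(ids, name="sample_id"),
        )
        tables[mol] = CommunityTable(
            pd.DataFrame(counts, index=ids, columns=pool.taxon_ids), meta
        )
    if return_compositions:
        return tables, comps
    return tables


# ---------------------------------------------------------------------------
# Conversion mechanisms
# ---------------------------------------------------------------------------

def apply_invasion(
    tables: dict[str, CommunityTable],
    n_newcomers: int,
    injection_rel_abund: float,
    occupancy: float,
    seed: int,
    prefix: str = "NEW",
) -> dict[str, CommunityTable]:
    """Inject novel taxa, absent from the regional pool, into a site.

    Each newcomer occupies a random ``occupancy`` fraction of the cores
    (shared across molecules, since a colonist is present in the soil of a
    core or not); within an occupied core the newcomer pool receives
    ``injection_rel_abund`` of the library, split among the newcomers
    present there by log-normal weights, and the resident counts are
    subsampled down so every library size is preserved exactly.
    """
    if n_newcomers == 0:
        return dict(tables)
    if occupancy <= 0:
        raise ValueError("occupancy must be positive")
    rng = np.random.default_rng([seed, 303])
    first = next(iter(tables.values()))
    cores = [s.rsplit("-", 1)[0] for s in first.sample_ids]
    n = len(cores)
    k = max(1, round(occupancy * n))
    present = np.zeros((n_newcomers, n), dtype=bool)
    for t in range(n_newcomers):
        present[t, rng.choice(n, size=k, replace=False)] = True
    weights = rng.lognormal(0.0, 1.0, n_newcomers)
    new_ids = [f"{prefix}{t:04d}" for t in range(n_newcomers)]

    out: dict[str, CommunityTable] = {}
    for mol, table in tables.items():
        arr = table.counts.to_numpy()
        arr = np.rint(arr).astype(np.int64)
        depths = arr.sum(axis=1)
        new_counts = np.zeros((n, n_newcomers), dtype=np.int64)
        resident = arr.copy()
        for j in range(n):
            who = present[:, j]
            if not who.any():
                continue
            total = int(round(injection_rel_abund * depths[j]))
            if total == 0:
                continue
            w = weights[who] / weights[who].sum()
            new_counts[j, who] = rng.multinomial(total, w)
            resident[j] = rng.multivariate_hypergeometric(arr[j], depths[j] - total)
        counts = pd.DataFrame(
            np.hstack([resident, new_counts]),
            index=table.counts.index,
            columns=list(table.counts.columns) + new_ids,
        )
        out[mol] = CommunityTable(counts, table.metadata)
    return out


def apply_bloom(
    tables: dict[str, CommunityTable],
    n_bloomers: int,
    fold: float,
    occupancy_boost: float,
    seed: int,
    compositions: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, CommunityTable], list[str]]:
    """Amplify resident taxa: the range-expansion mechanism.

    Bloomers are drawn from prevalent resident taxa (detected in at least
    half the cores, shared across molecules). Their *expected* relative
    abundances are multiplied by ``fold``, and ``occupancy_boost`` mixes
    each bloomer's per-sample expected share toward its site-wide mean —
    raising its occupancy and evening it out spatially, the range-expansion
    signature. Counts are then redrawn at the original library sizes, so
    depths are conserved exactly.

    ``compositions`` should be the latent expected relative-abundance
    matrices from :func:`simulate_community`; without them the observed
    relative abundances stand in (noisier, since the redraw then compounds
    sampling noise). With fold = 1 and boost = 0 the tables are returned
    unchanged. Returns the modified tables and the bloomer taxon ids.
    """
    rng = np.random.default_rng([seed, 404])
    first = next(iter(tables.values()))
    prevalence = sum(
        (t.counts > 0).groupby(
            [s.rsplit("-", 1)[0] for s in t.sample_ids]
        ).any().mean(axis=0)
        for t in tables.values()
    ) / len(tables)
    eligible = prevalence.index[prevalence >= 0.5]
    if len(eligible) < n_bloomers:
        eligible = prevalence.sort_values(ascending=False).index[: max(n_bloomers, 1)]
    if len(eligible) < n_bloomers:
        raise ValueError("fewer resident taxa than requested bloomers")
    bloomers = list(rng.choice(np.asarray(eligible, dtype=object), n_bloomers, replace=False))
    if fold == 1.0 and occupancy_boost == 0.0:
        return dict(tables), bloomers

    out: dict[str, CommunityTable] = {}
    for mol, table in tables.items():
        if compositions is not None and mol in compositions:
            W = np.array(compositions[mol], dtype=float, copy=True)
        else:
            W = table.counts.to_numpy(float).copy()
        depths = np.rint(table.counts.to_numpy().sum(axis=1)).astype(np.int64)
        cols = [table.counts.columns.get_loc(b) for b in bloomers]
        for c in cols:
            col = W[:, c]
            evened = (1 - occupancy_boost) * col + occupancy_boost * col.mean()
            W[:, c] = fold * evened
        P = W / W.sum(axis=1, keepdims=True)
        counts = np.vstack([
            rng.multinomial(depths[i], P[i]) for i in range(W.shape[0])
        ])
        out[mol] = CommunityTable(
            pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns),
            table.metadata,
        )
    return out, bloomers


# ---------------------------------------------------------------------------
# Scenario orchestration
# ---------------------------------------------------------------------------

ScenarioKind = Literal[
    "forest", "pristine", "converted", "bloom", "invasion", "invasion_strong",
    "bloom_invasion",
]


def simulate_site(
    config: ScenarioConfig,
    site: str,
    disturbed: bool = False,
    bloom: bool = False,
    invasion: str | None = None,  # None | "default" | "strong"
    seed: int = 0,
    pool: TaxonPool | None = None,
    env_seed: int | None = None,
) -> SiteData:
    """Simulate one site with its conversion mechanisms.

    ``env_seed`` pins the environmental field independently of the
    community draw, which is how a re-survey of the same site (the
    mechanism-attribution null) is simulated.
    """
    pool = pool or taxon_pool(config)
    coords = nested_coords(config)
    core_ids = [f"{site}-{i:02d}" for i in range(coords.shape[0])]
    env = simulate_environment(
        coords, config.env_ranges_m, config.env_nugget, config.n_env_vars,
        disturbance=config.disturbance if disturbed else 0.0,
        disturbance_axis=config.disturbance_axis if disturbed else 0.0,
        shift=config.disturbance_shift if disturbed else 0.0,
        axis_corr=config.env_axis_corr,
        seed=env_seed if env_seed is not None else seed * 7919 + 11,
        n_redundant=config.n_redundant_vars,
        sample_ids=core_ids,
    )
    tables, comps = simulate_community(
        env, config, seed=seed * 7919 + 13, pool=pool, site=site,
        return_compositions=True,
    )
    for mol, t in tables.items():
        t.metadata["x"] = np.repeat(coords[:, 0], 1)
        t.metadata["y"] = np.repeat(coords[:, 1], 1)
    bloomers: list[str] = []
    if bloom:
        tables, bloomers = apply_bloom(
            tables, config.n_bloomers, config.bloom_fold,
            config.bloom_occupancy_boost, seed=seed * 7919 + 17,
            compositions=comps,
        )
    if invasion == "default":
        tables = apply_invasion(
            tables, config.n_newcomers, config.injection_rel_abund,
            config.newcomer_occupancy, seed=seed * 7919 + 19,
        )
    elif invasion == "strong":
        tables = apply_invasion(
            tables, config.strong_n_newcomers, config.strong_injection_rel_abund,
            config.strong_newcomer_occupancy, seed=seed * 7919 + 19,
        )
    elif invasion is not None:
        raise ValueError(f"unknown invasion mode {invasion!r}")
    data = SiteData(site=site, env=env, tables=tables)
    data.injected_bloomers = bloomers  # type: ignore[attr-defined]
    return data


def simulate_pair(kind: ScenarioKind, config: ScenarioConfig, seed: int
                  ) -> tuple[SiteData, SiteData]:
    """A forest reference plus one target site under the given scenario.

    ``pristine`` simulates a re-survey of the same forest — identical
    environmental field, fresh community and sequencing draws — the null
    for mechanism attribution; the other kinds disturb the target's
    environment and optionally add bloom and/or invasion mechanisms.
    """
    pool = taxon_pool(config)
    forest = simulate_site(config, "forest", disturbed=False, seed=seed * 2 + 1, pool=pool)
    opts = {
        "forest": dict(disturbed=False),
        "pristine": dict(disturbed=False),
        "converted": dict(disturbed=True),
        "bloom": dict(disturbed=True, bloom=True),
        "invasion": dict(disturbed=True, invasion="default"),
        # invasion-only: no environmental disturbance, so the attribution
        # signal is the injected taxa themselves
        "invasion_strong": dict(disturbed=False, invasion="strong"),
        "bloom_invasion": dict(disturbed=True, bloom=True, invasion="default"),
    }
    if kind not in opts:
        raise ValueError(f"unknown scenario kind {kind!r}")
    env_seed = (seed * 2 + 1) * 7919 + 11 if kind == "pristine" else None
    target = simulate_site(config, kind, seed=seed * 2 + 2, pool=pool,
                           env_seed=env_seed, **opts[kind])
    return forest, target


def simulate_study(config: ScenarioConfig, seed: int | None = None) -> dict[str, SiteData]:
    """Three-site chronosequence: forest, burned (disturbed + bloom) and
    plantation (disturbed + bloom + newcomer injection)."""
    seed = config.seed if seed is None else seed
    pool = taxon_pool(config)
    return {
        "forest": simulate_site(config, "forest", seed=seed * 3 + 1, pool=pool),
        "burned": simulate_site(config, "burned", disturbed=True, bloom=True,
                                seed=seed * 3 + 2, pool=pool),
        "plantation": simulate_site(config, "plantation", disturbed=True, bloom=True,
                                    invasion="default", seed=seed * 3 + 3, pool=pool),
    }
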