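"""Generator of spatially explicit paired RNA/DNA communities."""

import numpy as np
import pytest

from soilbeta import ScenarioConfig, distances, matrix_stats, tables
from soilbeta.synthetic import (
    _compositions,
    apply_bloom,
    apply_invasion,
    nested_coords,
    simulate_community,
    simulate_environment,
    simulate_pair,
    simulate_site,
    simulate_study,
    taxon_pool,
)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_nested_coords_thirteen_distinct_points():
    coords = nested_coords()
    assert coords.shape == (13, 2)
    assert len({tuple(p) for p in coords}) == 13


def test_nested_coords_distance_extremes():
    coords = nested_coords()
    d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    off = d[np.triu_indices(13, 1)]
    assert off.min() == pytest.approx(0.1)
    assert off.max() == pytest.approx(100 * np.sqrt(2))


def test_nested_quadrats_share_origin_corner():
    coords = {tuple(p) for p in nested_coords()}
    assert (0.0, 0.0) in coords
    for s in (10.0, 1.0, 0.1):
        assert {(s, 0.0), (0.0, s), (s, s)} <= coords


def test_nondecreasing_quadrats_rejected():
    with pytest.raises(ValueError):
        ScenarioConfig(quadrat_sizes=(1.0, 10.0, 0.1))


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def test_structured_field_yields_env_decay():
    """Smooth within-plot field: env similarity decays with distance in
    >=90% of replicates."""
    coords = nested_coords()
    hits = 0
    n_rep = 50
    for s in range(n_rep):
        env = simulate_environment(coords, 200.0, 1e-4, 5, seed=s)
        from soilbeta.distances import DistanceMatrix, gower_similarity

        esim = gower_similarity(env)
        geo = DistanceMatrix(
            np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1)),
            env.sample_ids, "geographic")
        hits += matrix_stats.mantel(esim, geo, n_perm=99, seed=s).p_value < 0.05
    assert hits >= 0.9 * n_rep


def test_disturbance_destroys_structure_and_lowers_similarity():
    coords = nested_coords()
    from soilbeta.distances import DistanceMatrix, gower_similarity

    geo = DistanceMatrix(np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1)),
                         [f"s{i:02d}" for i in range(13)], "geographic")
    dead, dropped = 0, 0
    n_rep = 50
    for s in range(n_rep):
        calm = simulate_environment(coords, 50.0, 0.01, 5, seed=s)
        wild = simulate_environment(coords, 50.0, 0.01, 5, disturbance=6.0,
                                    disturbance_axis=2.0, shift=7.0, seed=s)
        dead += matrix_stats.mantel(gower_similarity(wild), geo,
                                    n_perm=99, seed=s).p_value >= 0.05
        dropped += (gower_similarity(wild).condensed().mean()
                    < gower_similarity(calm).condensed().mean())
    assert dead >= 0.8 * n_rep
    assert dropped >= 0.8 * n_rep


def test_nugget_only_field_has_flat_env_decay():
    coords = nested_coords()
    from soilbeta.distances import DistanceMatrix, gower_similarity

    slopes = []
    for s in range(30):
        env = simulate_environment(coords, 1e-3, 1.0, 5, seed=s)  # no spatial signal
        esim = gower_similarity(env)
        geo = DistanceMatrix(np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1)),
                             env.sample_ids, "geographic")
        fit = matrix_stats.decay_fit(esim, geo, n_perm=9, seed=s)
        slopes.append(fit.slope)
    assert abs(np.mean(slopes)) <= 3 * np.std(slopes) / np.sqrt(len(slopes)) + 1e-3


def test_redundant_variables_get_pruned(desk_config):
    site = simulate_site(desk_config, "forest", seed=1)
    pruned, log = distances.prune_correlated(site.env)
    removed = {r["removed"] for r in log}
    assert removed & {"buffer_pH", "cation_sat_pct", "pH"}
    assert len(pruned.variables) <= desk_config.n_env_vars


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def test_counts_are_integer_with_depths_in_range(desk_config):
    site = simulate_site(desk_config, "forest", seed=3)
    for t in site.tables.values():
        arr = t.counts.to_numpy()
        assert np.array_equal(arr, np.rint(arr))
        lo, hi = desk_config.depth_range
        sums = arr.sum(axis=1)
        # at most the configured shallow minority falls below the range
        assert (sums <= hi).all()
        assert np.mean(sums >= lo) >= 1 - 3 * desk_config.shallow_fraction


def test_fixed_seed_is_byte_identical(desk_config):
    a = simulate_site(desk_config, "forest", seed=9)
    b = simulate_site(desk_config, "forest", seed=9)
    for mol in a.tables:
        assert a.tables[mol].counts.equals(b.tables[mol].counts)
    assert a.env.values.equals(b.env.values)


def test_no_relic_no_coupling_collapses_rna_dna():
    cfg = ScenarioConfig.desk(seed=0, dna_relic_fraction=0.0, rna_env_coupling=1.0,
                              rna_active_fraction=1.0)
    pool = taxon_pool(cfg)
    axes = np.random.default_rng(0).normal(size=(5, pool.optima.shape[1]))
    rna, dna = _compositions(axes, pool, cfg)
    assert np.abs(rna - dna).sum(axis=1).max() == pytest.approx(0.0, abs=1e-12)


def test_rna_tracks_environment_more_than_dna(desk_config):
    """The headline RNA vs DNA contrast: partial Mantel of community to
    environment (controlling geography) is higher for RNA in >=80% of
    replicates."""
    hits = 0
    n_rep = 25
    for s in range(n_rep):
        site = simulate_site(desk_config, "forest", seed=1000 + s)
        pm = {}
        for mol in ("RNA", "DNA"):
            avg = tables.rarefaction_average(site.tables[mol],
                                             desk_config.rarefaction_depth, 15, seed=s)
            sim = distances.canberra(avg)
            env = site.env_for(mol)
            env = tables.EnvTable(env.values.loc[avg.sample_ids])
            esim = distances.gower_similarity(env)
            geo = distances.geographic(avg)
            pm[mol] = matrix_stats.partial_mantel(
                sim, esim.to_dissimilarity(), geo, n_perm=9, seed=s).statistic
        hits += pm["RNA"] > pm["DNA"]
    assert hits >= 0.8 * n_rep


# ---------------------------------------------------------------------------
# invasion and bloom
# ---------------------------------------------------------------------------

def test_invasion_identity_when_empty(desk_config):
    site = simulate_site(desk_config, "forest", seed=5)
    out = apply_invasion(site.tables, 0, 0.02, 0.25, seed=1)
    for mol in site.tables:
        assert out[mol].counts.equals(site.tables[mol].counts)


def test_invasion_preserves_depths_and_share(desk_config):
    site = simulate_site(desk_config, "forest", seed=6)
    before_depths = {m: t.counts.sum(axis=1) for m, t in site.tables.items()}
    out = apply_invasion(site.tables, 50, 0.02, 0.25, seed=2)
    for mol, t in out.items():
        assert np.allclose(t.counts.sum(axis=1), before_depths[mol])
        new_cols = [c for c in t.counts.columns if c.startswith("NEW")]
        assert len(new_cols) == 50
        share = (t.counts[new_cols].sum(axis=1) / t.counts.sum(axis=1)).mean()
        assert share == pytest.approx(0.02, rel=0.2)


def test_invasion_requires_positive_occupancy(desk_config):
    site = simulate_site(desk_config, "forest", seed=6)
    with pytest.raises(ValueError):
        apply_invasion(site.tables, 5, 0.02, 0.0, seed=0)


def test_bloom_identity_at_unit_fold(desk_config):
    site = simulate_site(desk_config, "forest", seed=7)
    out, bloomers = apply_bloom(site.tables, 10, 1.0, 0.0, seed=3)
    assert len(bloomers) == 10
    for mol in site.tables:
        assert out[mol].counts.equals(site.tables[mol].counts)


def test_bloom_preserves_depths_and_raises_bloomer_share(desk_config):
    site = simulate_site(desk_config, "forest", seed=8)
    out, bloomers = apply_bloom(site.tables, 25, 4.0, 0.5, seed=4)
    for mol in site.tables:
        assert np.allclose(out[mol].counts.sum(axis=1),
                           site.tables[mol].counts.sum(axis=1))
        before = site.tables[mol].counts[bloomers].sum().sum()
        after = out[mol].counts[bloomers].sum().sum()
        assert after > 1.5 * before


def test_bloom_scenario_is_homogenized(desk_config):
    """Mean pairwise similarity in the bloom scenario exceeds the forest
    baseline — the homogenization signature — in >=80% of replicates."""
    hits = 0
    n_rep = 15
    for s in range(n_rep):
        forest, blm = simulate_pair("bloom", desk_config, seed=2000 + s)
        af = tables.rarefaction_average(forest.tables["RNA"],
                                        desk_config.rarefaction_depth, 15, seed=s)
        ab = tables.rarefaction_average(blm.tables["RNA"],
                                        desk_config.rarefaction_depth, 15, seed=s)
        hits += (distances.canberra(ab).to_similarity().condensed().mean()
                 > distances.canberra(af).to_similarity().condensed().mean())
    assert hits >= 0.8 * n_rep


def test_study_builds_three_sites_with_shared_pool(desk_config):
    study = simulate_study(desk_config, seed=4)
    assert set(study) == {"forest", "burned", "plantation"}
    base = set(study["forest"].tables["RNA"].counts.columns)
    assert base <= set(study["plantation"].tables["RNA"].counts.columns)
    # plantation carries injected newcomers on top of the shared pool
    assert any(c.startswith("NEW") for c in study["plantation"].tables["RNA"].counts.columns)
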