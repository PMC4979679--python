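"""Synthetic gradient generator: scenarios, determinism and trait coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

import elevbeta as eb


def test_same_seed_same_output():
    cfg = eb.GradientSimConfig(n_species=20, n_years=2, seed=5)
    occ1, morph1 = eb.simulate_dataset(cfg)
    occ2, morph2 = eb.simulate_dataset(cfg)
    assert occ1.table.equals(occ2.table)
    assert morph1.equals(morph2)


def test_adding_years_preserves_earlier_strata():
    base = eb.GradientSimConfig(n_species=20, n_years=2, seed=5)
    longer = eb.GradientSimConfig(n_species=20, n_years=4, seed=5)
    t1 = eb.generate_occurrences(base).table
    t2 = eb.generate_occurrences(longer).table
    early = t2[t2["year"] <= 2].reset_index(drop=True)
    assert early.equals(t1.reset_index(drop=True))


def test_design_shape():
    cfg = eb.GradientSimConfig(n_species=15, n_years=2, seed=0)
    occ = eb.generate_occurrences(cfg)
    # 8 sites x 2 seasons x 2 years x 4 blocks
    assert len(occ.table) == 8 * 2 * 2 * 4
    assert occ.is_block_level
    assert len(occ.species) == 15


def test_nestedness_scenario_strict_subsets():
    cfg = eb.GradientSimConfig(
        n_species=10,
        site_elevations=(900, 1200, 1500, 1800),
        n_years=1,
        seasons=("wet",),
        scenario="nestedness",
        seed=3,
    )
    pooled = eb.pool_blocks(eb.generate_occurrences(cfg))
    sets = [pooled.assemblage(e, "wet", 1) for e in (900, 1200, 1500, 1800)]
    for lower, higher in zip(sets, sets[1:]):
        assert higher < lower  # strict subset going up the gradient


def test_nestedness_dry_season_still_nested():
    cfg = eb.GradientSimConfig(n_species=30, n_years=1, scenario="nestedness", seed=8)
    pooled = eb.pool_blocks(eb.generate_occurrences(cfg))
    elevs = pooled.elevations
    sets = [pooled.assemblage(e, "dry", 1) for e in elevs]
    for lower, higher in zip(sets, sets[1:]):
        assert higher <= lower
    assert all(sets)  # no empty assemblage


def test_nestedness_species_turnover_exactly_zero():
    cfg = eb.GradientSimConfig(n_species=40, n_years=1, scenario="nestedness", seed=9)
    pooled = eb.pool_blocks(eb.generate_occurrences(cfg))
    for season in ("wet", "dry"):
        mat = pooled.stratum_matrix(season, 1)
        elevs = list(mat.index)
        pairs = [(a, b) for i, a in enumerate(elevs) for b in elevs[i + 1 :]]
        for trip in eb.species_beta_matrix(mat, pairs):
            assert trip.beta_sim == 0.0


def test_turnover_distant_sites_high_simpson():
    """Two sites 2100 m apart with 150-m niche breadth share almost nothing."""
    sims = []
    for seed in range(200):
        cfg = eb.GradientSimConfig(
            n_species=92,
            site_elevations=(900, 3000),
            n_years=1,
            seasons=("wet",),
            n_blocks=1,
            niche_breadth=150.0,
            scenario="turnover",
            seed=seed,
        )
        pooled = eb.pool_blocks(eb.generate_occurrences(cfg))
        mat = pooled.stratum_matrix("wet", 1)
        rows = mat.to_numpy(dtype=bool)
        if not (rows[0].any() and rows[1].any()):
            continue
        sims.append(eb.species_beta_pair(
            mat.columns[rows[0]], mat.columns[rows[1]]
        ).beta_sim)
    assert len(sims) > 150
    assert np.mean(sims) > 0.9


def test_pooling_recovers_site_level_presence():
    cfg = eb.GradientSimConfig(n_species=25, n_years=1, seed=4)
    occ = eb.generate_occurrences(cfg)
    pooled = eb.pool_blocks(occ)
    block_union = (
        occ.table.groupby(["elevation_m", "season", "year"])[occ.species].max()
    )
    site = pooled.table.set_index(["elevation_m", "season", "year"])[occ.species]
    assert site.sort_index().equals(block_union.sort_index().astype(site.dtypes.iloc[0]))


def test_eyeless_fraction_exact_count():
    cfg = eb.GradientSimConfig(n_species=100, n_years=1, eyeless_fraction=0.1, seed=2)
    occ, morph = eb.simulate_dataset(cfg)
    per_species = morph.groupby("species_id")[
        ["interocular_distance", "head_width_across_eyes", "mandible_length"]
    ].max()
    eyeless = (per_species == 0).all(axis=1)
    assert int(eyeless.sum()) == 10


def test_morphology_invariants():
    cfg = eb.GradientSimConfig(n_species=30, n_years=1, seed=6)
    occ, morph = eb.simulate_dataset(cfg)
    assert (morph[["webers_length", "hind_femur_length", "hind_tibia_length"]] > 0).all().all()
    assert (morph["interocular_distance"] <= morph["head_width_across_eyes"] + 1e-12).all()
    assert morph.groupby("species_id").size().eq(cfg.n_individuals).all()


def test_zero_coupling_traits_independent_of_elevation():
    rs = []
    for seed in range(50):
        cfg = eb.GradientSimConfig(n_species=60, n_years=1, seasons=("wet",),
                                   trait_coupling=0.0, seed=seed)
        occ, morph = eb.simulate_dataset(cfg)
        traits = eb.compute_trait_indices(morph)
        opt = occ.species_meta.loc[traits.index, "optimum_elevation_m"]
        rs.append(pearsonr(opt, traits["relative_leg_length"]).statistic)
    rs = np.asarray(rs)
    # correlations centre on zero; with 60 species, |r| ~ 0.13 SD
    assert abs(rs.mean()) < 0.06
    crit = 2.0 / np.sqrt(60)
    assert np.mean(np.abs(rs) > crit) <= 0.15


def test_full_coupling_contracts_high_elevation_traits():
    wins = 0
    n_rep = 100
    for seed in range(n_rep):
        cfg = eb.GradientSimConfig(n_species=92, n_years=1, seasons=("wet",),
                                   trait_coupling=1.0, seed=seed)
        occ, morph = eb.simulate_dataset(cfg)
        traits = eb.compute_trait_indices(morph)
        pooled = eb.pool_blocks(occ)
        bottom = list(pooled.assemblage(900, "wet", 1))
        top = list(pooled.assemblage(3000, "wet", 1))
        if len(top) < 3 or len(bottom) < 3:
            continue
        v_top = traits.loc[top, "relative_leg_length"].var()
        v_bottom = traits.loc[bottom, "relative_leg_length"].var()
        wins += v_top < v_bottom
    assert wins >= 0.95 * n_rep


def test_occurrence_csv_round_trip(tmp_path):
    cfg = eb.GradientSimConfig(n_species=12, n_years=1, seed=1)
    occ = eb.generate_occurrences(cfg)
    path = tmp_path / "occ.csv"
    occ.to_csv(path)
    back = eb.OccurrenceSet.from_csv(path)
    assert back.table[back.species].equals(occ.table[occ.species].astype(back.table[back.species].dtypes.iloc[0]))
    assert back.species == occ.species


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(site_elevations=(900, 900, 1200)),
        dict(n_species=1),
        dict(trait_coupling=1.5),
        dict(scenario="chaos"),
        dict(niche_breadth=-1.0),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(eb.ConfigError):
        eb.GradientSimConfig(**kwargs)


def test_vanishing_expected_richness_rejected():
    cfg = eb.GradientSimConfig(n_species=10, niche_breadth=1.0, scenario="turnover")
    with pytest.raises(eb.ConfigError, match="richness"):
        eb.generate_occurrences(cfg)
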