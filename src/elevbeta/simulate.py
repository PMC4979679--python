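"""Synthetic elevational-gradient assemblages and morphological measurements.

Emulates a montane survey design: eight sites every 300 m of elevation from
900 to 3000 m a.s.l., each sampled in two seasons (wet/dry) over seven years
with four replicate blocks per site, and a regional pool of 92 species with
six raw morphological measurements per individual (up to six individuals per
species).  Three occupancy scenarios provide known ground truth for the
downstream beta-diversity partition:

* ``turnover`` — each species has a Gaussian occupancy curve around an
  elevational optimum, producing distance decay dominated by replacement.
* ``nestedness`` — species are ordered by elevational ceiling so every higher
  site's pool is a subset of every lower site's pool (species turnover
  component exactly zero).
* ``neutral`` — each site independently draws species at a fixed target
  richness; co-occurrence carries no signal (null-model calibration case).

``trait_coupling`` controls how strongly species' trait indices contract
toward the pool centroid with their elevational optimum: 0 makes traits
independent of elevation, 1 makes high-elevation species functionally nested
within low-elevation ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .occurrences import OccurrenceSet

_SPECIES_STREAM = 0
_OCCURRENCE_STREAM = 1
_MORPHOLOGY_STREAM = 2

#: Species-level base distributions for the four trait indices. Weber's length
#: is log-normal (mm); the other indices are uniform on ranges spanning values
#: typical of epigaeic ant faunas.
_LOG_WL_MEAN, _LOG_WL_SD = np.log(1.3), 0.35
_EYE_POSITION_RANGE = (0.05, 0.30)
_LEG_LENGTH_RANGE = (0.8, 1.8)
_MANDIBLE_RANGE = (0.15, 0.60)
#: Head width across eyes as a fraction of Weber's length.
_HEAD_WIDTH_FRACTION = 0.35


@dataclass(frozen=True)
class GradientSimConfig:
    """Study-design and scenario parameters for the simulator.

    Defaults mirror the emulated survey: 92 species, 8 sites at 300-m steps
    from 900 to 3000 m a.s.l., 2 seasons x 7 years x 4 blocks, six individuals
    measured per species.
    """

    n_species: int = 92
    site_elevations: tuple = tuple(range(900, 3001, 300))
    n_years: int = 7
    seasons: tuple = ("wet", "dry")
    n_blocks: int = 4
    scenario: str = "turnover"
    trait_coupling: float = 0.0
    niche_breadth: float = 400.0
    dry_season_factor: float = 0.7
    neutral_occupancy: float = 0.30
    block_occupancy: float = 0.7
    eyeless_fraction: float = 0.05
    n_individuals: int = 6
    measurement_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        elev = np.asarray(self.site_elevations, dtype=float)
        if elev.size < 2 or not (np.diff(elev) > 0).all():
            raise ConfigError("site_elevations must be strictly increasing with >= 2 sites")
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if not 0.0 <= self.trait_coupling <= 1.0:
            raise ConfigError("trait_coupling must lie in [0, 1]")
        if self.scenario not in ("turnover", "nestedness", "neutral"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.niche_breadth <= 0:
            raise ConfigError("niche_breadth must be positive")
        if not 0.0 < self.dry_season_factor <= 1.0:
            raise ConfigError("dry_season_factor must lie in (0, 1]")
        if not 0.0 < self.block_occupancy <= 1.0:
            raise ConfigError("block_occupancy must lie in (0, 1]")
        if not 0.0 <= self.eyeless_fraction <= 1.0:
            raise ConfigError("eyeless_fraction must lie in [0, 1]")
        if self.n_years < 1 or self.n_blocks < 1 or self.n_individuals < 1:
            raise ConfigError("n_years, n_blocks and n_individuals must be >= 1")
        if not self.seasons:
            raise ConfigError("at least one season label is required")

    @property
    def elevations(self) -> np.ndarray:
        return np.asarray(self.site_elevations, dtype=float)

    def season_factor(self, season: str) -> float:
        return self.dry_season_factor if season == "dry" else 1.0


def _rng(config: GradientSimConfig, *key: int) -> np.random.Generator:
    """Deterministic substream of the master seed; adding years or seasons
    never perturbs the draws of earlier strata."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def species_ids(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(1, n + 1)]


def _species_attributes(config: GradientSimConfig) -> pd.DataFrame:
    """Per-species latent attributes (optimum, ceiling, eyelessness).

    Drawn once per simulation from a dedicated stream so occurrence and
    morphology generation share the same species identities.
    """
    rng = _rng(config, _SPECIES_STREAM)
    elev = config.elevations
    n = config.n_species
    n_sites = elev.size

    optimum = rng.uniform(
        elev[0] - config.niche_breadth, elev[-1] + config.niche_breadth, size=n
    )
    ceilings = 1 + rng.integers(0, n_sites, size=n)
    if n >= n_sites:
        # Guarantee every ceiling level is represented so site pools along the
        # gradient are strictly nested, not merely nested.
        ceilings[:n_sites] = rng.permutation(n_sites) + 1
    neutral_optimum = rng.uniform(elev[0], elev[-1], size=n)

    n_eyeless = int(round(config.eyeless_fraction * n))
    eyeless = np.zeros(n, dtype=bool)
    if n_eyeless:
        eyeless[rng.choice(n, size=n_eyeless, replace=False)] = True

    if config.scenario == "turnover":
        scenario_optimum = optimum
    elif config.scenario == "nestedness":
        scenario_optimum = elev[ceilings - 1]
    else:
        scenario_optimum = neutral_optimum

    return pd.DataFrame(
        {
            "optimum_elevation_m": scenario_optimum,
            "ceiling_index": ceilings,
            "eyeless": eyeless,
        },
        index=species_ids(n),
    )


def _validate_expected_richness(config: GradientSimConfig) -> None:
    factor = min(config.season_factor(s) for s in config.seasons)
    elev = config.elevations
    if config.scenario == "turnover":
        grid = np.linspace(
            elev[0] - config.niche_breadth, elev[-1] + config.niche_breadth, 2001
        )
        for e in elev:
            p = np.exp(-0.5 * ((e - grid) / config.niche_breadth) ** 2)
            if config.n_species * p.mean() * factor < 1.0:
                raise ConfigError(
                    f"expected richness below 1 at {e:.0f} m; widen niche_breadth "
                    "or add species"
                )
    elif config.scenario == "neutral":
        if config.neutral_occupancy * config.n_species * factor < 1.0:
            raise ConfigError("expected neutral richness below 1 per site")
    # Nestedness guarantees a full pool at the lowest site and at least one
    # species at the highest (the maximal ceiling is exempt from reduction).


def _stratum_presence(
    config: GradientSimConfig,
    attrs: pd.DataFrame,
    season: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Site-level presence (n_sites x n_species boolean) for one stratum."""
    elev = config.elevations
    n_sites, n = elev.size, config.n_species
    factor = config.season_factor(season)

    if config.scenario == "turnover":
        opt = attrs["optimum_elevation_m"].to_numpy()
        p = np.exp(-0.5 * ((elev[:, None] - opt[None, :]) / config.niche_breadth) ** 2)
        return rng.random((n_sites, n)) < p * factor

    if config.scenario == "nestedness":
        ceilings = attrs["ceiling_index"].to_numpy().copy()
        if factor < 1.0:
            # Season effect as a stochastic one-step range contraction; this
            # preserves the scenario's strict-subset structure, which a
            # multiplicative thinning would destroy.
            reduce = rng.random(n) < (1.0 - factor)
            reduce[int(np.argmax(ceilings))] = False  # keep the top site occupied
            ceilings = np.maximum(ceilings - reduce.astype(int), 1)
        return np.arange(1, n_sites + 1)[:, None] <= ceilings[None, :]

    richness = max(1, int(round(config.neutral_occupancy * n * factor)))
    present = np.zeros((n_sites, n), dtype=bool)
    for s in range(n_sites):
        present[s, rng.choice(n, size=richness, replace=False)] = True
    return present


def generate_occurrences(config: GradientSimConfig) -> OccurrenceSet:
    """Block-level binary incidence for the full survey design.

    Presence is decided at the site level per (season, year) stratum, then
    allocated to replicate blocks with per-block inclusion probability
    ``block_occupancy`` and at least one block forced, so pooling blocks
    recovers the site-level assemblage exactly.
    """
    _validate_expected_richness(config)
    attrs = _species_attributes(config)
    ids = list(attrs.index)
    n_sites = config.elevations.size

    frames = []
    for yi in range(config.n_years):
        year = yi + 1
        for si, season in enumerate(config.seasons):
            rng = _rng(config, _OCCURRENCE_STREAM, yi, si)
            present = _stratum_presence(config, attrs, season, rng)
            blocks = rng.random((n_sites, config.n_species, config.n_blocks))
            blocks = blocks < config.block_occupancy
            # Force every present species into at least one block.
            missing = np.argwhere(present & ~blocks.any(axis=2))
            for s, k in missing:
                blocks[s, k, rng.integers(config.n_blocks)] = True
            incidence = present[:, :, None] & blocks

            for s in range(n_sites):
                for blk in range(config.n_blocks):
                    row = {
                        "elevation_m": config.site_elevations[s],
                        "season": season,
                        "year": year,
                        "block": blk + 1,
                    }
                    row.update(dict(zip(ids, incidence[s, :, blk].astype(np.int8))))
                    frames.append(row)
    table = pd.DataFrame(frames)
    return OccurrenceSet(table, species_meta=attrs)


def generate_morphology(config: GradientSimConfig, occ: OccurrenceSet) -> pd.DataFrame:
    """Individual-level morphological measurements for the simulated pool.

    Species mean indices are drawn from the pool distributions and, with
    ``trait_coupling > 0``, contracted toward the pool centroid in proportion
    to the species' elevational optimum (so high-elevation species become
    functionally nested).  Individual measurements add multiplicative
    log-normal noise (CV ``measurement_cv``).  Eyeless species have both eye
    measurements and the mandible length exactly zero.
    """
    if occ.species_meta is None:
        raise ConfigError("occurrence set lacks species metadata; generate it first")
    attrs = occ.species_meta
    rng = _rng(config, _MORPHOLOGY_STREAM)
    n = len(attrs)
    elev = config.elevations

    log_wl = rng.normal(_LOG_WL_MEAN, _LOG_WL_SD, size=n)
    eye_pos = rng.uniform(*_EYE_POSITION_RANGE, size=n)
    leg = rng.uniform(*_LEG_LENGTH_RANGE, size=n)
    mandible = rng.uniform(*_MANDIBLE_RANGE, size=n)

    if config.trait_coupling > 0:
        opt = attrs["optimum_elevation_m"].to_numpy()
        rel = np.clip((opt - elev[0]) / (elev[-1] - elev[0]), 0.0, 1.0)
        scale = 1.0 - config.trait_coupling * rel
        centers = (
            _LOG_WL_MEAN,
            np.mean(_EYE_POSITION_RANGE),
            np.mean(_LEG_LENGTH_RANGE),
            np.mean(_MANDIBLE_RANGE),
        )
        log_wl = centers[0] + scale * (log_wl - centers[0])
        eye_pos = centers[1] + scale * (eye_pos - centers[1])
        leg = centers[2] + scale * (leg - centers[2])
        mandible = centers[3] + scale * (mandible - centers[3])

    wl = np.exp(log_wl)
    head_width = _HEAD_WIDTH_FRACTION * wl
    eye_gap = eye_pos * wl  # head width minus interocular distance
    femur = tibia = leg * wl / 2.0
    mandible_len = mandible * head_width
    eyeless = attrs["eyeless"].to_numpy()

    cv = config.measurement_cv
    k = config.n_individuals
    rows = []
    for s, sid in enumerate(attrs.index):
        noise = np.exp(rng.normal(0.0, cv, size=(k, 6)))
        wl_i = wl[s] * noise[:, 0]
        hw_i = head_width[s] * noise[:, 1]
        gap_i = eye_gap[s] * noise[:, 2]
        io_i = np.maximum(hw_i - gap_i, 0.0)
        fem_i = femur[s] * noise[:, 3]
        tib_i = tibia[s] * noise[:, 4]
        ml_i = mandible_len[s] * noise[:, 5]
        if eyeless[s]:
            hw_i = io_i = ml_i = np.zeros(k)
        for ind in range(k):
            rows.append(
                {
                    "species_id": sid,
                    "individual_id": f"{sid}_i{ind + 1}",
                    "webers_length": wl_i[ind],
                    "interocular_distance": io_i[ind],
                    "head_width_across_eyes": hw_i[ind],
                    "hind_femur_length": fem_i[ind],
                    "hind_tibia_length": tib_i[ind],
                    "mandible_length": ml_i[ind],
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(config: GradientSimConfig) -> tuple[OccurrenceSet, pd.DataFrame]:
    """Occurrences and morphology for one simulated survey."""
    occ = generate_occurrences(config)
    return occ, generate_morphology(config, occ)


def write_morphology_csv(morphology: pd.DataFrame, path) -> None:
    morphology.to_csv(path, index=False)


def read_morphology_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
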