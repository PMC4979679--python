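"""End-to-end orchestration of the beta-diversity study design.

Blocks are pooled into site-level assemblages per (season, year) stratum,
species-poor or geometrically degenerate assemblages are filtered out, site
pairs are formed (against the lowest retained elevation, or all pairwise),
and observed plus null-standardized species and functional metrics are
emitted as one tidy row per pair and composition.

Comparisons are always made within a (season, year) stratum, never across
years, matching the per-stratum null construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta import species_beta_pair
from .errors import ConfigError, HullDegenerate, HullInfeasible
from .hulls import assemblage_hull, functional_beta_pair
from .nulls import METRICS, null_distributions, ses
from .occurrences import OccurrenceSet, pool_blocks
from .simulate import GradientSimConfig, simulate_dataset
from .traits import TraitSpace, compute_trait_indices, pcoa, species_distance_matrix

RESULT_COLUMNS = (
    "year",
    "season",
    "composition",
    "base_elevation_m",
    "comparison_elevation_m",
    "delta_elevation_m",
    "beta_sor",
    "beta_sim",
    "beta_sne",
    "ses_sor",
    "ses_sim",
    "ses_sne",
    "n_null",
    "ses_undefined",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full analysis.

    ``n_axes`` is the number of synthetic-trait axes used for hulls (and the
    richness filter threshold ``n_axes + 1``); ``n_iter`` the null-model
    iterations per stratum; ``mode`` either ``vs_base`` (lowest retained
    elevation against all higher sites) or ``all_pairwise``.
    """

    n_axes: int = 4
    n_iter: int = 1000
    mode: str = "vs_base"
    seed: int = 0
    swap_multiplier: int = 10
    compositions: tuple = ("species", "functional")

    def __post_init__(self) -> None:
        if self.mode not in ("vs_base", "all_pairwise"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_iter < 2:
            raise ConfigError("n_iter must be at least 2")
        unknown = set(self.compositions) - {"species", "functional"}
        if unknown or not self.compositions:
            raise ConfigError(f"invalid compositions {self.compositions!r}")


@dataclass
class Exclusion:
    """One assemblage dropped by the hull filter, with the reason."""

    elevation_m: float
    season: str
    year: object
    richness: int
    reason: str


@dataclass
class PipelineResult:
    results: pd.DataFrame
    exclusions: list[Exclusion]
    stratum_errors: list[tuple] = field(default_factory=list)
    trait_space: TraitSpace | None = None
    traits: pd.DataFrame | None = None

    def write_results(self, path) -> None:
        self.results.to_csv(path, index=False, float_format="%.10g")

    def write_exclusion_log(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.exclusions:
                fh.write(
                    f"excluded elevation={e.elevation_m} season={e.season} "
                    f"year={e.year} richness={e.richness}: {e.reason}\n"
                )


def filter_hullable(
    pooled: OccurrenceSet,
    space: TraitSpace | None = None,
    n_axes: int = 4,
) -> tuple[OccurrenceSet, list[Exclusion]]:
    """Drop assemblages that cannot be projected as a convex hull.

    An assemblage needs at least ``n_axes + 1`` species (geometric necessity)
    and, when a trait space is supplied, an affinely non-degenerate point set.
    """
    if pooled.is_block_level:
        raise ConfigError("filter_hullable expects pooled (site-level) data")
    species = pooled.species
    keep = []
    exclusions = []
    for idx, row in pooled.table.iterrows():
        present = [s for s in species if row[s] > 0]
        richness = len(present)
        meta = (row["elevation_m"], row["season"], row["year"])
        if richness < n_axes + 1:
            exclusions.append(Exclusion(*meta, richness, "too few species for a convex hull"))
            continue
        if space is not None:
            try:
                assemblage_hull(present, space, n_axes=n_axes)
            except (HullInfeasible, HullDegenerate) as exc:
                exclusions.append(Exclusion(*meta, richness, str(exc)))
                continue
        keep.append(idx)
    if not keep:
        warnings.warn("hull filter removed every assemblage")
    retained = OccurrenceSet(
        pooled.table.loc[keep].reset_index(drop=True), species_meta=pooled.species_meta
    )
    return retained, exclusions


def build_pairs(pooled: OccurrenceSet, mode: str = "vs_base") -> dict[tuple, list[tuple]]:
    """Site pairs per (season, year) stratum.

    ``vs_base`` pairs the lowest *retained* elevation in the stratum with each
    higher site; ``all_pairwise`` returns every unordered pair (lower
    elevation first).  Strata with fewer than two retained sites are skipped
    with a warning.
    """
    if mode not in ("vs_base", "all_pairwise"):
        raise ConfigError(f"unknown mode {mode!r}")
    out = {}
    for season, year in pooled.strata():
        elevs = sorted(pooled.stratum_matrix(season, year).index)
        if len(elevs) < 2:
            warnings.warn(f"stratum ({season}, {year}) has fewer than two sites; skipped")
            continue
        base = elevs[0]
        if mode == "vs_base":
            out[(season, year)] = [(base, e) for e in elevs[1:]]
        else:
            out[(season, year)] = [
                (elevs[i], elevs[j])
                for i in range(len(elevs))
                for j in range(i + 1, len(elevs))
            ]
    return out


def _season_codes(occ: OccurrenceSet) -> dict[str, int]:
    return {s: k for k, s in enumerate(sorted(occ.table["season"].unique()))}


def _stratum_rows(
    matrix: pd.DataFrame,
    space: TraitSpace | None,
    pairs: list[tuple],
    season: str,
    year,
    config: PipelineConfig,
    season_code: int,
) -> list[dict]:
    species = np.asarray(matrix.columns, dtype=object)
    bools = matrix.to_numpy(dtype=bool)
    site_species = {site: species[bools[k]] for k, site in enumerate(matrix.index)}

    rows = []
    for comp_idx, composition in enumerate(config.compositions):
        if composition == "functional" and space is None:
            raise ConfigError("functional composition requires morphology data")
        rng = np.random.default_rng(
            np.random.SeedSequence(
                config.seed, spawn_key=(3, comp_idx, int(year), season_code)
            )
        )
        if composition == "species":
            observed = {
                p: species_beta_pair(site_species[p[0]], site_species[p[1]], pair=p)
                for p in pairs
            }
        else:
            hulls = {
                site: assemblage_hull(sp, space, n_axes=config.n_axes, site_id=site)
                for site, sp in site_species.items()
            }
            observed = {
                p: functional_beta_pair(hulls[p[0]], hulls[p[1]], pair=p) for p in pairs
            }
        nulls = null_distributions(
            matrix,
            space,
            pairs,
            n_iter=config.n_iter,
            composition=composition,
            seed=rng,
            n_axes=config.n_axes,
            swap_multiplier=config.swap_multiplier,
        )
        by_pair: dict[tuple, dict[str, object]] = {}
        for nd in nulls:
            by_pair.setdefault(nd.pair, {})[nd.metric] = nd
        for p in pairs:
            trip = observed[p]
            records = {m: ses(v, by_pair[p][m]) for m, v in zip(METRICS, trip)}
            rows.append(
                {
                    "year": year,
                    "season": season,
                    "composition": composition,
                    "base_elevation_m": p[0],
                    "comparison_elevation_m": p[1],
                    "delta_elevation_m": abs(p[1] - p[0]),
                    "beta_sor": trip.beta_sor,
                    "beta_sim": trip.beta_sim,
                    "beta_sne": trip.beta_sne,
                    "ses_sor": records["sor"].ses,
                    "ses_sim": records["sim"].ses,
                    "ses_sne": records["sne"].ses,
                    "n_null": records["sor"].n_null,
                    "ses_undefined": any(r.undefined for r in records.values()),
                }
            )
    return rows


def run_pipeline(
    occ: OccurrenceSet,
    morphology: pd.DataFrame | None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Observed and standardized beta-diversity partition for a full survey.

    ``occ`` may be block- or site-level; blocks are pooled by union.  With
    ``morphology=None`` only species composition can be requested.  Failures
    are isolated per stratum: an error in one (season, year) is logged in
    ``stratum_errors`` and does not abort the others.
    """
    pooled = pool_blocks(occ)

    space = None
    traits = None
    if morphology is not None:
        traits = compute_trait_indices(morphology)
        space = pcoa(species_distance_matrix(traits))
    elif "functional" in config.compositions:
        raise ConfigError("functional composition requires a morphology table")

    retained, exclusions = filter_hullable(pooled, space, n_axes=config.n_axes)
    pairs = build_pairs(retained, config.mode)
    codes = _season_codes(retained)

    rows: list[dict] = []
    errors: list[tuple] = []
    for (season, year), stratum_pairs in pairs.items():
        matrix = retained.stratum_matrix(season, year)
        try:
            rows.extend(
                _stratum_rows(matrix, space, stratum_pairs, season, year, config, codes[season])
            )
        except ConfigError:
            raise
        except Exception as exc:  # pragma: no cover - per-stratum isolation
            errors.append(((season, year), repr(exc)))
    results = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    results = results.sort_values(
        ["year", "season", "composition", "base_elevation_m", "comparison_elevation_m"],
        kind="mergesort",
    ).reset_index(drop=True)
    return PipelineResult(results, exclusions, errors, space, traits)


def run_simulated(
    sim_config: GradientSimConfig,
    pipeline_config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Simulate a survey under ``sim_config`` and run the full analysis."""
    occ, morphology = simulate_dataset(sim_config)
    needs_morphology = "functional" in pipeline_config.compositions
    return run_pipeline(occ, morphology if needs_morphology else None, pipeline_config)
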