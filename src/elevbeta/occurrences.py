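"""Binary site-by-species incidence tables with survey metadata.

The central container is :class:`OccurrenceSet`, a thin wrapper around a tidy
:class:`pandas.DataFrame` in which each row is one sampled assemblage (a
replicate block, or a pooled elevational site) and each species is a 0/1
column.  Metadata columns identify the elevation (m a.s.l.), season, year and,
at block level, the replicate block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Recognised metadata columns, in canonical order. ``block`` is present only
#: in block-level tables and disappears after pooling.
META_COLUMNS = ("elevation_m", "season", "year", "block")

_REQUIRED_META = ("elevation_m", "season", "year")


@dataclass
class OccurrenceSet:
    """Binary incidence of species across sampled assemblages.

    Parameters
    ----------
    table:
        One row per assemblage.  Must contain the metadata columns
        ``elevation_m``, ``season`` and ``year`` (plus ``block`` for
        block-level data); every remaining column is a species with cells
        in {0, 1}.
    species_meta:
        Optional per-species metadata (indexed by species id).  The synthetic
        generator stores each species' elevational optimum and eyelessness
        here; it is not required for any analysis step.
    """

    table: pd.DataFrame
    species_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_META if c not in self.table.columns]
        if missing:
            raise ConfigError(f"occurrence table lacks metadata columns {missing}")
        sp = self.species
        if not sp:
            raise ConfigError("occurrence table has no species columns")
        values = self.table[sp].to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ConfigError("incidence cells must be binary (0/1)")
        self.table = self.table.copy()
        self.table[sp] = self.table[sp].astype(np.int8)

    # -- basic structure -----------------------------------------------------

    @property
    def meta_columns(self) -> list[str]:
        return [c for c in META_COLUMNS if c in self.table.columns]

    @property
    def species(self) -> list[str]:
        return [c for c in self.table.columns if c not in META_COLUMNS]

    @property
    def is_block_level(self) -> bool:
        return "block" in self.table.columns

    @property
    def elevations(self) -> list[float]:
        return sorted(self.table["elevation_m"].unique().tolist())

    def strata(self) -> list[tuple[str, int]]:
        """Sorted (season, year) strata present in the table."""
        pairs = self.table[["season", "year"]].drop_duplicates()
        return sorted((str(s), y) for s, y in pairs.itertuples(index=False))

    # -- views ---------------------------------------------------------------

    def stratum_matrix(self, season: str, year) -> pd.DataFrame:
        """Site-by-species binary matrix for one (season, year) stratum.

        Only defined for site-level (pooled) data; rows are indexed by
        elevation in ascending order.
        """
        if self.is_block_level:
            raise ConfigError("stratum_matrix requires site-level (pooled) data")
        mask = (self.table["season"] == season) & (self.table["year"] == year)
        sub = self.table.loc[mask]
        if sub.empty:
            raise KeyError(f"no assemblages for season={season!r}, year={year!r}")
        mat = sub.set_index("elevation_m")[self.species].sort_index()
        return mat

    def assemblage(self, elevation_m, season: str, year) -> frozenset[str]:
        """Set of species present in one pooled assemblage."""
        row = self.stratum_matrix(season, year).loc[elevation_m]
        return frozenset(row.index[row.to_numpy() > 0])

    # -- IO ------------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        cols = self.meta_columns + self.species
        self.table[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, species_meta: pd.DataFrame | None = None) -> "OccurrenceSet":
        table = pd.read_csv(path)
        return cls(table, species_meta=species_meta)


def pool_blocks(occ: OccurrenceSet) -> OccurrenceSet:
    """Pool replicate blocks into site-level assemblages.

    A species is present at a (site, season, year) if it occurs in at least
    one of the site's blocks (set union across blocks).
    """
    if not occ.is_block_level:
        return occ
    grouped = (
        occ.table.groupby(["elevation_m", "season", "year"], as_index=False)[occ.species]
        .max()
    )
    return OccurrenceSet(grouped, species_meta=occ.species_meta)


def all_site_pairs(elevations: list[float]) -> list[tuple[float, float]]:
    """All unordered elevation pairs, lower elevation first."""
    return [tuple(sorted(p)) for p in combinations(sorted(elevations), 2)]
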