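"""Pairwise beta-diversity partition into turnover and nestedness components.

Implements the incidence-based Sørensen-family partition: total dissimilarity
``beta_sor`` splits additively into a turnover component ``beta_sim`` (Simpson
dissimilarity, insensitive to richness differences) and a nestedness-resultant
component ``beta_sne = beta_sor - beta_sim``.  With ``a`` the number of shared
species and ``b``, ``c`` the numbers unique to each site::

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))

The same formulas are applied to trait-space volumes for the functional
partition (see :mod:`elevbeta.hulls`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import EmptyAssemblageError
from .occurrences import OccurrenceSet


@dataclass(frozen=True)
class BetaTriplet:
    """(beta_sor, beta_sim, beta_sne) for one ordered site pair.

    ``composition`` records whether the triplet was computed from species
    identities or from trait-space (functional) volumes.
    """

    beta_sor: float
    beta_sim: float
    beta_sne: float
    pair: tuple | None = None
    composition: str = "species"

    def __iter__(self):
        return iter((self.beta_sor, self.beta_sim, self.beta_sne))


def partition_components(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Sørensen/Simpson/nestedness-resultant partition from shared/unique quantities.

    ``a`` is the shared quantity (species count or intersection volume), ``b``
    and ``c`` the quantities unique to each assemblage.  Returns
    ``(beta_sor, beta_sim, beta_sne)``.
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("partition components must be non-negative")
    denom = 2.0 * a + b + c
    if denom == 0:
        raise EmptyAssemblageError("both assemblages are empty; dissimilarity undefined")
    beta_sor = (b + c) / denom
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    return beta_sor, beta_sim, beta_sor - beta_sim


def species_beta_pair(
    occ_i: Iterable[str],
    occ_j: Iterable[str],
    pair: tuple | None = None,
) -> BetaTriplet:
    """Partitioned beta diversity between two assemblages given as species sets."""
    set_i, set_j = set(occ_i), set(occ_j)
    if not set_i or not set_j:
        raise EmptyAssemblageError("pairwise dissimilarity undefined for an empty assemblage")
    a = len(set_i & set_j)
    b = len(set_i - set_j)
    c = len(set_j - set_i)
    sor, sim, sne = partition_components(a, b, c)
    return BetaTriplet(sor, sim, sne, pair=pair, composition="species")


def _pair_triplet_from_rows(row_i: np.ndarray, row_j: np.ndarray, pair=None) -> BetaTriplet:
    """Triplet from two boolean incidence rows (fast path used by null models)."""
    if not row_i.any() or not row_j.any():
        raise EmptyAssemblageError("pairwise dissimilarity undefined for an empty assemblage")
    a = int(np.count_nonzero(row_i & row_j))
    b = int(np.count_nonzero(row_i & ~row_j))
    c = int(np.count_nonzero(row_j & ~row_i))
    sor, sim, sne = partition_components(a, b, c)
    return BetaTriplet(sor, sim, sne, pair=pair, composition="species")


def species_beta_matrix(
    occ: OccurrenceSet | pd.DataFrame,
    pairs: list[tuple],
    season: str | None = None,
    year=None,
) -> list[BetaTriplet]:
    """Species beta triplets for a list of site pairs.

    ``occ`` is either a site-by-species binary DataFrame (indexed by site id /
    elevation) or a site-level :class:`OccurrenceSet`, in which case ``season``
    and ``year`` select the stratum.
    """
    if isinstance(occ, OccurrenceSet):
        if season is None or year is None:
            raise ValueError("season and year are required with an OccurrenceSet input")
        matrix = occ.stratum_matrix(season, year)
    else:
        matrix = occ
    rows = matrix.to_numpy(dtype=bool)
    index = {site: k for k, site in enumerate(matrix.index)}
    out = []
    for i, j in pairs:
        if i not in index or j not in index:
            raise KeyError(f"unknown site id in pair ({i}, {j})")
        out.append(_pair_triplet_from_rows(rows[index[i]], rows[index[j]], pair=(i, j)))
    return out
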