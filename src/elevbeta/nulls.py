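"""Null models and standardized effect sizes for beta-diversity metrics.

Two randomizations are implemented, one per composition type:

* **independent swap** — repeated 2x2 checkerboard flips of the binary
  site-by-species matrix, preserving every site's richness and every species'
  occurrence frequency while shuffling co-occurrence.  Species metrics are
  recomputed on each null matrix.
* **trait-label shuffle** — a uniform random permutation of which species owns
  which synthetic-trait coordinate row.  The pooled trait space (and hence the
  pooled hull) is untouched; functional metrics are recomputed on the fixed
  occurrence matrix.

Observed values are standardized against the resulting null distribution as
``SES = (observed - mean(null)) / SD(null)`` with sample SD; |SES| > 1.96 is
flagged as non-random at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta import _pair_triplet_from_rows
from .errors import ConfigError, ElevBetaError, HullDegenerate, HullInfeasible
from .hulls import assemblage_hull, functional_beta_pair
from .traits import TraitSpace

METRICS = ("sor", "sim", "sne")

#: Two-sided 5% significance band on the SES scale.
SES_CRITICAL = 1.96


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def independent_swap(matrix, n_swaps: int | None = None, seed=None):
    """Randomize a binary matrix by attempted 2x2 checkerboard swaps.

    Each attempt picks two distinct rows and two distinct columns; if the 2x2
    submatrix is a checkerboard it is flipped, otherwise the attempt is a
    no-op.  Row and column sums are invariant.  ``n_swaps`` defaults to
    10 x (number of presences).  Accepts and returns either a DataFrame or an
    ndarray.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    m = matrix.to_numpy() if is_frame else np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ConfigError("independent swap needs a matrix with >= 2 rows and columns")
    if not np.isin(m, (0, 1)).all():
        raise ConfigError("independent swap requires a binary matrix")
    m = m.astype(np.int8).copy()
    nr, nc = m.shape
    if n_swaps is None:
        n_swaps = 10 * int(m.sum())
    rng = _as_rng(seed)

    # Draw distinct row/column pairs in bulk; the offset trick guarantees
    # r1 != r2 and c1 != c2 so every attempt is a legal candidate.
    r1 = rng.integers(0, nr, size=n_swaps)
    r2 = (r1 + 1 + rng.integers(0, nr - 1, size=n_swaps)) % nr
    c1 = rng.integers(0, nc, size=n_swaps)
    c2 = (c1 + 1 + rng.integers(0, nc - 1, size=n_swaps)) % nc
    for k in range(n_swaps):
        i, j, p, q = r1[k], r2[k], c1[k], c2[k]
        a = m[i, p]
        d = m[j, q]
        if a != d:
            continue
        b = m[i, q]
        if b != m[j, p] or a == b:
            continue
        m[i, p] = b
        m[i, q] = a
        m[j, p] = d
        m[j, q] = b
    if is_frame:
        return pd.DataFrame(m, index=matrix.index, columns=matrix.columns)
    return m


def shuffle_traits(space: TraitSpace, seed=None, subset=None) -> TraitSpace:
    """Randomly reassign which species owns which coordinate row.

    The multiset of coordinate rows is unchanged, so the pooled trait space
    and its convex hull are exactly invariant.  ``subset`` restricts the
    permutation to the given species ids (e.g. the pool of one season-year
    stratum); other assignments are left alone.
    """
    if len(space.species_ids) < 2:
        raise ConfigError("need at least two species to shuffle")
    rng = _as_rng(seed)
    ids = space.species_ids.copy()
    if subset is None:
        positions = np.arange(len(ids))
    else:
        subset = set(subset)
        positions = np.array([k for k, s in enumerate(ids) if s in subset])
    perm = rng.permutation(len(positions))
    ids[positions] = ids[positions][perm]
    return space.with_species_ids(ids)


@dataclass
class NullDistribution:
    """Null values of one metric for one site pair."""

    metric: str
    composition: str
    pair: tuple
    values: np.ndarray
    n_dropped: int = 0


@dataclass
class SESRecord:
    """Observed value standardized against its null distribution."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    significant: bool | None
    n_null: int

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.ses)


def ses(observed: float, null) -> SESRecord:
    """Standardized effect size of an observed value against null draws.

    SD uses the sample convention (n-1).  A zero-SD null yields an undefined
    SES (NaN) with the observed value and null mean still reported.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null, dtype=float)
    if values.size == 0:
        raise ConfigError("empty null distribution")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sd > 0:
        z = (observed - mean) / sd
        return SESRecord(observed, mean, sd, z, abs(z) > SES_CRITICAL, values.size)
    return SESRecord(observed, mean, sd, float("nan"), None, values.size)


def null_distributions(
    matrix: pd.DataFrame,
    space: TraitSpace | None,
    pairs: list[tuple],
    n_iter: int,
    composition: str,
    seed=None,
    n_axes: int = 4,
    swap_multiplier: int = 10,
) -> list[NullDistribution]:
    """Null distributions of all three metrics for each pair in one stratum.

    ``matrix`` is the stratum's site-by-species binary matrix (rows indexed by
    site id).  For ``composition='species'`` each iteration swap-randomizes
    the matrix and recomputes the species triplets; for ``'functional'`` each
    iteration shuffles trait labels among the species present in the stratum
    and recomputes hull-based triplets on the fixed matrix.  Iterations where
    a null assemblage fails the hull filter are dropped and counted.
    """
    if n_iter < 2:
        raise ConfigError("n_iter must be at least 2")
    if composition not in ("species", "functional"):
        raise ConfigError(f"unknown composition {composition!r}")
    rng = _as_rng(seed)
    index = {site: k for k, site in enumerate(matrix.index)}
    for i, j in pairs:
        if i not in index or j not in index:
            raise KeyError(f"unknown site id in pair ({i}, {j})")

    collected: dict[tuple, dict[str, list[float]]] = {
        p: {m: [] for m in METRICS} for p in pairs
    }
    dropped = {p: 0 for p in pairs}

    if composition == "species":
        base = matrix.to_numpy().astype(np.int8)
        n_swaps = swap_multiplier * int(base.sum())
        for _ in range(n_iter):
            null_matrix = independent_swap(base, n_swaps=n_swaps, seed=rng)
            rows = null_matrix.astype(bool)
            for p in pairs:
                trip = _pair_triplet_from_rows(rows[index[p[0]]], rows[index[p[1]]])
                for m, v in zip(METRICS, trip):
                    collected[p][m].append(v)
    else:
        if space is None:
            raise ConfigError("functional nulls require a trait space")
        bools = matrix.to_numpy(dtype=bool)
        species = np.asarray(matrix.columns, dtype=object)
        pool = species[bools.any(axis=0)]
        site_species = {site: species[bools[k]] for site, k in index.items()}
        for _ in range(n_iter):
            shuffled = shuffle_traits(space, seed=rng, subset=pool)
            hull_cache: dict = {}
            for p in pairs:
                try:
                    hulls = []
                    for site in p:
                        if site not in hull_cache:
                            hull_cache[site] = assemblage_hull(
                                site_species[site], shuffled, n_axes=n_axes, site_id=site
                            )
                        hulls.append(hull_cache[site])
                    trip = functional_beta_pair(*hulls, pair=p)
                except (HullInfeasible, HullDegenerate):
                    dropped[p] += 1
                    continue
                for m, v in zip(METRICS, trip):
                    collected[p][m].append(v)

    out = []
    for p in pairs:
        if not collected[p]["sor"]:
            raise ElevBetaError(f"all {n_iter} null iterations failed for pair {p}")
        for m in METRICS:
            out.append(
                NullDistribution(
                    metric=m,
                    composition=composition,
                    pair=p,
                    values=np.asarray(collected[p][m], dtype=float),
                    n_dropped=dropped[p],
                )
            )
    return out
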