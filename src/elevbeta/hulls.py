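"""Assemblage convex hulls in trait space and functional beta diversity.

An assemblage is projected into the synthetic-trait space as the convex hull
of its species' coordinates; the hull's d-dimensional content is the
assemblage's functional volume.  Shared and unique volumes between two hulls
feed the same Sørensen-family partition used for species composition, giving
functional turnover and nestedness components.

Intersection volumes are computed by stacking both hulls' facet halfspaces,
locating a strictly interior point (Chebyshev centre, via linear programming)
and enumerating the intersection polytope's vertices with qhull; an infeasible
or radius-zero LP means the polytopes share no d-dimensional volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .beta import BetaTriplet, partition_components
from .errors import ConfigError, HullDegenerate, HullInfeasible
from .traits import TraitSpace

#: Hull volumes below this are treated as degenerate (lower-dimensional).
VOLUME_TOLERANCE = 1e-12


@dataclass
class Hull:
    """Convex polytope of one assemblage in d-dimensional trait space.

    ``equations`` holds facet halfspaces in qhull form: rows ``[normal, offset]``
    with ``normal . x + offset <= 0`` for interior points.
    """

    points: np.ndarray
    equations: np.ndarray
    volume: float
    site_id: object | None = None

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def contains(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of which query points lie inside (or on) the hull."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts @ self.equations[:, :-1].T + self.equations[:, -1] <= tol).all(axis=1)


def hull_from_points(points, site_id=None, min_volume: float = VOLUME_TOLERANCE) -> Hull:
    """Convex hull of a point cloud; raises :class:`HullDegenerate` if flat.

    Coincident points are legal inputs — duplicates are removed before vertex
    enumeration, with no jitter applied.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    d = pts.shape[1]
    if pts.shape[0] < d + 1:
        raise HullDegenerate(
            f"{pts.shape[0]} distinct points cannot span a {d}-dimensional hull"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise HullDegenerate(f"degenerate point configuration: {exc}") from None
    if hull.volume < min_volume:
        raise HullDegenerate(f"hull volume {hull.volume:.3e} below tolerance")
    return Hull(pts[hull.vertices], hull.equations, float(hull.volume), site_id=site_id)


def assemblage_hull(
    species_ids,
    space: TraitSpace,
    n_axes: int = 4,
    site_id=None,
) -> Hull:
    """Hull of an assemblage's species on the first ``n_axes`` synthetic traits.

    Raises :class:`HullInfeasible` when the assemblage has fewer than
    ``n_axes + 1`` species (the filter that removes species-poor assemblages)
    and :class:`HullDegenerate` when the coordinates are affinely flat.
    """
    ids = sorted(set(species_ids))
    if n_axes < 1 or n_axes > space.n_axes:
        raise ConfigError(f"n_axes must be in [1, {space.n_axes}]")
    if len(ids) < n_axes + 1:
        raise HullInfeasible(
            f"assemblage of {len(ids)} species cannot span a {n_axes}-dimensional hull"
        )
    coords = space.coordinates_for(ids, n_axes=n_axes)
    return hull_from_points(coords, site_id=site_id)


def _chebyshev_center(halfspaces: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Centre and radius of the largest ball inside a halfspace system."""
    a = halfspaces[:, :-1]
    b = -halfspaces[:, -1]
    norms = np.linalg.norm(a, axis=1)
    d = a.shape[1]
    c = np.zeros(d + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=np.hstack([a, norms[:, None]]),
        b_ub=b,
        bounds=[(None, None)] * d + [(0, None)],
        method="highs",
    )
    if not res.success:
        return None, 0.0
    return res.x[:-1], float(res.x[-1])


def hull_intersection_volume(h1: Hull, h2: Hull, radius_tol: float = 1e-10) -> float:
    """d-content of the intersection polytope of two hulls.

    Returns 0 when the intersection is empty or lower-dimensional (the
    inscribed-ball radius of the combined halfspace system is ~0).
    """
    if h1.dim != h2.dim:
        raise ConfigError(f"dimension mismatch: {h1.dim} vs {h2.dim}")
    halfspaces = np.vstack([h1.equations, h2.equations])
    center, radius = _chebyshev_center(halfspaces)
    if center is None or radius <= radius_tol:
        return 0.0
    try:
        intersection = HalfspaceIntersection(halfspaces, center)
        volume = float(ConvexHull(intersection.intersections).volume)
    except QhullError:
        return 0.0
    return 0.0 if volume < VOLUME_TOLERANCE else volume


def functional_beta_pair(h1: Hull, h2: Hull, pair: tuple | None = None) -> BetaTriplet:
    """Functional beta-diversity partition from two assemblage hulls.

    Shared volume plays the role of shared species; each hull's volume outside
    the intersection is its unique component.
    """
    if h1.volume <= 0 and h2.volume <= 0:
        raise ConfigError("both hulls have zero volume; functional dissimilarity undefined")
    shared = hull_intersection_volume(h1, h2)
    b = max(h1.volume - shared, 0.0)
    c = max(h2.volume - shared, 0.0)
    if pair is None and h1.site_id is not None and h2.site_id is not None:
        pair = (h1.site_id, h2.site_id)
    sor, sim, sne = partition_components(shared, b, c)
    return BetaTriplet(sor, sim, sne, pair=pair, composition="functional")


def classify_trait_space_regions(
    base_hull: Hull,
    higher_hulls: list[Hull],
    grid_resolution: int = 100,
) -> pd.DataFrame:
    """Label trait-space regions as turnover- or nestedness-dominated.

    On a rectangular grid over the bounding box of all hulls (first two
    synthetic traits), a cell covered by a higher-elevation hull counts as
    *turnover* if the base (lowest-elevation) hull does not cover it, and as
    *nestedness* if the base hull covers it too.  The combined score is
    ``(turnover - nestedness) / (turnover + nestedness)``: +1 where replacement
    of trait space dominates, -1 where higher assemblages only re-occupy base
    trait space, NaN where no higher hull reaches.
    """
    hulls = [base_hull, *higher_hulls]
    if any(h.dim != 2 for h in hulls):
        raise ConfigError("region classification is defined on the first two axes only")
    if grid_resolution < 10:
        raise ConfigError("grid_resolution must be at least 10")
    if not higher_hulls:
        raise ConfigError("need at least one higher-elevation hull")

    allpts = np.vstack([h.points for h in hulls])
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    edges = [np.linspace(lo[k], hi[k], grid_resolution + 1) for k in range(2)]
    centers = [(e[:-1] + e[1:]) / 2 for e in edges]
    gx, gy = np.meshgrid(centers[0], centers[1], indexing="ij")
    cells = np.column_stack([gx.ravel(), gy.ravel()])

    in_base = base_hull.contains(cells)
    turnover = np.zeros(len(cells), dtype=int)
    nested = np.zeros(len(cells), dtype=int)
    for h in higher_hulls:
        inside = h.contains(cells)
        turnover += inside & ~in_base
        nested += inside & in_base
    total = turnover + nested
    with np.errstate(invalid="ignore"):
        score = np.where(total > 0, (turnover - nested) / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "x": cells[:, 0],
            "y": cells[:, 1],
            "turnover_count": turnover,
            "nestedness_count": nested,
            "score": score,
        }
    )
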