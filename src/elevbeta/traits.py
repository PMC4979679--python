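"""Trait indices, species distance matrix and principal coordinates analysis.

Six raw morphological measurements per individual (mm) are reduced to four
per-species ecological indices:

* **Weber's length** — body size, pronotum to propodeum (passes through).
* **eye position** — (head width across eyes − interocular distance) / Weber's
  length; large values mean dorsally placed eyes, 0 means eyeless.
* **relative leg length** — (hind femur + hind tibia) / Weber's length.
* **relative mandible length** — mandible length / head width across eyes.

Indices are centred and scaled across species, converted to a Euclidean
distance matrix, and embedded by classical scaling (PCoA).  The resulting
orthogonal axes act as synthetic, uncorrelated traits; assemblage convex hulls
are built on them (:mod:`elevbeta.hulls`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, DegenerateSpaceError, NonEuclideanDistanceError

MEASUREMENT_COLUMNS = (
    "webers_length",
    "interocular_distance",
    "head_width_across_eyes",
    "hind_femur_length",
    "hind_tibia_length",
    "mandible_length",
)

TRAIT_COLUMNS = (
    "webers_length",
    "eye_position",
    "relative_leg_length",
    "relative_mandible_length",
)

#: Eigenvalues at or below this threshold are discarded when building axes.
EIGENVALUE_TOLERANCE = 1e-8


def compute_trait_indices(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-species trait indices from a table of individual measurements.

    ``raw`` must have columns ``species_id`` plus the six measurement columns;
    measurements are averaged within species before the index formulas are
    applied.  Eyeless species (both eye measurements zero) get
    ``eye_position = 0``; their mandible length must also be zero, in which
    case ``relative_mandible_length = 0``.
    """
    missing = [c for c in ("species_id", *MEASUREMENT_COLUMNS) if c not in raw.columns]
    if missing:
        raise ConfigError(f"morphology table lacks columns {missing}")
    if raw.empty:
        raise ConfigError("morphology table is empty")
    vals = raw[list(MEASUREMENT_COLUMNS)]
    if (vals.to_numpy() < 0).any():
        raise ConfigError("measurements must be non-negative")

    means = raw.groupby("species_id")[list(MEASUREMENT_COLUMNS)].mean()
    if (means["webers_length"] <= 0).any():
        bad = means.index[means["webers_length"] <= 0].tolist()
        raise ConfigError(f"non-positive Weber's length for species {bad}")

    wl = means["webers_length"]
    hw = means["head_width_across_eyes"]
    io = means["interocular_distance"]
    ml = means["mandible_length"]

    sightless = hw == 0
    if ((ml > 0) & sightless).any():
        bad = means.index[(ml > 0) & sightless].tolist()
        raise ConfigError(
            f"species {bad} have zero head width but non-zero mandible length; "
            "relative mandible length is undefined"
        )

    eye_position = (hw - io) / wl
    relative_leg_length = (means["hind_femur_length"] + means["hind_tibia_length"]) / wl
    relative_mandible = pd.Series(0.0, index=means.index)
    relative_mandible[~sightless] = ml[~sightless] / hw[~sightless]

    return pd.DataFrame(
        {
            "webers_length": wl,
            "eye_position": eye_position,
            "relative_leg_length": relative_leg_length,
            "relative_mandible_length": relative_mandible,
        }
    )


def species_distance_matrix(traits: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Euclidean distances between species on centred, unit-SD trait indices.

    Each trait column is centred to mean 0 and scaled to unit sample SD
    (``ddof=1``).  A trait constant across all species carries no information;
    its scaled column is set to zero with a warning.
    """
    if len(traits) < 2:
        raise ConfigError("need at least two species for a distance matrix")
    x = traits[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ConfigError("trait table contains missing values")
    sd = x.std(axis=0, ddof=ddof)
    z = x - x.mean(axis=0)
    constant = sd == 0
    if constant.any():
        names = [t for t, flag in zip(TRAIT_COLUMNS, constant) if flag]
        warnings.warn(f"traits constant across species treated as zero columns: {names}")
        z[:, constant] = 0.0
    z[:, ~constant] = z[:, ~constant] / sd[~constant]
    d = squareform(pdist(z))
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


def eigenvalue_summary(eigenvalues) -> tuple[np.ndarray, np.ndarray]:
    """Relative and cumulative-relative eigenvalues (descending order assumed)."""
    lam = np.asarray(eigenvalues, dtype=float)
    total = lam.sum()
    if total <= 0:
        raise DegenerateSpaceError("eigenvalue sum is non-positive")
    rel = lam / total
    return rel, np.cumsum(rel)


@dataclass
class TraitSpace:
    """Species coordinates on PCoA axes plus the eigenvalue spectrum.

    Axis ``k`` is scaled by the square root of its eigenvalue, so pairwise
    Euclidean distances among full-dimensional coordinates reproduce the input
    distances when those are Euclidean-embeddable.
    """

    species_ids: np.ndarray
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    relative_eigenvalues: np.ndarray
    cumulative_relative: np.ndarray
    _row_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.species_ids = np.asarray(self.species_ids, dtype=object)
        self._row_index = {sid: k for k, sid in enumerate(self.species_ids)}

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def coordinates_for(self, species_ids, n_axes: int | None = None) -> np.ndarray:
        """Coordinate rows for a collection of species, sorted by species id."""
        ids = sorted(species_ids)
        try:
            rows = [self._row_index[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} not present in trait space") from None
        coords = self.coordinates[rows]
        return coords if n_axes is None else coords[:, :n_axes]

    def with_species_ids(self, species_ids) -> "TraitSpace":
        """Same coordinate rows under a new id-to-row assignment (used by nulls)."""
        return replace(self, species_ids=np.asarray(species_ids, dtype=object))


def pcoa(
    distances,
    eig_tol: float = EIGENVALUE_TOLERANCE,
    negative_tol_factor: float = 1e-6,
) -> TraitSpace:
    """Classical scaling of a distance matrix into orthogonal synthetic traits.

    Double-centres ``-0.5 * D**2``, eigendecomposes, and retains eigenvalues
    above ``eig_tol``.  Inputs here are Euclidean by construction, so a
    negative eigenvalue below ``-negative_tol_factor * lambda_max`` aborts with
    a diagnostic instead of applying a correction.
    """
    if isinstance(distances, pd.DataFrame):
        ids = np.asarray(distances.index, dtype=object)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        ids = np.arange(d.shape[0]).astype(object)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ConfigError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ConfigError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise ConfigError("need at least two species")

    b = -0.5 * d**2
    b = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    lam, vec = eigh(b)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]

    lam_max = lam[0]
    if lam_max <= eig_tol:
        raise DegenerateSpaceError("no eigenvalue exceeds the retention tolerance")
    if lam[-1] < -negative_tol_factor * lam_max:
        raise NonEuclideanDistanceError(
            f"negative eigenvalue {lam[-1]:.3e} (lambda_max {lam_max:.3e}); "
            "input distances are not Euclidean-embeddable"
        )

    keep = lam > eig_tol
    lam_kept = lam[keep]
    coords = vec[:, keep] * np.sqrt(lam_kept)

    # Eigenvector sign is arbitrary: force the largest-magnitude coordinate on
    # each axis to be positive so results are deterministic.
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]

    rel, cum = eigenvalue_summary(lam_kept)
    return TraitSpace(ids, coords, lam_kept, rel, cum)


def trait_loadings(traits: pd.DataFrame, space: TraitSpace) -> pd.DataFrame:
    """Pearson correlation of each trait index with each synthetic-trait axis."""
    ids = list(space.species_ids)
    if set(ids) != set(traits.index):
        raise ConfigError("trait table and trait space cover different species")
    x = traits.loc[ids, list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    axes = space.coordinates
    out = np.full((x.shape[1], axes.shape[1]), np.nan)
    for j in range(axes.shape[1]):
        if axes[:, j].std() == 0:
            warnings.warn(f"axis {j + 1} is constant; loadings undefined")
            continue
        for t in range(x.shape[1]):
            if x[:, t].std() == 0:
                warnings.warn(f"trait {TRAIT_COLUMNS[t]} is constant; loading undefined")
                continue
            out[t, j] = np.corrcoef(x[:, t], axes[:, j])[0, 1]
    cols = [f"axis{j + 1}" for j in range(axes.shape[1])]
    return pd.DataFrame(out, index=list(TRAIT_COLUMNS), columns=cols)


def trait_space_summary(space: TraitSpace, traits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Eigenvalue rows (and loadings if traits are given) as one tidy table."""
    cols = [f"axis{j + 1}" for j in range(space.n_axes)]
    rows = {
        "eigenvalue": space.eigenvalues,
        "relative_eigenvalue": space.relative_eigenvalues,
        "cumulative_eigenvalue": space.cumulative_relative,
    }
    summary = pd.DataFrame(rows, index=cols).T
    if traits is not None:
        summary = pd.concat([summary, trait_loadings(traits, space)])
    return summary
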