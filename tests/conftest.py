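import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import elevbeta as eb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_dataset():
    """One-year, one-season turnover survey with morphology."""
    cfg = eb.GradientSimConfig(n_species=40, n_years=1, seasons=("wet",), seed=11)
    occ, morph = eb.simulate_dataset(cfg)
    return cfg, occ, morph


@pytest.fixture
def trait_space(rng):
    """Trait space built from random points in 4-D (Euclidean by construction)."""
    pts = rng.normal(size=(30, 4))
    from scipy.spatial.distance import pdist, squareform

    d = pd.DataFrame(
        squareform(pdist(pts)),
        index=[f"sp{i:03d}" for i in range(1, 31)],
        columns=[f"sp{i:03d}" for i in range(1, 31)],
    )
    return eb.pcoa(d)


def make_pooled(matrix: dict, season="wet", year=1):
    """Site-level OccurrenceSet from {elevation: iterable of species}."""
    species = sorted({s for v in matrix.values() for s in v})
    rows = []
    for elev, present in matrix.items():
        row = {"elevation_m": elev, "season": season, "year": year}
        row.update({s: int(s in present) for s in species})
        rows.append(row)
    return eb.OccurrenceSet(pd.DataFrame(rows))
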