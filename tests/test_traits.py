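"""Trait indices, distance scaling and classical-scaling ordination."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import elevbeta as eb
from elevbeta.traits import TRAIT_COLUMNS


def _raw(rows):
    cols = [
        "species_id",
        "individual_id",
        "webers_length",
        "interocular_distance",
        "head_width_across_eyes",
        "hind_femur_length",
        "hind_tibia_length",
        "mandible_length",
    ]
    return pd.DataFrame(rows, columns=cols)


class TestTraitIndices:
    def test_printed_formulas(self):
        raw = _raw([("a", "a1", 1.0, 0.30, 0.50, 0.60, 0.50, 0.20)])
        t = eb.compute_trait_indices(raw)
        assert t.loc["a", "eye_position"] == pytest.approx(0.20)
        assert t.loc["a", "relative_leg_length"] == pytest.approx(1.10)
        assert t.loc["a", "relative_mandible_length"] == pytest.approx(0.40)
        assert t.loc["a", "webers_length"] == pytest.approx(1.0)

    def test_individuals_averaged_before_indices(self):
        raw = _raw(
            [
                ("a", "a1", 1.0, 0.30, 0.50, 0.60, 0.50, 0.20),
                ("a", "a2", 3.0, 0.30, 0.50, 0.60, 0.50, 0.20),
            ]
        )
        t = eb.compute_trait_indices(raw)
        assert t.loc["a", "webers_length"] == pytest.approx(2.0)
        # indices use the averaged measurements, not averaged per-individual indices
        assert t.loc["a", "eye_position"] == pytest.approx(0.20 / 2.0)

    def test_eyeless_species_zero_eye_position(self):
        raw = _raw([("blind", "b1", 2.0, 0.0, 0.0, 1.0, 1.0, 0.0)])
        t = eb.compute_trait_indices(raw)
        assert t.loc["blind", "eye_position"] == 0.0
        assert t.loc["blind", "relative_mandible_length"] == 0.0

    def test_zero_webers_length_rejected(self):
        raw = _raw([("a", "a1", 0.0, 0.1, 0.2, 0.3, 0.3, 0.1)])
        with pytest.raises(eb.ConfigError):
            eb.compute_trait_indices(raw)

    def test_eyeless_with_mandible_rejected(self):
        raw = _raw([("a", "a1", 1.0, 0.0, 0.0, 0.3, 0.3, 0.1)])
        with pytest.raises(eb.ConfigError):
            eb.compute_trait_indices(raw)


class TestDistanceMatrix:
    def test_two_species_brute_force_value(self):
        t = pd.DataFrame(
            {
                "webers_length": [1.0, 2.0],
                "eye_position": [0.1, 0.3],
                "relative_leg_length": [1.0, 1.5],
                "relative_mandible_length": [0.2, 0.5],
            },
            index=["a", "b"],
        )
        # With sample-SD scaling, two points end up +-1/sqrt(2) on each of the
        # k informative traits, so their distance is sqrt(2k).
        d = eb.species_distance_matrix(t)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(2 * 4))
        t["webers_length"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            d3 = eb.species_distance_matrix(t)
        assert d3.iloc[0, 1] == pytest.approx(np.sqrt(2 * 3))

    def test_duplicated_species_distance_zero(self, rng):
        x = rng.uniform(0.1, 2.0, size=(5, 4))
        t = pd.DataFrame(np.vstack([x, x[:1]]), columns=list(TRAIT_COLUMNS))
        d = eb.species_distance_matrix(t)
        assert d.iloc[0, 5] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_permutation_equivariance(self, rng):
        x = rng.uniform(0.1, 2.0, size=(8, 4))
        t = pd.DataFrame(x, columns=list(TRAIT_COLUMNS), index=[f"s{i}" for i in range(8)])
        d = eb.species_distance_matrix(t)
        perm = rng.permutation(8)
        dp = eb.species_distance_matrix(t.iloc[perm])
        assert np.allclose(dp.to_numpy(), d.iloc[perm, perm].to_numpy())


class TestPCoA:
    def test_relative_and_cumulative_eigenvalues(self):
        rel, cum = eb.eigenvalue_summary([154.92, 135.82, 41.77, 31.49])
        assert np.round(rel, 2).tolist() == [0.43, 0.37, 0.11, 0.09]
        assert np.round(cum, 2).tolist() == [0.43, 0.80, 0.91, 1.00]

    def test_collinear_points_single_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        space = eb.pcoa(d)
        assert space.n_axes == 1
        assert space.eigenvalues[0] == pytest.approx(2.0)

    def test_distances_recovered_for_euclidean_input(self, rng):
        pts = rng.normal(size=(12, 4))
        d = squareform(pdist(pts))
        space = eb.pcoa(d)
        assert np.abs(squareform(pdist(space.coordinates)) - d).max() < 1e-6
        assert space.relative_eigenvalues.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(space.cumulative_relative) >= -1e-12)

    def test_rotation_leaves_eigenvalues_unchanged(self, rng):
        pts = rng.normal(size=(10, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        d1 = squareform(pdist(pts))
        d2 = squareform(pdist(pts @ q))
        assert np.allclose(eb.pcoa(d1).eigenvalues, eb.pcoa(d2).eigenvalues, atol=1e-8)

    def test_four_traits_give_at_most_four_axes(self, rng):
        t = pd.DataFrame(rng.uniform(0.1, 2.0, size=(20, 4)), columns=list(TRAIT_COLUMNS))
        space = eb.pcoa(eb.species_distance_matrix(t))
        assert 1 <= space.n_axes <= 4

    def test_degenerate_space_rejected(self):
        with pytest.raises(eb.DegenerateSpaceError):
            eb.pcoa(np.zeros((3, 3)))

    def test_non_euclidean_rejected(self):
        # Violates the triangle inequality strongly; classical scaling yields
        # a large negative eigenvalue.
        d = np.array(
            [[0, 1, 1, 10], [1, 0, 1, 1], [1, 1, 0, 1], [10, 1, 1, 0]], dtype=float
        )
        with pytest.raises(eb.NonEuclideanDistanceError):
            eb.pcoa(d)

    def test_matches_independent_pcoa_implementation(self, rng):
        """Cross-check eigenvalues and distances against scikit-bio's PCoA."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(15, 4))
        d = squareform(pdist(pts))
        ours = eb.pcoa(d)
        ref = skbio_pcoa(skbio.DistanceMatrix(d))
        ref_eigs = np.asarray(ref.eigvals)[: ours.n_axes]
        assert np.allclose(ours.eigenvalues, ref_eigs, atol=1e-8)
        ref_coords = np.asarray(ref.samples)[:, : ours.n_axes]
        assert np.allclose(
            squareform(pdist(ours.coordinates)), squareform(pdist(ref_coords)), atol=1e-8
        )


class TestLoadings:
    def test_dominant_trait_loads_on_first_axis(self, rng):
        # After unit-SD scaling every trait has equal variance, so dominance
        # of an axis comes from correlation: leg length carries the full
        # latent factor, two traits carry it diluted, one is independent.
        n = 40
        factor = rng.normal(size=n)
        t = pd.DataFrame(
            {
                "webers_length": 1.3 + 0.10 * factor + 0.15 * rng.normal(size=n),
                "eye_position": 0.18 + 0.02 * factor + 0.03 * rng.normal(size=n),
                "relative_leg_length": 1.3 + 0.30 * factor,
                "relative_mandible_length": 0.4 + 0.10 * rng.normal(size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        space = eb.pcoa(eb.species_distance_matrix(t))
        load = eb.trait_loadings(t, space)
        assert load.abs().to_numpy().max() <= 1.0 + 1e-12
        a1 = load["axis1"].abs()
        assert a1.idxmax() == "relative_leg_length"

    def test_duplicating_every_species_preserves_loadings(self, rng):
        x = rng.uniform(0.1, 2.0, size=(10, 4))
        t = pd.DataFrame(x, columns=list(TRAIT_COLUMNS), index=[f"s{i}" for i in range(10)])
        t2 = pd.concat([t, t.set_index(t.index + "_dup")])
        l1 = eb.trait_loadings(t, eb.pcoa(eb.species_distance_matrix(t)))
        l2 = eb.trait_loadings(t2, eb.pcoa(eb.species_distance_matrix(t2)))
        assert np.allclose(np.abs(l1.to_numpy()), np.abs(l2.to_numpy()), atol=1e-6)
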