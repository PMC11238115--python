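"""Exactness and invariance properties of the coordinate/Gram/distance
conversions and the MDS reconstruction."""

import numpy as np
import pytest

from gramconf.geometry import (Conformer, DistanceMatrix, GeometryError,
                               GramMatrix, add_gram_noise,
                               angle_cosine_from_gram, center_coordinates,
                               DegenerateGeometryError, distance_from_coords,
                               distance_to_gram, effective_rank,
                               gram_from_coords, gram_to_distance,
                               mds_reconstruct)
from gramconf.metrics import aligned_rmsd


def random_conformer(rng, n=8):
    return Conformer(rng.normal(scale=2.0, size=(n, 3)), ["C"] * n)


class TestCentering:
    def test_single_atom_moves_to_origin(self):
        c = center_coordinates(Conformer(np.array([[3.0, 4, 5]]), ["C"]))
        assert np.allclose(c.coords, 0.0)

    def test_symmetric_pair(self):
        c = center_coordinates(
            Conformer(np.array([[0.0, 0, 0], [2.0, 0, 0]]), ["C", "C"]))
        assert np.allclose(c.coords, [[-1, 0, 0], [1, 0, 0]])

    def test_distances_preserved_and_means_zero(self, rng):
        c = random_conformer(rng, 10)
        before = distance_from_coords(c).values
        centered = center_coordinates(c)
        assert np.abs(centered.coords.mean(axis=0)).max() < 1e-12
        assert np.allclose(distance_from_coords(centered).values, before,
                           atol=1e-10)

    def test_empty_conformer_rejected(self):
        with pytest.raises(GeometryError):
            Conformer(np.zeros((0, 3)), [])


class TestGramAndDistance:
    def test_hand_inner_products(self):
        g = gram_from_coords(
            Conformer(np.array([[-1.0, 0, 0], [1.0, 0, 0]]), ["C", "C"]))
        assert np.allclose(g.values, [[1, -1], [-1, 1]])

    def test_single_atom_gram_is_zero(self):
        g = gram_from_coords(Conformer(np.array([[2.0, 1, 0]]), ["C"]))
        assert np.allclose(g.values, [[0.0]])

    def test_matches_bruteforce_dot_products(self, rng):
        c = center_coordinates(random_conformer(rng, 6))
        g = gram_from_coords(c).values
        brute = np.array([[c.coords[i] @ c.coords[j] for j in range(6)]
                          for i in range(6)])
        assert np.allclose(g, brute, atol=1e-12)

    def test_trace_equals_sum_of_squared_norms(self, rng):
        c = center_coordinates(random_conformer(rng, 7))
        g = gram_from_coords(c)
        assert np.isclose(np.trace(g.values),
                          np.sum(np.linalg.norm(c.coords, axis=1) ** 2))

    def test_distance_hand_value_and_zero_diagonal(self, rng):
        d = distance_from_coords(
            Conformer(np.array([[-1.0, 0, 0], [1.0, 0, 0]]), ["C", "C"]))
        assert np.isclose(d.values[0, 1], 2.0)
        c = random_conformer(rng, 9)
        assert np.allclose(np.diag(distance_from_coords(c).values), 0.0)

    def test_distance_matches_bruteforce(self, rng):
        c = random_conformer(rng, 8)
        d = distance_from_coords(c).values
        brute = np.array([[np.linalg.norm(c.coords[i] - c.coords[j])
                           for j in range(8)] for i in range(8)])
        assert np.allclose(d, brute, atol=1e-12)

    def test_e3_invariance_of_gram(self, point_clouds, rng):
        """Rigid motions and reflections leave the Gram matrix unchanged."""
        from scipy.stats import ortho_group
        for cloud in point_clouds[:20]:
            g0 = gram_from_coords(cloud).values
            for _ in range(3):
                q = ortho_group.rvs(3, random_state=rng)
                t = rng.normal(scale=5.0, size=3)
                moved = Conformer(cloud.coords @ q + t, cloud.elements)
                assert np.abs(gram_from_coords(moved).values - g0).max() < 1e-9


class TestConversions:
    def test_gram_to_distance_hand_value(self):
        d = gram_to_distance(GramMatrix(np.array([[1.0, -1], [-1, 1]])))
        assert np.isclose(d.values[0, 1], 2.0)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_distance_to_gram_hand_value(self):
        d = DistanceMatrix(np.array([[0.0, 2], [2, 0]]),
                           origin_distances=np.array([1.0, 1.0]))
        g = distance_to_gram(d)
        assert np.isclose(g.values[0, 1], -1.0)
        assert np.allclose(np.diag(g.values), [1.0, 1.0])

    def test_round_trip_gram_distance_gram(self, point_clouds):
        for cloud in point_clouds:
            g = gram_from_coords(cloud)
            back = distance_to_gram(gram_to_distance(g))
            assert np.abs(back.values - g.values).max() < 1e-10

    def test_gram_to_distance_consistent_with_coords(self, point_clouds):
        for cloud in point_clouds:
            via_gram = gram_to_distance(gram_from_coords(cloud)).values
            direct = distance_from_coords(cloud).values
            assert np.abs(via_gram - direct).max() < 1e-10

    def test_invalid_gram_raises(self):
        bad = GramMatrix(np.array([[0.0, 5.0], [5.0, 0.0]]))  # D^2 = -10
        with pytest.raises(GeometryError):
            gram_to_distance(bad)

    def test_missing_origin_distances_raises(self):
        d = DistanceMatrix(np.array([[0.0, 1], [1, 0]]))
        with pytest.raises(GeometryError):
            distance_to_gram(d)


class TestAngles:
    def test_right_angle(self, examples):
        ex = examples["right_angle_triple"]
        g = gram_from_coords(ex.conformer)
        assert abs(angle_cosine_from_gram(g, 0, 1, 2)) < 1e-12

    def test_collinear(self, examples):
        g = gram_from_coords(examples["linear_chain_3"].conformer)
        assert np.isclose(angle_cosine_from_gram(g, 0, 1, 2), -1.0)

    def test_tetrahedral(self, examples):
        ex = examples["tetrahedron_5"]
        g = gram_from_coords(ex.conformer)
        for (i, j, k), expected in ex.expected["angle_cosine"].items():
            assert np.isclose(angle_cosine_from_gram(g, i, j, k), expected,
                              atol=1e-12)

    def test_matches_direct_vector_formula_any_centering(self, rng):
        """Gram-entry formula equals the direct arm-vector cosine and does
        not depend on where the origin sits."""
        for _ in range(20):
            c = random_conformer(rng, 6)
            g = gram_from_coords(c)
            x = center_coordinates(c).coords
            i, j, k = rng.choice(6, size=3, replace=False)
            direct = ((x[i] - x[j]) @ (x[k] - x[j])
                      / (np.linalg.norm(x[i] - x[j]) * np.linalg.norm(x[k] - x[j])))
            assert np.isclose(angle_cosine_from_gram(g, i, j, k), direct,
                              atol=1e-10)

    def test_degenerate_arm_raises(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]])
        g = GramMatrix(coords @ coords.T)
        with pytest.raises(DegenerateGeometryError):
            angle_cosine_from_gram(g, 0, 1, 2)


class TestReconstruction:
    def test_machine_precision_on_exact_gram(self, point_clouds):
        for cloud in point_clouds:
            g = gram_from_coords(cloud)
            rec = mds_reconstruct(g, cloud.elements)
            ref = center_coordinates(cloud)
            assert aligned_rmsd(ref, rec, allow_reflection=True,
                                heavy_only=False) < 1e-8

    def test_planar_molecule_rank_two(self, examples):
        g = gram_from_coords(examples["planar_ring_6"].conformer)
        assert effective_rank(g) == 2
        rec = mds_reconstruct(g)
        assert np.abs(rec.coords[:, 2]).max() < 1e-10

    def test_rank_three_for_generic_clouds(self, point_clouds):
        for cloud in point_clouds:
            assert effective_rank(gram_from_coords(cloud)) == 3

    def test_collinear_rank_one(self, examples):
        g = gram_from_coords(examples["linear_chain_3"].conformer)
        assert effective_rank(g) == 1

    def test_reconstruction_fixed_point(self, point_clouds):
        """gram(mds(G)) = G for exact rank-<=3 PSD input."""
        for cloud in point_clouds[:20]:
            g = gram_from_coords(cloud)
            again = gram_from_coords(mds_reconstruct(g, cloud.elements))
            assert np.abs(again.values - g.values).max() < 1e-8

    def test_noisy_gram_matches_full_decomposition_oracle(self, rng):
        """Truncating the full eigendecomposition to its top three components
        is exactly what the reconstruction computes, noise or not."""
        cloud = random_conformer(rng, 10)
        g = add_gram_noise(gram_from_coords(cloud), sigma=0.05, seed=3)
        v = (g.values + g.values.T) / 2
        w, q = np.linalg.eigh(v)
        top = np.argsort(w)[::-1][:3]
        oracle = q[:, top] * np.sqrt(np.clip(w[top], 0, None))
        oracle -= oracle.mean(axis=0)
        rec = mds_reconstruct(g)
        ref = Conformer(oracle, ["C"] * 10)
        assert aligned_rmsd(ref, rec, allow_reflection=True,
                            heavy_only=False) < 1e-10

    def test_mirror_images_share_gram(self, examples):
        ex = examples["mirror_pair_chiral"]
        g1 = gram_from_coords(ex.conformer)
        g2 = gram_from_coords(ex.expected["mirror"])
        assert np.allclose(g1.values, g2.values, atol=1e-12)


class TestNoise:
    def test_sigma_zero_identity(self, rng):
        g = gram_from_coords(random_conformer(rng, 5))
        assert np.array_equal(add_gram_noise(g, 0.0, seed=1).values, g.values)

    def test_deterministic_under_seed(self, rng):
        g = gram_from_coords(random_conformer(rng, 5))
        a = add_gram_noise(g, 0.3, seed=42).values
        b = add_gram_noise(g, 0.3, seed=42).values
        assert np.array_equal(a, b)

    def test_symmetric_output(self, rng):
        g = gram_from_coords(random_conformer(rng, 6))
        noisy = add_gram_noise(g, 0.5, seed=9).values
        assert np.allclose(noisy, noisy.T)

    def test_empirical_sigma(self):
        n = 200
        g = GramMatrix(np.zeros((n, n)))
        noisy = add_gram_noise(g, 0.7, seed=5).values
        triu = noisy[np.triu_indices(n, k=1)]
        assert abs(triu.std() - 0.7) / 0.7 < 0.1

    def test_negative_sigma_rejected(self, rng):
        g = gram_from_coords(random_conformer(rng, 4))
        with pytest.raises(GeometryError):
            add_gram_noise(g, -0.1, seed=0)

    def test_rmsd_grows_with_noise(self, rng):
        """Reconstruction error increases monotonically with noise scale."""
        sigmas = [0.0, 0.01, 0.1, 1.0]
        means = []
        for sigma in sigmas:
            vals = []
            for rep in range(30):
                c = random_conformer(np.random.default_rng(rep), 10)
                g = add_gram_noise(gram_from_coords(c), sigma, seed=rep)
                rec = mds_reconstruct(g)
                vals.append(aligned_rmsd(center_coordinates(c), rec,
                                         allow_reflection=True, heavy_only=False))
            means.append(np.mean(vals))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))
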