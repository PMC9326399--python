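import numpy as np
import pytest

from omicsfuse import (DistanceMatrix, OmicsMatrix, PhateConfig, SimilarityMatrix,
                       alpha_decay_kernel, diffuse_power, diffusion_operator,
                       mds_embed, phate, potential_distance, von_neumann_entropy)
from omicsfuse.embed import DiffusionOperator


def _dist(points, ids=None):
    pts = np.asarray(points, float)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids)


def _sim(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(values, ids)


class TestAlphaDecayKernel:
    def test_zero_distance_and_unit_scaled_distance(self):
        # equally spaced line: sigma_i = 1 for knn=1
        d = _dist([[0.0], [1.0], [2.0]])
        k = alpha_decay_kernel(d, PhateConfig(knn=1, decay_alpha=2.0))
        assert k.values[0, 0] == pytest.approx(1.0)
        assert k.values[0, 1] == pytest.approx(np.exp(-1.0))

    def test_sharp_alpha_approaches_knn_indicator(self):
        d = _dist([[0.0], [1.0], [1.5], [10.0]])
        k = alpha_decay_kernel(d, PhateConfig(knn=2, decay_alpha=400.0))
        # within the bandwidth -> ~1, beyond -> ~0
        assert k.values[1, 2] > 0.99
        assert k.values[0, 3] < 1e-6


class TestDiffusionOperator:
    def test_uniform_affinity_gives_uniform_rows(self):
        p = diffusion_operator(_sim(np.ones((2, 2))))
        np.testing.assert_allclose(p.values, 0.5 * np.ones((2, 2)))

    def test_rows_stochastic_and_blocks_preserved(self, rng):
        a = np.zeros((6, 6))
        a[:3, :3] = rng.uniform(0.5, 1, (3, 3))
        a[3:, 3:] = rng.uniform(0.5, 1, (3, 3))
        a = 0.5 * (a + a.T)
        p = diffusion_operator(_sim(a))
        np.testing.assert_allclose(p.values.sum(1), 1.0, atol=1e-10)
        assert np.all(p.values[:3, 3:] == 0)


class TestDiffusePower:
    def test_t_one_is_identity_operation(self, rng):
        a = rng.uniform(size=(5, 5))
        p = diffusion_operator(_sim(0.5 * (a + a.T)))
        np.testing.assert_allclose(diffuse_power(p, 1).values, p.values)

    def test_rank_one_operator_is_idempotent(self):
        p = DiffusionOperator(0.5 * np.ones((2, 2)), ["a", "b"])
        for t in (2, 7, 50):
            np.testing.assert_allclose(diffuse_power(p, t).values, p.values, atol=1e-12)

    @pytest.mark.parametrize("t", [2, 3, 11, 20])
    def test_matches_naive_repeated_multiplication(self, t, rng):
        a = rng.uniform(size=(6, 6))
        p = diffusion_operator(_sim(0.5 * (a + a.T)))
        naive = np.linalg.matrix_power(p.values, t)
        np.testing.assert_allclose(diffuse_power(p, t).values, naive, atol=1e-12)

    def test_power_preserves_stochasticity(self, rng):
        a = rng.uniform(size=(8, 8))
        p = diffusion_operator(_sim(0.5 * (a + a.T)))
        pt = diffuse_power(p, 200)
        np.testing.assert_allclose(pt.values.sum(1), 1.0, atol=1e-10)
        assert pt.t_applied == 200


class TestVonNeumannEntropy:
    def test_rank_one_operator_has_zero_entropy(self):
        p = DiffusionOperator(np.full((3, 3), 1 / 3), ["a", "b", "c"])
        h, _ = von_neumann_entropy(p, [1, 2, 5])
        np.testing.assert_allclose(h, 0.0, atol=1e-12)

    def test_identity_operator_has_log_n_entropy(self):
        p = DiffusionOperator(np.eye(2), ["a", "b"])
        h, _ = von_neumann_entropy(p, [1, 3, 9])
        np.testing.assert_allclose(h, np.log(2), atol=1e-12)

    def test_entropy_nonincreasing_in_t(self, rng):
        a = rng.uniform(size=(10, 10))
        p = diffusion_operator(_sim(0.5 * (a + a.T)))
        h, t_knee = von_neumann_entropy(p, list(range(1, 30)))
        assert all(b <= a + 1e-10 for a, b in zip(h, h[1:]))
        assert 1 <= t_knee < 30


class TestPotentialDistance:
    def test_identical_rows_at_zero_distance(self):
        p = DiffusionOperator(np.full((3, 3), 1 / 3), ["a", "b", "c"])
        d = potential_distance(p)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_two_state_chain_closed_form(self):
        p = DiffusionOperator(np.array([[0.9, 0.1], [0.1, 0.9]]), ["a", "b"])
        d = potential_distance(p, eps=1e-12)
        expected = np.sqrt(2.0) * abs(np.log(0.9 / 0.1))
        assert d.values[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_permutation_equivariance(self, rng):
        a = rng.uniform(size=(6, 6))
        p = diffusion_operator(_sim(0.5 * (a + a.T)))
        d = potential_distance(p).values
        perm = rng.permutation(6)
        pp = DiffusionOperator(p.values[np.ix_(perm, perm)],
                               [p.sample_ids[i] for i in perm])
        dp = potential_distance(pp).values
        np.testing.assert_allclose(dp, d[np.ix_(perm, perm)], atol=1e-12)

    def test_nonpositive_eps_rejected(self):
        p = DiffusionOperator(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError):
            potential_distance(p, eps=0.0)


class TestMdsEmbed:
    def test_345_triangle_embeds_exactly_in_2d(self):
        d = DistanceMatrix(np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]]),
                           ["a", "b", "c"])
        e = mds_embed(d)
        from scipy.spatial.distance import pdist

        got = np.sort(pdist(e.coords))
        np.testing.assert_allclose(got, [3, 4, 5], atol=1e-6)
        np.testing.assert_allclose(e.coords.mean(0), 0.0, atol=1e-8)

    def test_deterministic_under_repeat(self, rng):
        pts = rng.normal(size=(8, 4))
        d = _dist_from(pts)
        e1, e2 = mds_embed(d), mds_embed(d)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_all_zero_distances_collapse_to_origin(self):
        d = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        e = mds_embed(d)
        assert np.all(e.coords == 0.0)
        assert e.stress == 0.0

    def test_smacof_does_not_increase_stress(self, rng):
        # the refined stress must not exceed the classical-MDS stress
        from omicsfuse.embed import _classical_mds, _stress

        pts = rng.normal(size=(15, 6))
        d = _dist_from(pts)
        init_stress = _stress(d.values, _classical_mds(d.values**2))
        e = mds_embed(d)
        assert e.stress <= init_stress + 1e-9


def _dist_from(pts):
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, [f"s{i}" for i in range(len(pts))])


class TestPhate:
    def test_separated_blobs_stay_separated(self, rng):
        pts = np.concatenate([rng.normal(0, 0.3, (12, 5)), rng.normal(20, 0.3, (12, 5))])
        m = OmicsMatrix(pts, [f"s{i}" for i in range(24)],
                        [f"g{j}" for j in range(5)], "expression")
        e = phate(m, PhateConfig(knn=3, t="auto"))
        c0, c1 = e.coords[:12].mean(0), e.coords[12:].mean(0)
        scatter = lambda x, c: np.linalg.norm(x - c, axis=1).mean()
        spread = 0.5 * (scatter(e.coords[:12], c0) + scatter(e.coords[12:], c1))
        assert np.linalg.norm(c0 - c1) > 5 * max(spread, 1e-12)

    def test_precomputed_block_similarity_separates_blocks(self):
        w = np.full((8, 8), 1e-12)
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        e = phate(_sim(w), PhateConfig(t=50))
        a, b = e.coords[:4], e.coords[4:]
        # convex hulls cannot overlap when every a-point is far from every b-point
        gap = min(np.linalg.norm(x - y) for x in a for y in b)
        within = max(a.std(), b.std())
        assert gap > 3 * within

    def test_permutation_equivariance_up_to_rigid_motion(self, rng):
        from scipy.spatial import procrustes

        pts = rng.normal(size=(14, 4))
        ids = [f"s{i}" for i in range(14)]
        m = OmicsMatrix(pts, ids, [f"g{j}" for j in range(4)], "expression")
        e = phate(m, PhateConfig(knn=3, t=5))
        perm = rng.permutation(14)
        mp = OmicsMatrix(pts[perm], [ids[i] for i in perm],
                         [f"g{j}" for j in range(4)], "expression")
        ep = phate(mp, PhateConfig(knn=3, t=5))
        _, _, disparity = procrustes(e.coords[perm], ep.coords)
        assert disparity < 1e-6
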