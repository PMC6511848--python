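"""Kernel factorization, landmark solve and cross-species scores."""

import networkx as nx
import numpy as np
import pytest

from munk.embedding import (
    EmbeddingMatrix,
    LandmarkList,
    cross_species_scores,
    embed_target,
    factorize_kernel,
    select_landmarks,
    to_dissimilarity,
)
from munk.graph_io import HomologPairs
from munk.kernels import KernelMatrix, regularized_laplacian
from .conftest import net_from_edges


def kernel_of(net, lam=1.0):
    return regularized_laplacian(net, lam)


class TestFactorization:
    def test_identity_kernel(self):
        k = KernelMatrix(("a", "b", "c"), np.eye(3), 1.0)
        c = factorize_kernel(k)
        np.testing.assert_allclose(c.coords @ c.coords.T, np.eye(3), atol=1e-10)

    def test_single_edge_reconstruction(self, single_edge_net):
        k = kernel_of(single_edge_net)
        c = factorize_kernel(k)
        assert c.k == 2
        assert np.max(np.abs(c.coords @ c.coords.T - k.values)) < 1e-10

    def test_rank_one_matrix(self):
        v = np.array([1.0, 2.0, 2.0])
        k = KernelMatrix(("a", "b", "c"), np.outer(v, v), 1.0)
        c = factorize_kernel(k)
        assert c.k == 1
        np.testing.assert_allclose(c.coords @ c.coords.T, np.outer(v, v), atol=1e-8)

    def test_negative_eigenvalue_rejected(self):
        k = KernelMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0)
        with pytest.raises(ValueError, match="kernel"):
            factorize_kernel(k)

    @pytest.mark.parametrize("seed", range(10))
    def test_reconstruction_random_graphs(self, seed):
        g = nx.gnp_random_graph(int(np.random.default_rng(seed).integers(10, 120)),
                                0.1, seed=seed)
        net = net_from_edges(g.edges, extra_nodes=g.nodes)
        k = kernel_of(net, lam=0.5)
        c = factorize_kernel(k)
        assert np.max(np.abs(c.coords @ c.coords.T - k.values)) < 1e-8


class TestLandmarkSelection:
    def make_candidates(self):
        return HomologPairs(tuple((f"s{i}", f"t{i}") for i in range(5)))

    def nets(self):
        # s0/t0 are hubs of stars; everyone else degree 1
        n1 = net_from_edges([("s0", f"s{i}") for i in range(1, 5)])
        n2 = net_from_edges([("t0", f"t{i}") for i in range(1, 5)])
        return n1, n2

    def test_all_candidates_selected_when_n_equals(self):
        n1, n2 = self.nets()
        cand = self.make_candidates()
        for strategy in ("random", "degree"):
            lm = select_landmarks(cand, 5, strategy, 0, n1, n2)
            assert sorted(lm.pairs) == sorted(cand.pairs)

    def test_degree_strategy_puts_hub_pair_first(self):
        n1, n2 = self.nets()
        lm = select_landmarks(self.make_candidates(), 2, "degree", 0, n1, n2)
        assert lm.pairs[0] == ("s0", "t0")

    def test_random_is_seed_deterministic(self):
        n1, n2 = self.nets()
        cand = self.make_candidates()
        a = select_landmarks(cand, 3, "random", 42, n1, n2)
        b = select_landmarks(cand, 3, "random", 42, n1, n2)
        c = select_landmarks(cand, 3, "random", 43, n1, n2)
        assert a.pairs == b.pairs
        assert set(a.pairs) != set(c.pairs) or a.pairs != c.pairs

    def test_too_many_requested(self):
        n1, n2 = self.nets()
        with pytest.raises(ValueError):
            select_landmarks(self.make_candidates(), 6, "random", 0, n1, n2)


class TestEmbedTarget:
    def test_identity_network_all_landmarks_reproduces_kernel(self, triangle_net):
        k = kernel_of(triangle_net)
        c1 = factorize_kernel(k)
        lm = LandmarkList(tuple((v, v) for v in triangle_net.nodes))
        c2hat = embed_target(c1, k, lm)
        d12 = cross_species_scores(c1, c2hat)
        assert np.max(np.abs(d12.values - k.values)) < 1e-8

    def test_single_edge_one_landmark_hand_value(self, single_edge_net):
        # both networks are a single edge; one landmark anchors node a <-> a'
        k1 = kernel_of(single_edge_net, lam=1.0)
        net2 = net_from_edges([("a'", "b'")])
        k2 = kernel_of(net2, lam=1.0)
        c1 = factorize_kernel(k1)
        lm = LandmarkList((("a", "a'"),))
        d12 = cross_species_scores(c1, embed_target(c1, k2, lm)).values
        expected = np.array([[2 / 3, 1 / 3], [1 / 3, 1 / 6]])
        np.testing.assert_allclose(d12, expected, atol=1e-10)
        # independent least-squares oracle for the same solve
        c1l = c1.coords[[0]]
        d2l = k2.values[[0]]
        c2hat_t, *_ = np.linalg.lstsq(c1l, d2l, rcond=None)
        np.testing.assert_allclose(c1.coords @ c2hat_t, expected, atol=1e-10)

    def test_landmark_constraint_full_row_rank(self, world):
        pos1 = {v: i for i, v in enumerate(world.c1.node_index)}
        pos2 = {v: i for i, v in enumerate(world.c2hat.node_index)}
        c1l = world.c1.coords[[pos1[s] for s, _ in world.landmarks.pairs]]
        d2 = regularized_laplacian(world.core2)
        d2l = d2.values[[pos2[t] for _, t in world.landmarks.pairs]]
        assert np.linalg.matrix_rank(c1l) == len(world.landmarks)
        assert np.max(np.abs(c1l @ world.c2hat.coords.T - d2l)) < 1e-6

    def test_minimum_norm_among_solutions(self):
        # fewer landmarks than dimensions -> nontrivial null space
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        k1 = kernel_of(net)
        net2 = net_from_edges([("w", "x"), ("x", "y"), ("y", "z"), ("z", "w")])
        k2 = kernel_of(net2)
        c1 = factorize_kernel(k1)
        lm = LandmarkList((("a", "w"), ("b", "x")))
        c2hat = embed_target(c1, k2, lm)
        c1l = c1.coords[[0, 1]]
        pinv = np.linalg.pinv(c1l)
        null_proj = np.eye(c1.k) - pinv @ c1l
        rng = np.random.default_rng(0)
        base = np.linalg.norm(c2hat.coords.T)
        for _ in range(5):
            w = rng.normal(size=(c1.k, k2.values.shape[0]))
            z = null_proj @ w
            perturbed = c2hat.coords.T + z
            # constraint still satisfied, norm strictly larger
            assert np.max(np.abs(c1l @ perturbed - k2.values[[0, 1]])) < 1e-8
            assert np.linalg.norm(perturbed) > base + 1e-9

    def test_empty_landmarks_rejected(self):
        with pytest.raises(ValueError):
            LandmarkList(())

    def test_orthogonal_invariance_of_scores(self, world):
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(world.c1.k, world.c1.k)))
        rotated = EmbeddingMatrix(world.c1.node_index, world.c1.coords @ q, True)
        d2 = regularized_laplacian(world.core2)
        c2hat_rot = embed_target(rotated, d2, world.landmarks)
        d12_rot = cross_species_scores(rotated, c2hat_rot)
        assert np.max(np.abs(d12_rot.values - world.scores.values)) < 1e-8


class TestDissimilarity:
    def test_reciprocal_and_sentinel(self, world):
        v = np.array([[2.0, 0.0], [-1.0, 4.0]])
        from munk.embedding import CrossSpeciesScores

        s = CrossSpeciesScores(("a", "b"), ("x", "y"), v)
        d = to_dissimilarity(s).values
        assert d[0, 0] == 0.5 and d[1, 1] == 0.25
        assert np.isinf(d[0, 1]) and np.isinf(d[1, 0])

    def test_monotone_reversal(self):
        from scipy.stats import spearmanr

        from munk.embedding import CrossSpeciesScores

        rng = np.random.default_rng(3)
        v = rng.uniform(0.1, 5.0, size=(6, 7))
        s = CrossSpeciesScores(tuple("abcdef"), tuple("tuvwxyz"), v)
        d = to_dissimilarity(s).values
        rho = spearmanr(v.ravel(), d.ravel()).statistic
        assert rho == pytest.approx(-1.0)
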