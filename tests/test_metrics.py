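"""Unit and property tests for the graph-topology metrics."""

import numpy as np
import pytest

from conntopo import metrics as M

import oracles
from conftest import random_weighted_graph


def path_graph(weights=(1.0, 1.0)) -> np.ndarray:
    n = len(weights) + 1
    W = np.zeros((n, n))
    for i, w in enumerate(weights):
        W[i, i + 1] = W[i + 1, i] = w
    return W


def complete_graph(n: int, w: float = 1.0) -> np.ndarray:
    W = np.full((n, n), w, dtype=float)
    np.fill_diagonal(W, 0.0)
    return W


class TestElementaryExamples:
    def test_degree_triangle_path_empty(self):
        assert (M.degree_centrality(complete_graph(3)) == [2, 2, 2]).all()
        assert (M.degree_centrality(path_graph()) == [1, 2, 1]).all()
        assert (M.degree_centrality(np.zeros((4, 4))) == 0).all()

    def test_shortest_paths_inverse_weight(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert M.shortest_path_matrix(W)[0, 1] == pytest.approx(2.0)
        D = M.shortest_path_matrix(path_graph())
        assert D[0, 2] == pytest.approx(2.0)
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        assert np.isinf(M.shortest_path_matrix(W)[0, 2])

    def test_characteristic_path_length(self):
        D = M.shortest_path_matrix(path_graph())
        assert M.characteristic_path_length(D) == (pytest.approx(4 / 3), 0)
        D = M.shortest_path_matrix(complete_graph(4))
        assert M.characteristic_path_length(D)[0] == pytest.approx(1.0)
        # two components {0,1} and {2}: mean over finite pairs, 2 excluded
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        lp, excluded = M.characteristic_path_length(M.shortest_path_matrix(W))
        assert lp == pytest.approx(1.0)
        assert excluded == 2
        with pytest.raises(ValueError):
            M.characteristic_path_length(M.shortest_path_matrix(np.zeros((3, 3))))

    def test_efficiencies(self):
        D = M.shortest_path_matrix(path_graph())
        assert M.global_efficiency(D) == pytest.approx(5 / 6)
        assert M.nodal_efficiency(D)[0] == pytest.approx(0.75)
        assert M.global_efficiency(M.shortest_path_matrix(np.zeros((4, 4)))) == 0.0

    def test_clustering(self):
        c, cp = M.clustering_coefficients(complete_graph(3))
        assert np.allclose(c, 1.0) and cp == pytest.approx(1.0)
        c, cp = M.clustering_coefficients(path_graph())
        assert np.allclose(c, 0.0) and cp == 0.0
        # equal weights cancel under max-normalisation
        c, _ = M.clustering_coefficients(complete_graph(3, w=0.37))
        assert np.allclose(c, 1.0)

    def test_local_efficiency(self):
        eloc, mean_eloc = M.local_efficiency(complete_graph(3))
        assert np.allclose(eloc, 1.0) and mean_eloc == pytest.approx(1.0)
        eloc, _ = M.local_efficiency(path_graph())
        assert eloc[1] == 0.0  # middle node's neighbours are unconnected
        assert eloc[0] == 0.0  # leaf convention

    def test_betweenness(self):
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        bc = M.betweenness_centrality(star)
        assert bc[0] == pytest.approx(6.0)  # C(4,2)
        assert np.allclose(bc[1:], 0.0)
        assert np.allclose(M.betweenness_centrality(path_graph()), [0, 1, 0])
        assert np.allclose(M.betweenness_centrality(complete_graph(5)), 0.0)

    def test_detect_hubs(self):
        assert list(M.detect_hubs([1, 1, 1, 1, 6])) == [4]
        assert list(M.detect_hubs([3, 3, 3])) == []
        assert list(M.detect_hubs([0, 0, 10, 10])) == []
        with pytest.raises(ValueError):
            M.detect_hubs([1.0])

    def test_auc_over_sparsity(self):
        grid = 0.05 + 0.01 * np.arange(19)
        assert M.auc_over_sparsity(np.ones(19), grid) == pytest.approx(0.19)
        assert M.auc_over_sparsity(np.zeros(19), grid) == 0.0
        assert M.auc_over_sparsity(grid, grid) == pytest.approx(0.0266)
        with pytest.raises(ValueError):
            M.auc_over_sparsity(np.ones(5), grid)


class TestOracleEquivalence:
    @pytest.mark.parametrize("dyadic", [False, True])
    def test_all_metrics_match_bruteforce(self, dyadic):
        rng = np.random.default_rng(12345 + dyadic)
        for _ in range(12):
            n = int(rng.integers(3, 9))
            W = random_weighted_graph(n, rng, density=0.6, dyadic=dyadic)
            D = M.shortest_path_matrix(W)
            assert np.allclose(D, oracles.fw_distances(W), atol=1e-9)
            assert np.allclose(
                M.nodal_efficiency(D), oracles.nodal_eff(W), atol=1e-9
            )
            assert M.global_efficiency(D) == pytest.approx(
                oracles.global_eff(W), abs=1e-9
            )
            c, _ = M.clustering_coefficients(W)
            assert np.allclose(c, oracles.clustering(W), atol=1e-9)
            eloc, _ = M.local_efficiency(W)
            assert np.allclose(eloc, oracles.local_eff(W), atol=1e-9)
            assert (M.degree_centrality(W) == oracles.degree(W)).all()
            if dyadic:  # exact tie handling required for path counting
                assert np.allclose(
                    M.betweenness_centrality(W), oracles.betweenness(W), atol=1e-9
                )

    def test_binary_reduction(self):
        # with unit weights the weighted formulas equal their binary forms
        rng = np.random.default_rng(7)
        W = (random_weighted_graph(7, rng, density=0.5) > 0).astype(float)
        c, _ = M.clustering_coefficients(W)
        assert np.allclose(c, oracles.clustering(W), atol=1e-12)
        D = M.shortest_path_matrix(W)
        hops = oracles.fw_distances(W)
        assert np.allclose(D, hops, atol=1e-12)


class TestInvariants:
    def test_node_relabelling_permutes_metrics(self):
        rng = np.random.default_rng(3)
        W = random_weighted_graph(8, rng, density=0.6)
        perm = rng.permutation(8)
        Wp = W[np.ix_(perm, perm)]
        ne = M.nodal_efficiency(M.shortest_path_matrix(W))
        nep = M.nodal_efficiency(M.shortest_path_matrix(Wp))
        assert np.allclose(nep, ne[perm], atol=1e-12)
        _, cp = M.clustering_coefficients(W)
        _, cpp = M.clustering_coefficients(Wp)
        assert cp == pytest.approx(cpp, abs=1e-12)
        bc = M.betweenness_centrality(W)
        bcp = M.betweenness_centrality(Wp)
        assert np.allclose(bcp, bc[perm], atol=1e-9)

    def test_adding_edge_never_increases_distances(self):
        rng = np.random.default_rng(4)
        W = random_weighted_graph(8, rng, density=0.4)
        D0 = M.shortest_path_matrix(W)
        zero = np.argwhere(np.triu(W == 0, k=1))
        i, j = zero[rng.integers(len(zero))]
        W2 = W.copy()
        W2[i, j] = W2[j, i] = 1.0
        D1 = M.shortest_path_matrix(W2)
        assert (D1 <= D0 + 1e-12).all()


class TestMatchedRandomNetworks:
    def test_degree_sequence_and_weights_preserved(self):
        rng = np.random.default_rng(0)
        W = random_weighted_graph(12, rng, density=0.4)
        deg = M.degree_centrality(W)
        weights = np.sort(W[np.triu_indices(12, 1)][W[np.triu_indices(12, 1)] > 0])
        for R in M.iter_matched_random(W, 5, rng):
            assert (M.degree_centrality(R) == deg).all()
            rw = np.sort(R[np.triu_indices(12, 1)][R[np.triu_indices(12, 1)] > 0])
            assert np.allclose(rw, weights)

    def test_triangle_topology_unchanged(self):
        W = complete_graph(3)
        W[0, 1] = W[1, 0] = 0.5
        with pytest.warns(UserWarning, match="no valid degree-preserving swap"):
            nets = M.matched_random_networks(W, 3, np.random.default_rng(0))
        for R in nets:
            assert ((R > 0) == (W > 0)).all()
            assert np.allclose(np.sort(R[R > 0]), np.sort(W[W > 0]))

    def test_lattice_clustering_above_random(self):
        n, k = 40, 3
        W = np.zeros((n, n))
        for d in range(1, k + 1):
            for i in range(n):
                j = (i + d) % n
                W[i, j] = W[j, i] = 1.0
        _, cp_lattice = M.clustering_coefficients(W)
        rng = np.random.default_rng(1)
        cps = []
        for R in M.iter_matched_random(W, 30, rng):
            _, cpr = M.clustering_coefficients(R)
            cps.append(cpr)
        mean, sd = np.mean(cps), np.std(cps, ddof=1)
        assert cp_lattice > mean + 3 * sd / np.sqrt(len(cps))

    def test_small_world_identity(self):
        rng = np.random.default_rng(2)
        W = random_weighted_graph(10, rng, density=0.6)
        gamma, lam, sigma = M.small_world_indices(W, [W, W])
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)
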