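"""Spectral stage: normalized spectrum, sweep cut, k-means embedding,
and the end-to-end detector."""

import numpy as np
import pytest

from cliquecond import (
    Graph,
    Partition,
    brute_force_optimum,
    detect_communities,
    induced_clique_graph,
    kmeans_embed_partition,
    maximal_cliques,
    nmi,
    normalized_spectrum,
    sweep_bipartition,
)
from cliquecond.datasets import karate_club, karate_factions

from conftest import random_graph


def clique_graph(g):
    return induced_clique_graph(g, maximal_cliques(g))


def blocks(p: Partition):
    return {frozenset(s) for s in p.as_sets()}


class TestNormalizedSpectrum:
    def test_complete_graph_lambda2(self):
        # K_n's normalized Laplacian has lambda2 = n/(n-1); the uniform
        # clique weights cancel in the normalization
        for n in (3, 4, 6):
            g = Graph([str(i) for i in range(n)],
                      [(i, j) for i in range(n) for j in range(i + 1, n)])
            basis = normalized_spectrum(clique_graph(g), 2)
            assert basis.eigenvalues[1] == pytest.approx(n / (n - 1), abs=1e-10)

    def test_disconnected_has_zero_multiplicity_two(self, two_triangles):
        basis = normalized_spectrum(clique_graph(two_triangles), 2)
        assert abs(basis.eigenvalues[0]) < 1e-8
        assert abs(basis.eigenvalues[1]) < 1e-8

    def test_connected_lambda2_positive(self):
        rng = np.random.default_rng(1)
        from cliquecond import connected_components

        done = 0
        while done < 10:
            g = random_graph(rng, 10, 0.5)
            if len(connected_components(g)) != 1:
                continue
            basis = normalized_spectrum(clique_graph(g), 3)
            assert basis.eigenvalues[1] > 1e-10
            # spectrum within [0, 2], first eigenvalue 0, orthonormal vectors
            assert abs(basis.eigenvalues[0]) < 1e-8
            assert basis.eigenvalues[-1] <= 2 + 1e-8
            gram = basis.eigenvectors.T @ basis.eigenvectors
            assert np.allclose(gram, np.eye(3), atol=1e-8)
            done += 1

    def test_m_too_large_rejected(self, triangle):
        with pytest.raises(ValueError, match="exceeds"):
            normalized_spectrum(clique_graph(triangle), 4)

    def test_zero_degree_vertex_named(self):
        g = Graph("abc", [(0, 1)])
        with pytest.raises(ValueError, match="'c'"):
            normalized_spectrum(clique_graph(g), 2)


class TestSweep:
    def test_bridge_of_triangles_optimum(self, bridge_triangles):
        res = sweep_bipartition(clique_graph(bridge_triangles))
        assert res.phi_hat == pytest.approx(0.1)
        assert res.A in ({0, 1, 2}, {3, 4, 5})

    def test_disconnected_returns_component_split(self, two_triangles):
        res = sweep_bipartition(clique_graph(two_triangles))
        assert res.phi_hat == 0.0
        assert res.A in ({0, 1, 2}, {3, 4, 5})

    def test_phi_hat_is_sweep_minimum_and_lemma3(self):
        rng = np.random.default_rng(23)
        from cliquecond import connected_components

        done = 0
        while done < 15:
            g = random_graph(rng, int(rng.integers(5, 13)), 0.4)
            if len(connected_components(g)) != 1:
                continue
            res = sweep_bipartition(clique_graph(g))
            assert res.phi_hat == pytest.approx(res.sweep_trace.min())
            assert res.lambda2 >= res.phi_hat**2 / 2 - 1e-8
            done += 1

    def test_within_theorem4_band_of_brute_force(self):
        rng = np.random.default_rng(29)
        from cliquecond import connected_components

        done = 0
        while done < 15:
            g = random_graph(rng, int(rng.integers(5, 12)), 0.5)
            if len(connected_components(g)) != 1:
                continue
            res = sweep_bipartition(clique_graph(g))
            _, phi_star = brute_force_optimum(g)
            assert phi_star <= res.phi_hat + 1e-12
            assert res.phi_hat <= 2 * np.sqrt(phi_star) + 1e-8
            done += 1

    def test_sign_invariance_of_sweep(self, bridge_triangles):
        """Prefixes of the reversed order are complements of suffixes, so the
        best Cheeger ratio cannot depend on the eigenvector's sign."""
        C = clique_graph(bridge_triangles)
        basis = normalized_spectrum(C, 2)
        for sign in (+1.0, -1.0):
            flipped = type(basis)(
                basis.eigenvalues, basis.eigenvectors * sign, basis.degree_scaling
            )
            import cliquecond.spectral as sp

            order = sp._sweep_order(flipped)
            # evaluate all prefixes directly
            ratios = []
            from cliquecond import cheeger_ratio

            for i in range(1, C.n):
                ratios.append(cheeger_ratio(C, set(int(v) for v in order[:i])))
            assert min(ratios) == pytest.approx(0.1)


class TestKMeansEmbedding:
    def test_three_components_recovered_exactly(self):
        g = Graph(
            [str(i) for i in range(9)],
            [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (6, 7), (6, 8), (7, 8)],
        )
        basis = normalized_spectrum(clique_graph(g), 3)
        p = kmeans_embed_partition(basis, 3, seed=0)
        assert blocks(p) == {
            frozenset({0, 1, 2}),
            frozenset({3, 4, 5}),
            frozenset({6, 7, 8}),
        }

    def test_gn_flat_top_recovery(self):
        from cliquecond import generate_gn

        scores = []
        for seed in range(5):
            bench = generate_gn(1.0, seed=seed + 100)
            det = detect_communities(bench.graph, m=4, seed=seed)
            scores.append(nmi(bench.truth, det.partition))
        assert np.mean(scores) >= 0.99

    def test_seed_stability_on_separated_input(self):
        from cliquecond import generate_gn

        bench = generate_gn(1.0, seed=5)
        p1 = detect_communities(bench.graph, m=4, seed=11).partition
        p2 = detect_communities(bench.graph, m=4, seed=999).partition
        assert blocks(p1) == blocks(p2)


class TestDetectCommunities:
    def test_karate_single_disagreement_is_node9(self):
        g = karate_club()
        truth = karate_factions(g)
        det = detect_communities(g, m=2, seed=0)
        p, t = det.partition.assignment, truth.assignment
        direct, flipped = int((p != t).sum()), int((p != 1 - t).sum())
        assert min(direct, flipped) == 1
        wrong = np.flatnonzero(p != t if direct < flipped else p != 1 - t)
        assert [g.labels[v] for v in wrong] == ["9"]

    def test_two_five_cliques_with_bridge(self):
        K = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges = K + [(i + 5, j + 5) for i, j in K] + [(4, 5)]
        g = Graph([str(i) for i in range(10)], edges)
        det = detect_communities(g, m=2, seed=0)
        assert blocks(det.partition) == {
            frozenset(range(5)),
            frozenset(range(5, 10)),
        }
        _, phi_star = brute_force_optimum(g)
        assert det.phi_hat == pytest.approx(phi_star)

    def test_permutation_equivariance(self, bridge_triangles):
        g = bridge_triangles
        rng = np.random.default_rng(31)
        perm = rng.permutation(g.n)  # new index of old vertex v is perm[v]
        g2 = Graph(
            [g.labels[int(np.flatnonzero(perm == i)[0])] for i in range(g.n)],
            [(int(perm[u]), int(perm[v])) for u, v in g.edges],
        )
        p1 = detect_communities(g, m=2, seed=0).partition
        p2 = detect_communities(g2, m=2, seed=0).partition
        lab_blocks_1 = {frozenset(g.labels[v] for v in s) for s in p1.as_sets()}
        lab_blocks_2 = {frozenset(g2.labels[v] for v in s) for s in p2.as_sets()}
        assert lab_blocks_1 == lab_blocks_2

    def test_isolated_vertices_become_singletons(self):
        g = Graph("abcdef", [(0, 1), (0, 2), (1, 2), (3, 4)])  # 'f' isolated
        det = detect_communities(g, m=2, seed=0)
        assert det.n_isolated == 1
        assert det.partition.m == 3
        assert {5} in [s for s in det.partition.as_sets()]

    def test_m_bounds_checked(self, triangle):
        with pytest.raises(ValueError):
            detect_communities(triangle, m=1)
        with pytest.raises(ValueError):
            detect_communities(triangle, m=4)

    def test_m2_disconnected_returns_zero_conductance_split(self, two_triangles):
        det = detect_communities(two_triangles, m=2, seed=0)
        assert det.phi_hat == 0.0
        assert blocks(det.partition) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
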