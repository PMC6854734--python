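import math

import numpy as np
import pytest
from sklearn.base import clone

from comorbnet import (
    DiseaseNetwork,
    DiseaseSeedMap,
    ProteinGraph,
    QStepNetworkBuilder,
    SyntheticSpec,
    build_layer_network,
    build_layers,
    build_network,
    cosine_distance,
    expand_vectors,
    gaussian_similarity,
    generate,
    integrate_networks,
    network_density,
    reachable_within,
)


def random_graph(rng, n, p=0.15):
    names = [f"n{i}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return ProteinGraph(names, edges)


class TestReachableWithin:
    @pytest.mark.parametrize(
        "q,expected",
        [
            (0, {"P2", "P3"}),
            (1, {"P1", "P2", "P3", "P4"}),
            (2, {"P1", "P2", "P3", "P4", "P5"}),
            (3, {"P1", "P2", "P3", "P4", "P5", "P6"}),
        ],
    )
    def test_toy_walks(self, toy_graph, q, expected):
        assert reachable_within(toy_graph, {"P2", "P3"}, q) == expected

    def test_unknown_seed_errors(self, toy_graph):
        with pytest.raises(ValueError, match="seed protein"):
            reachable_within(toy_graph, {"P99"}, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_walk_enumeration(self, seed):
        """Oracle: v is reachable by a walk of length <= q iff ((A+I)^q)[s,v] > 0."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        g = random_graph(rng, n)
        names = list(g.proteins)
        A = g.adjacency().toarray().astype(np.int64)
        reach_mat = np.eye(n, dtype=np.int64) + A
        q = int(rng.integers(0, 5))
        M = np.linalg.matrix_power(reach_mat, q) if q else np.eye(n, dtype=np.int64)
        seeds = set(rng.choice(names, size=max(1, n // 5), replace=False))
        seed_idx = [names.index(s) for s in seeds]
        expected = {names[v] for v in range(n) if M[seed_idx, v].sum() > 0}
        assert reachable_within(g, seeds, q) == expected

    def test_exact_mode_returns_frontier(self, toy_graph):
        assert reachable_within(toy_graph, {"P2", "P3"}, 2, "exact") == {"P5"}
        assert reachable_within(toy_graph, {"P2", "P3"}, 0, "exact") == {"P2", "P3"}


class TestExpandVectors:
    def test_toy_rows(self, toy_graph, toy_seeds):
        v0 = expand_vectors(toy_seeds, toy_graph, 0)
        assert v0.row("D_A") == {"P2", "P3"}
        assert v0.indicator.sum(axis=1).tolist() == [2, 1, 1]
        v1 = expand_vectors(toy_seeds, toy_graph, 1)
        assert v1.row("D_A") == {"P1", "P2", "P3", "P4"}

    def test_rows_nested_in_q(self, toy_graph, toy_seeds):
        prev = expand_vectors(toy_seeds, toy_graph, 0).indicator
        for q in range(1, 5):
            cur = expand_vectors(toy_seeds, toy_graph, q).indicator
            assert (prev <= cur).all()
            prev = cur

    def test_fixed_point_after_component_closure(self, toy_graph, toy_seeds):
        v4 = expand_vectors(toy_seeds, toy_graph, 4).indicator
        v9 = expand_vectors(toy_seeds, toy_graph, 9).indicator
        assert (v4 == v9).all()

    def test_matches_setwise_bfs(self, toy_graph, toy_seeds):
        for q in range(4):
            vecs = expand_vectors(toy_seeds, toy_graph, q)
            for d in toy_seeds.diseases:
                assert vecs.row(d) == reachable_within(
                    toy_graph, toy_seeds.seeds[d], q
                )


class TestSimilarity:
    def test_cosine_identity_and_disjoint(self):
        assert cosine_distance([1, 0, 1], [1, 0, 1]) == 0.0
        assert cosine_distance([1, 0, 0], [0, 1, 1]) == 1.0

    def test_cosine_worked_example(self):
        assert cosine_distance([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5, abs=1e-15)

    def test_cosine_zero_vector_errors(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance([0, 0], [1, 0])

    def test_gaussian_values(self):
        assert gaussian_similarity(0.0, 1.0, True) == 1.0
        assert gaussian_similarity(0.3, 1.0, False) == 0.0
        assert gaussian_similarity(1.0, 1.0, True) == pytest.approx(
            math.exp(-1), abs=1e-15
        )

    def test_gaussian_monotone_in_distance(self):
        d = np.linspace(0, 1, 11)
        w = [gaussian_similarity(x, 0.7, True) for x in d]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_gaussian_invalid_inputs(self):
        with pytest.raises(ValueError):
            gaussian_similarity(-0.1, 1.0, True)
        with pytest.raises(ValueError):
            gaussian_similarity(0.1, 0.0, True)


class TestLayerNetworks:
    def test_toy_q0_single_edge(self, toy_graph, toy_seeds):
        net = build_network(toy_graph, toy_seeds, 0)
        i, j = net.index("D_B"), net.index("D_C")
        assert net.n_edges == 1
        assert net.weights[i, j] == pytest.approx(1.0, abs=1e-15)

    def test_toy_q1_all_edges_present(self, toy_graph, toy_seeds):
        net = build_network(toy_graph, toy_seeds, 1)
        a, b, c = (net.index(d) for d in ("D_A", "D_B", "D_C"))
        assert net.weights[a, b] > 0 and net.weights[a, c] > 0 and net.weights[b, c] > 0

    def test_toy_q1_one_sided_weight(self, toy_graph, toy_seeds):
        """D_A expanded (P1..P4, norm 2) vs D_B seeds (P1): dist 1/2."""
        net = build_network(toy_graph, toy_seeds, 1, sigma=1.0)
        assert net.weights[net.index("D_A"), net.index("D_B")] == pytest.approx(
            math.exp(-0.5), abs=1e-12
        )

    def test_toy_q1_mutual_weight(self, toy_graph, toy_seeds):
        """Both expanded: D_A (P1..P4) vs D_B (P1,P2): dist 1 - 2/(2*sqrt(2))."""
        net = build_network(toy_graph, toy_seeds, 1, comparison="mutual")
        expected = math.exp(-(1 - 2 / (2 * math.sqrt(2))))
        assert net.weights[net.index("D_A"), net.index("D_B")] == pytest.approx(
            expected, abs=1e-12
        )

    def test_build_layer_network_matches_build_network(self, toy_graph, toy_seeds):
        v1 = expand_vectors(toy_seeds, toy_graph, 1)
        v0 = expand_vectors(toy_seeds, toy_graph, 0)
        direct = build_layer_network(v1, base=v0)
        assert direct == build_network(toy_graph, toy_seeds, 1)

    def test_exact_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, 25)
        seeds = {
            f"d{i}": frozenset(
                rng.choice(list(g.proteins), size=rng.integers(1, 4), replace=False)
            )
            for i in range(8)
        }
        net = build_network(g, DiseaseSeedMap(seeds), 2)
        assert (net.weights == net.weights.T).all()
        assert np.diag(net.weights).sum() == 0.0

    def test_permutation_equivariance(self, toy_graph, toy_seeds):
        renamed = DiseaseSeedMap(
            {
                "Z_was_A": toy_seeds.seeds["D_A"],
                "A_was_B": toy_seeds.seeds["D_B"],
                "M_was_C": toy_seeds.seeds["D_C"],
            }
        )
        net = build_network(toy_graph, toy_seeds, 1)
        net2 = build_network(toy_graph, renamed, 1)
        mapping = {"D_A": "Z_was_A", "D_B": "A_was_B", "D_C": "M_was_C"}
        for d1 in toy_seeds.diseases:
            for d2 in toy_seeds.diseases:
                assert net.weights[net.index(d1), net.index(d2)] == pytest.approx(
                    net2.weights[net2.index(mapping[d1]), net2.index(mapping[d2])],
                    abs=1e-15,
                )


class TestIntegration:
    def test_single_layer_rescaled(self, toy_graph, toy_seeds):
        net = build_network(toy_graph, toy_seeds, 1)
        integ = integrate_networks([net])
        assert np.allclose(integ.weights, net.weights / net.weights.max())

    def test_two_identical_layers_equal_one(self, toy_graph, toy_seeds):
        net = build_network(toy_graph, toy_seeds, 1)
        one = integrate_networks([net])
        two = integrate_networks([net, net])
        assert np.allclose(one.weights, two.weights, rtol=0, atol=1e-15)

    def test_disjoint_layers_union(self):
        a = DiseaseNetwork(("A", "B", "C"),
                           np.array([[0, 0.4, 0], [0.4, 0, 0], [0, 0, 0]]), "q=0")
        b = DiseaseNetwork(("A", "B", "C"),
                           np.array([[0, 0, 0], [0, 0, 0.8], [0, 0.8, 0]]), "q=1")
        integ = integrate_networks([a, b])
        assert integ.n_edges == 2
        assert integ.layer_tag == "integrated 0~1"
        assert integ.weights.max() == 1.0  # rescaled by the max entry

    def test_mismatched_disease_sets_error(self):
        a = DiseaseNetwork(("A", "B"), np.zeros((2, 2)))
        b = DiseaseNetwork(("A", "C"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="different disease sets"):
            integrate_networks([a, b])


class TestDensity:
    def test_extremes(self):
        n = 4
        empty = DiseaseNetwork(tuple("ABCD"), np.zeros((n, n)))
        full = DiseaseNetwork(tuple("ABCD"), np.ones((n, n)) - np.eye(n))
        assert network_density(empty) == 0.0
        assert network_density(full) == 100.0

    def test_toy_q0_one_of_three_pairs(self, toy_graph, toy_seeds):
        net = build_network(toy_graph, toy_seeds, 0)
        assert network_density(net) == pytest.approx(100 / 3, abs=1e-9)

    def test_single_disease_errors(self):
        net = DiseaseNetwork(("A",), np.zeros((1, 1)))
        with pytest.raises(ValueError, match="fewer than 2"):
            network_density(net)

    @pytest.mark.parametrize("seed", range(5))
    def test_density_monotone_in_q(self, seed):
        spec = SyntheticSpec(n_diseases=18, n_proteins=150, n_modules=3, seed=seed)
        graph, seed_map, _ = generate(spec)
        dens = [
            network_density(net)
            for net in build_layers(graph, seed_map, range(4))
        ]
        assert all(a <= b for a, b in zip(dens, dens[1:]))


class TestQStepNetworkBuilder:
    def _toy_inputs(self, toy_graph, toy_seeds):
        order = tuple(sorted(toy_graph.proteins))
        A = toy_graph.adjacency(order=order)
        X = np.zeros((toy_seeds.n_diseases, len(order)), dtype=bool)
        for i, d in enumerate(toy_seeds.diseases):
            for p in toy_seeds.seeds[d]:
                X[i, order.index(p)] = True
        return X, A

    def test_transform_matches_functional_api(self, toy_graph, toy_seeds):
        X, A = self._toy_inputs(toy_graph, toy_seeds)
        est = QStepNetworkBuilder(adjacency=A, q=1)
        W = est.fit_transform(X)
        assert np.allclose(W, build_network(toy_graph, toy_seeds, 1).weights)

    def test_integrated_transform(self, toy_graph, toy_seeds):
        X, A = self._toy_inputs(toy_graph, toy_seeds)
        W = QStepNetworkBuilder(adjacency=A, q=3, integrate=True).fit_transform(X)
        layers = build_layers(toy_graph, toy_seeds, range(4))
        assert np.allclose(W, integrate_networks(layers).weights)

    def test_sklearn_clone_and_params(self, toy_graph):
        A = toy_graph.adjacency()
        est = QStepNetworkBuilder(adjacency=A, q=2, sigma=0.5)
        cloned = clone(est)
        assert cloned.get_params()["q"] == 2
        assert cloned.get_params()["sigma"] == 0.5

    def test_rejects_empty_seed_row(self, toy_graph, toy_seeds):
        X, A = self._toy_inputs(toy_graph, toy_seeds)
        X[0] = False
        with pytest.raises(ValueError, match="at least one seed"):
            QStepNetworkBuilder(adjacency=A).fit(X)
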