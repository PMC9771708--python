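from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ventnet
from ventnet import PresenceMatrix
from ventnet.simnet import DissimilarityMatrix, molloy_reed_kappa

from _oracles import brute_force_betweenness, sorensen_from_sets


def matrix_from_rows(rows):
    """Build a PresenceMatrix from per-site species sets."""
    species = sorted(set().union(*rows))
    values = np.array([[1 if sp in r else 0 for sp in species] for r in rows])
    return PresenceMatrix(
        tuple(f"s{i}" for i in range(len(rows))), tuple(species), values
    )


class TestSorensen:
    def test_identical_assemblages(self):
        m = matrix_from_rows([{"a", "b"}, {"a", "b"}])
        assert ventnet.sorensen_matrix(m).values[0, 1] == 0.0

    def test_disjoint_assemblages(self):
        m = matrix_from_rows([{"a", "b"}, {"c", "d"}])
        assert ventnet.sorensen_matrix(m).values[0, 1] == 1.0

    def test_partial_overlap(self):
        m = matrix_from_rows([{"s1", "s2", "s3"}, {"s2", "s3", "s4"}])
        D = ventnet.sorensen_matrix(m)
        assert D.values[0, 1] == pytest.approx(1 / 3)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_set_operations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sites, n_species = rng.integers(2, 8), rng.integers(2, 12)
        values = rng.random((n_sites, n_species)) < rng.uniform(0.3, 0.9)
        values[values.sum(axis=1) == 0, 0] = True
        keep = values.sum(axis=0) > 0
        values = values[:, keep]
        m = PresenceMatrix(
            tuple(f"s{i}" for i in range(n_sites)),
            tuple(f"p{j}" for j in range(values.shape[1])),
            values.astype(int),
        )
        D = ventnet.sorensen_matrix(m)
        rows = [set(np.nonzero(r)[0]) for r in m.values]
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                assert D.values[i, j] == pytest.approx(
                    sorensen_from_sets(rows[i], rows[j]), abs=1e-12
                )

    def test_adding_shared_species_never_increases_d(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = set(rng.choice(20, size=rng.integers(1, 8), replace=False))
            b = set(rng.choice(20, size=rng.integers(1, 8), replace=False))
            new = 100 + seed  # species recorded at both sites
            before = sorensen_from_sets(a, b)
            after = sorensen_from_sets(a | {new}, b | {new})
            assert after <= before + 1e-12


class TestNetworkConstruction:
    def test_disjoint_sites_have_no_edges(self):
        m = matrix_from_rows([{"a"}, {"b"}, {"c"}])
        net = ventnet.build_similarity_network(ventnet.sorensen_matrix(m))
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 0

    def test_identical_sites_form_unit_triangle(self):
        m = matrix_from_rows([{"a", "b"}] * 3)
        net = ventnet.build_similarity_network(ventnet.sorensen_matrix(m))
        assert net.graph.number_of_edges() == 3
        assert all(s == 1.0 for _, _, s in net.graph.edges(data="similarity"))


class TestPercolationThreshold:
    def test_single_edge_is_already_at_percolation(self):
        D = DissimilarityMatrix(("a", "b"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert ventnet.percolation_threshold(D) == pytest.approx(0.4)

    def test_k4_hand_stepped_sequence(self, k4_dissimilarity):
        d_p = ventnet.percolation_threshold(k4_dissimilarity)
        assert d_p == pytest.approx(0.7)
        net = ventnet.apply_threshold(
            ventnet.build_similarity_network(k4_dissimilarity), d_p
        )
        assert sorted(tuple(sorted(e)) for e in net.graph.edges) == [
            ("A", "D"),
            ("B", "C"),
            ("B", "D"),
        ]

    def test_invariant_to_site_ordering(self, k4_dissimilarity):
        rng = np.random.default_rng(5)
        perm = rng.permutation(4)
        shuffled = DissimilarityMatrix(
            tuple(np.array(k4_dissimilarity.ids)[perm]),
            k4_dissimilarity.values[np.ix_(perm, perm)],
        )
        assert ventnet.percolation_threshold(shuffled) == pytest.approx(
            ventnet.percolation_threshold(k4_dissimilarity)
        )

    def test_edgeless_network_rejected(self):
        m = matrix_from_rows([{"a"}, {"b"}])
        with pytest.raises(ValueError, match="no links"):
            ventnet.percolation_threshold(ventnet.sorensen_matrix(m))

    def test_kappa_of_complete_identical_network(self):
        for n in (3, 5, 8):
            m = matrix_from_rows([{"a", "b", "c"}] * n)
            net = ventnet.build_similarity_network(ventnet.sorensen_matrix(m))
            degrees = np.array([d for _, d in net.graph.degree])
            assert molloy_reed_kappa(degrees) == pytest.approx(n - 1)

    def test_giant_component_criterion(self, k4_dissimilarity):
        d_p = ventnet.percolation_threshold(
            k4_dissimilarity, criterion="giant-component"
        )
        net = ventnet.apply_threshold(
            ventnet.build_similarity_network(k4_dissimilarity), d_p
        )
        assert net.n_components == 1


class TestApplyThreshold:
    def test_threshold_one_is_identity(self, k4_dissimilarity):
        full = ventnet.build_similarity_network(k4_dissimilarity)
        thr = ventnet.apply_threshold(full, 1.0)
        assert set(thr.graph.edges) == set(full.graph.edges)

    def test_threshold_zero_removes_everything_but_nodes(self, k4_dissimilarity):
        full = ventnet.build_similarity_network(k4_dissimilarity)
        thr = ventnet.apply_threshold(full, 0.0)
        assert thr.graph.number_of_edges() == 0
        assert set(thr.graph.nodes) == set(full.graph.nodes)
        assert thr.thresholded

    def test_thresholded_edges_are_subset(self, k4_dissimilarity):
        full = ventnet.build_similarity_network(k4_dissimilarity)
        for d_p in (0.3, 0.65, 0.9):
            thr = ventnet.apply_threshold(full, d_p)
            assert set(thr.graph.edges) <= set(full.graph.edges)
            assert all(
                d < d_p for _, _, d in thr.graph.edges(data="dissimilarity")
            )


class TestBetweenness:
    def test_path_centre_scores_one(self):
        m = matrix_from_rows([{"a", "b"}, {"b", "c"}, {"c", "d"}])
        net = ventnet.apply_threshold(
            ventnet.build_similarity_network(ventnet.sorensen_matrix(m)), 1.0
        )
        cb = ventnet.betweenness(net)
        assert cb["s1"] == pytest.approx(1.0)
        assert cb["s0"] == cb["s2"] == 0.0

    def test_star_centre_closed_form(self):
        rows = [{"hub", f"leaf{i}"} for i in range(5)]
        rows.append({"hub"})  # the centre shares only the hub species
        m = matrix_from_rows(rows)
        net = ventnet.apply_threshold(
            ventnet.build_similarity_network(ventnet.sorensen_matrix(m)), 1.0
        )
        # remove leaf-leaf edges to leave a pure star on the centre site s5
        drop = [
            (u, v)
            for u, v in net.graph.edges
            if "s5" not in (u, v)
        ]
        net.graph.remove_edges_from(drop)
        cb = ventnet.betweenness(net, weights="none")
        assert cb["s5"] == pytest.approx(5 * 4 / 2)

    @pytest.mark.parametrize("weights", ["dissimilarity", "none"])
    def test_matches_brute_force_on_random_graphs(self, weights):
        import networkx as nx
        from ventnet.simnet import SimilarityNetwork

        for seed in range(3):
            rng = np.random.default_rng(seed)
            g = nx.gnp_random_graph(7, 0.45, seed=seed)
            for u, v in g.edges:
                g[u][v]["dissimilarity"] = float(rng.uniform(0.1, 0.9))
            net = SimilarityNetwork(graph=g, thresholded=True)
            cb = ventnet.betweenness(net, weights=weights)
            oracle = brute_force_betweenness(
                g, "dissimilarity" if weights == "dissimilarity" else None
            )
            for node in g.nodes:
                assert cb[node] == pytest.approx(oracle[node], abs=1e-9)

    def test_isolated_and_leaf_nodes_score_zero(self, k4_dissimilarity):
        net = ventnet.apply_threshold(
            ventnet.build_similarity_network(k4_dissimilarity), 0.6
        )
        cb = ventnet.betweenness(net)
        for node, deg in net.graph.degree:
            if deg <= 1:
                assert cb[node] == 0.0
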