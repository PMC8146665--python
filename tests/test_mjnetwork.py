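"""Median-joining networks against MST-enumeration and Steiner-point oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from hapsignal.hapcluster import ClusterAssignment
from hapsignal.hapio import ValidationError
from hapsignal.mjnetwork import (
    components_by_edge_filter,
    concordance,
    median_join,
    minimum_spanning_network,
    write_dot,
    write_graphml,
)


def seqs(*strings):
    return np.array([[int(c) for c in s] for s in strings], dtype=np.uint8)


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def mst_weight(points):
    """Minimum spanning tree weight by Kruskal over explicit pairs."""
    pts = list(points)
    g = nx.Graph()
    for i, j in itertools.combinations(range(len(pts)), 2):
        g.add_edge(i, j, weight=hamming(pts[i], pts[j]))
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_tree(g).edges(data=True))


def edges_in_some_mst(points):
    """Union of all minimum spanning trees by exhaustive enumeration."""
    pts = list(points)
    n = len(pts)
    pairs = list(itertools.combinations(range(n), 2))
    best_weight = None
    keep = set()
    for subset in itertools.combinations(pairs, n - 1):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(subset)
        if not nx.is_connected(g):
            continue
        w = sum(hamming(pts[i], pts[j]) for i, j in subset)
        if best_weight is None or w < best_weight:
            best_weight = w
            keep = set()
        if w == best_weight:
            for i, j in subset:
                keep.add(frozenset((tuple(pts[i]), tuple(pts[j]))))
    return keep


class TestMinimumSpanningNetwork:
    def test_two_haplotypes_single_edge(self):
        g = minimum_spanning_network(seqs("000", "111"))
        assert g.number_of_edges() == 1
        assert g.edges[(0, 0, 0), (1, 1, 1)]["weight"] == 3

    def test_star_fixture(self):
        g = minimum_spanning_network(seqs("0000", "1000", "0100", "0010"))
        center = (0, 0, 0, 0)
        assert g.number_of_edges() == 3
        for leaf in [(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0)]:
            assert g.edges[center, leaf]["weight"] == 1

    def test_equidistant_quartet_keeps_all_edges(self):
        # all pairwise distances 2: every edge belongs to some MST
        g = minimum_spanning_network(seqs("0000", "1100", "1010", "0110"))
        assert g.number_of_edges() == 6

    def test_matches_mst_enumeration_oracle(self):
        rng = np.random.default_rng(70)
        for _ in range(10):
            mat = rng.integers(0, 2, size=(6, 7)).astype(np.uint8)
            distinct = sorted({tuple(r) for r in mat})
            if len(distinct) < 3:
                continue
            g = minimum_spanning_network(np.array(distinct))
            got = {frozenset((u, v)) for u, v in g.edges}
            expected = edges_in_some_mst(distinct)
            assert got == expected

    def test_duplicates_collapse_with_multiplicity(self):
        g = minimum_spanning_network(seqs("000", "000", "111"))
        assert g.nodes[(0, 0, 0)]["multiplicity"] == 2

    def test_connected(self):
        rng = np.random.default_rng(71)
        mat = rng.integers(0, 2, size=(12, 10)).astype(np.uint8)
        g = minimum_spanning_network(mat)
        assert nx.is_connected(g)


class TestMedianJoin:
    def test_worked_triplet_against_steiner_oracle(self):
        """{000, 110, 101}: exhaustive search over {0,1}^3 says the best
        single Steiner point is 100 (MST weight 3); median_join finds it."""
        observed = [(0, 0, 0), (1, 1, 0), (1, 0, 1)]
        best = min(
            itertools.product((0, 1), repeat=3),
            key=lambda m: mst_weight(observed + [m]),
        )
        assert mst_weight(observed + [best]) == 3

        net = median_join(seqs("000", "110", "101"))
        med = net.median_nodes
        assert len(med) == 1
        assert net.node_sequence(med[0]) == (1, 0, 0) == best
        weights = [d["weight"] for _, _, d in net.graph.edges(data=True)]
        assert sorted(weights) == [1, 1, 1]
        assert net.graph.degree[med[0]] == 3

    def test_two_haplotypes_no_medians(self):
        net = median_join(seqs("0011", "1111"))
        assert net.median_nodes == []
        assert net.graph.number_of_edges() == 1

    def test_star_fixture_no_medians(self):
        net = median_join(seqs("0000", "1000", "0100", "0010"))
        assert net.median_nodes == []

    def test_fixed_point_when_medians_present(self):
        """If the observed set already contains all triplet medians the MJN
        equals the minimum spanning network."""
        mat = seqs("000", "100", "110", "111")
        net = median_join(mat)
        msn = minimum_spanning_network(mat)
        got = {
            frozenset((net.node_sequence(u), net.node_sequence(v)))
            for u, v in net.graph.edges
        }
        expected = {frozenset((u, v)) for u, v in msn.edges}
        assert net.median_nodes == []
        assert got == expected

    def test_every_observed_haplotype_is_one_node(self):
        rng = np.random.default_rng(72)
        mat = rng.integers(0, 2, size=(30, 8)).astype(np.uint8)
        net = median_join(mat)
        assert len(net.hap_nodes) == 30
        obs_seqs = {net.node_sequence(n) for n in net.observed_nodes}
        assert obs_seqs == {tuple(r) for r in mat}
        for n in net.median_nodes:
            assert net.graph.nodes[n]["multiplicity"] == 0
        assert nx.is_connected(net.graph)

    def test_deterministic(self):
        rng = np.random.default_rng(73)
        mat = rng.integers(0, 2, size=(20, 9)).astype(np.uint8)
        a = median_join(mat)
        b = median_join(mat)
        assert list(a.graph.nodes(data=True)) == list(b.graph.nodes(data=True))
        assert list(a.graph.edges(data=True)) == list(b.graph.edges(data=True))

    def test_population_counts_attached(self):
        net = median_join(seqs("00", "00", "11"), populations=["KE", "KE", "AO"])
        node = net.hap_nodes[0]
        assert net.graph.nodes[node]["populations"] == {"KE": 2}

    def test_rejects_non_binary(self):
        with pytest.raises(ValidationError):
            median_join(np.array([[0, 2], [1, 0]]))


def make_assignment(labels):
    labels = np.asarray(labels, dtype=object)
    return ClusterAssignment(
        labels=labels,
        haplotype_samples=[f"s{i // 2}" for i in range(len(labels))],
        cut_height=7,
        linkage_method="single",
        min_cluster_freq=0.01,
    )


class TestComponents:
    def test_chain_filtered_at_two(self):
        # A -2- B -3- C with max_edge 2 -> {A,B}, {C}
        net = median_join(seqs("110000", "000000", "000111"))
        comp = components_by_edge_filter(net, max_edge=2)
        hap = comp.hap_component
        assert hap[0] == hap[1] != hap[2]

    def test_all_light_edges_one_component(self):
        net = median_join(seqs("000", "100", "110"))
        comp = components_by_edge_filter(net, max_edge=1)
        assert len(set(comp.hap_component)) == 1

    def test_huge_max_edge_single_component(self):
        rng = np.random.default_rng(74)
        mat = rng.integers(0, 2, size=(15, 8)).astype(np.uint8)
        net = median_join(mat)
        comp = components_by_edge_filter(net, max_edge=10**6)
        assert len(set(comp.hap_component)) == 1

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(75)
        for _ in range(10):
            mat = rng.integers(0, 2, size=(14, 7)).astype(np.uint8)
            net = median_join(mat)
            max_edge = int(rng.integers(1, 4))
            comp = components_by_edge_filter(net, max_edge)
            # oracle: naive union-find over the same graph
            parent = {n: n for n in net.graph.nodes}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v, d in net.graph.edges(data=True):
                if d["weight"] <= max_edge:
                    parent[find(u)] = find(v)
            for u in net.graph.nodes:
                for v in net.graph.nodes:
                    assert (comp.node_component[u] == comp.node_component[v]) == (
                        find(u) == find(v)
                    )

    def test_invalid_max_edge(self):
        net = median_join(seqs("00", "11"))
        with pytest.raises(ValidationError):
            components_by_edge_filter(net, max_edge=0)


class TestConcordance:
    def test_identical_partitions(self):
        net = median_join(seqs("000000", "000000", "111111", "111111"))
        comp = components_by_edge_filter(net, max_edge=2)
        clusters = make_assignment(["C1", "C1", "C2", "C2"])
        assert concordance(comp, clusters) == 1.0

    def test_one_misassigned_of_four(self):
        # components {h0,h1}, {h2,h3}; clusters put h3 apart -> 3/4 under
        # plurality matching with the tie resolved towards the larger cluster
        net = median_join(seqs("000000", "000000", "111111", "111111"))
        comp = components_by_edge_filter(net, max_edge=2)
        clusters = make_assignment(["C1", "C1", "C1", "C2"])
        assert concordance(comp, clusters) == 0.75

    def test_one_to_one_matching_mode(self):
        net = median_join(seqs("000000", "000000", "111111", "111111"))
        comp = components_by_edge_filter(net, max_edge=2)
        clusters = make_assignment(["C1", "C1", "C2", "C2"])
        assert concordance(comp, clusters, matching="one_to_one") == 1.0

    def test_disjoint_universe_rejected(self):
        net = median_join(seqs("00", "11"))
        comp = components_by_edge_filter(net)
        with pytest.raises(ValidationError):
            concordance(comp, make_assignment(["C1"] * 5))


class TestExport:
    def test_graphml_and_dot_written(self, tmp_path):
        net = median_join(seqs("000", "110", "101"), populations=["a", "b", "a"])
        write_graphml(net, tmp_path / "n.graphml")
        write_dot(net, tmp_path / "n.dot")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert g.number_of_nodes() == 4
        dot = (tmp_path / "n.dot").read_text()
        assert dot.startswith("graph mjn {") and "--" in dot
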