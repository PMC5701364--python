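"""Edge betweenness, iterative edge removal, modularity and selection."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pte import communities, similarity
from pte.errors import ConsistencyError, SelectionError

from conftest import (
    brute_force_betweenness,
    make_identical_sorters,
    random_weighted_graph,
    set_partitions,
)


def _weighted_graph(edges):
    g = nx.Graph()
    for u, v, score in edges:
        g.add_edge(u, v, score=score, distance=1.0 / score)
    return g


# ------------------------------------------------------- edge betweenness

def test_fruit_example_edge_betweenness(fig3_dataset):
    """g-s carries the three pairs involving seaweed; r-g and t-g carry
    two pairs each; r-t only itself."""
    net = similarity.build_network(fig3_dataset)
    bt = communities.edge_betweenness(net)
    assert bt[("grapes", "seaweed")] == pytest.approx(3.0)
    assert bt[("grapes", "raspberry")] == pytest.approx(2.0)
    assert bt[("grapes", "tomato")] == pytest.approx(2.0)
    assert bt[("raspberry", "tomato")] == pytest.approx(1.0)


def test_unweighted_path_betweenness():
    g = _weighted_graph([("a", "b", 1), ("b", "c", 1)])
    bt = communities.edge_betweenness(g)
    assert bt == {("a", "b"): pytest.approx(2.0), ("b", "c"): pytest.approx(2.0)}


def test_equal_length_paths_split_fractionally():
    """A 4-cycle with equal weights: two routes per opposite pair."""
    g = _weighted_graph([("a", "b", 2), ("b", "c", 2), ("c", "d", 2), ("d", "a", 2)])
    bt = communities.edge_betweenness(g)
    # each edge: its own pair (1) + half of each of the 2 opposite pairs
    for e, v in bt.items():
        assert v == pytest.approx(2.0)


@pytest.mark.parametrize("reciprocal", [True, False])
def test_betweenness_matches_exhaustive_oracle(reciprocal):
    """Kernel output equals exhaustive simple-path enumeration on random
    small graphs, with both tie-prone reciprocal and continuous weights."""
    rng = np.random.default_rng(20 + reciprocal)
    for _ in range(25):
        g = random_weighted_graph(rng, reciprocal_weights=reciprocal)
        got = communities.edge_betweenness(g)
        want, _ = brute_force_betweenness(g)
        assert set(got) == set(want)
        for e in want:
            assert got[e] == pytest.approx(want[e], abs=1e-9)


def test_betweenness_matches_igraph():
    """Independent cross-check against the igraph implementation."""
    igraph = pytest.importorskip("igraph")
    rng = np.random.default_rng(7)
    for _ in range(20):
        g = random_weighted_graph(rng, reciprocal_weights=False)
        nodes = sorted(g.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        ig = igraph.Graph([(idx[u], idx[v]) for u, v in g.edges])
        w = [g[u][v]["distance"] for u, v in g.edges]
        ref = dict(
            zip(
                (tuple(sorted(e)) for e in g.edges),
                ig.edge_betweenness(weights=w),
            )
        )
        got = communities.edge_betweenness(g)
        for e, v in ref.items():
            assert got[e] == pytest.approx(v, abs=1e-8)


# ------------------------------------------------------------ dendrogram

def test_fruit_example_first_removal(fig3_dataset):
    net = similarity.build_network(fig3_dataset)
    dendro = communities.girvan_newman(net)
    assert dendro.removed_edges[0] == (("grapes", "seaweed"), pytest.approx(3.0))
    assert dendro.community_counts() == (1, 2, 3, 4)


def test_bridge_between_triangles_removed_first():
    tri1 = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]
    tri2 = [("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
    g = _weighted_graph(tri1 + tri2 + [("c", "x", 1)])
    dendro = communities.girvan_newman(g)
    assert dendro.removed_edges[0][0] == ("c", "x")
    assert dendro.levels[1] == (
        frozenset({"a", "b", "c"}),
        frozenset({"x", "y", "z"}),
    )


def test_disjoint_cliques_already_split_at_level_zero():
    net = similarity.build_network(
        make_identical_sorters([["A", "B", "C"], ["D", "E", "F"]], m=3)
    )
    dendro = communities.girvan_newman(net)
    assert len(dendro.levels[0]) == 2


def test_edgeless_network_single_level():
    g = nx.Graph()
    g.add_nodes_from(["A", "B", "C"])
    dendro = communities.girvan_newman(g)
    assert dendro.community_counts() == (3,)
    assert dendro.removed_edges == ()
    assert dendro.quality == (0.0,)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30)
def test_dendrogram_nested_and_ends_in_singletons(seed):
    """Each level refines its predecessor; the last level is singletons."""
    rng = np.random.default_rng(seed)
    g = random_weighted_graph(rng)
    dendro = communities.girvan_newman(g)
    assert all(len(c) == 1 for c in dendro.levels[-1])
    for coarse, fine in zip(dendro.levels, dendro.levels[1:]):
        for comm in fine:
            assert any(comm <= parent for parent in coarse)
        assert len(fine) == len(coarse) + 1


def test_dendrogram_deterministic(fig3_dataset):
    net = similarity.build_network(fig3_dataset)
    a = communities.girvan_newman(net)
    b = communities.girvan_newman(net)
    assert a == b


def test_tie_break_is_lexicographic():
    """On an equal-weight square every edge ties; the smallest pair goes."""
    g = _weighted_graph([("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "a", 1)])
    dendro = communities.girvan_newman(g)
    assert dendro.removed_edges[0][0] == ("a", "b")


# ------------------------------------------------------------- modularity

def test_single_community_has_zero_modularity(fig3_dataset):
    net = similarity.build_network(fig3_dataset)
    assert communities.partition_quality(net, [set(net.nodes)]) == pytest.approx(0.0)


def test_fruit_example_modularity_value(fig3_dataset):
    """W=5, within={r-t,r-g,t-g}=4: Q = 4/5 - (9/10)^2 - (1/10)^2 = -0.02."""
    net = similarity.build_network(fig3_dataset)
    q = communities.partition_quality(
        net, [{"raspberry", "tomato", "grapes"}, {"seaweed"}]
    )
    assert q == pytest.approx(-0.02)


def test_clique_partition_maximises_modularity_by_enumeration():
    """Exhaustive search over all partitions of two disjoint triangles."""
    net = similarity.build_network(
        make_identical_sorters([["A", "B", "C"], ["D", "E", "F"]], m=2)
    )
    cliques = [{"A", "B", "C"}, {"D", "E", "F"}]
    q_cliques = communities.partition_quality(net, cliques)
    best = max(
        communities.partition_quality(net, p)
        for p in set_partitions(list(net.nodes))
    )
    assert q_cliques == pytest.approx(best)
    merged = communities.partition_quality(net, [set(net.nodes)])
    assert q_cliques > merged


def test_partition_quality_validates_cover(fig3_dataset):
    net = similarity.build_network(fig3_dataset)
    with pytest.raises(ConsistencyError):
        communities.partition_quality(net, [{"raspberry"}])
    with pytest.raises(ConsistencyError):
        communities.partition_quality(
            net, [set(net.nodes), {"raspberry"}]
        )


# -------------------------------------------------------------- selection

def test_fruit_example_selects_single_community(fig3_dataset):
    """The worked example's stated outcome: one group of all four items."""
    net = similarity.build_network(fig3_dataset)
    clustering, dendro = communities.detect_themes(net)
    assert communities.select_partition(dendro, net) == (frozenset(net.nodes),)
    assert clustering.groups == {v: 1 for v in net.nodes}
    assert clustering.unassigned == frozenset()


def test_two_cliques_selected(fig3_dataset):
    net = similarity.build_network(
        make_identical_sorters([["A", "B", "C"], ["D", "E", "F"]], m=2)
    )
    clustering, _ = communities.detect_themes(net)
    assert clustering.as_partition() == (
        frozenset({"A", "B", "C"}),
        frozenset({"D", "E", "F"}),
    )


def test_fixed_k_selection(fig3_dataset):
    net = similarity.build_network(fig3_dataset)
    dendro = communities.girvan_newman(net)
    singles = communities.select_partition(dendro, net, k=net.number_of_nodes())
    assert all(len(c) == 1 for c in singles)
    with pytest.raises(SelectionError):
        communities.select_partition(dendro, net, k=99)


# ------------------------------------------------------------- clustering

def test_finalize_clustering_size_rule():
    clustering = communities.finalize_clustering(
        [{"A", "B", "C"}, {"D", "E"}, {"F"}]
    )
    assert clustering.groups == {"A": 1, "B": 1, "C": 1, "D": 2, "E": 2}
    assert clustering.unassigned == frozenset({"F"})


def test_finalize_clustering_seven_communities_three_singletons():
    """Seven communities of which three singletons: 4 groups, 3 unassigned."""
    comms = [
        {"ID3", "ID4", "ID7", "ID8", "ID9"},
        {"ID2", "ID32", "ID34"},
        {"ID5", "ID10", "ID15", "ID22", "ID26"},
        {"ID27", "ID28", "ID29", "ID30"},
        {"ID1"}, {"ID19"}, {"ID36"},
    ]
    clustering = communities.finalize_clustering(comms)
    assert len(clustering.group_ids) == 4
    assert clustering.unassigned == frozenset({"ID1", "ID19", "ID36"})


def test_all_singletons_all_unassigned():
    clustering = communities.finalize_clustering([{"A"}, {"B"}, {"C"}])
    assert clustering.groups == {}
    assert clustering.unassigned == frozenset({"A", "B", "C"})


def test_clustering_round_trip(tmp_path):
    clustering = communities.finalize_clustering([{"A", "B"}, {"C", "D", "E"}, {"F"}])
    path = communities.write_clustering(clustering, tmp_path / "clust.csv")
    again = communities.read_clustering(path)
    assert again == clustering


def test_dendrogram_json(tmp_path, fig3_dataset):
    import json

    net = similarity.build_network(fig3_dataset)
    dendro = communities.girvan_newman(net)
    payload = json.loads(dendro.to_json(tmp_path / "dendro.json"))
    assert len(payload["levels"]) == 4
    assert payload["levels"][0]["n_communities"] == 1
    assert payload["removed_edges"][0]["edge"] == ["grapes", "seaweed"]


# ------------------------------------------------------ planted recovery

@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25)
def test_exact_recovery_for_identical_sorters(seed):
    """If all sorters submit the same partition (parts >= 2), the selected
    partition is exactly that partition."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 31))
    m = int(rng.integers(2, 9))
    labels = [f"E{i}" for i in range(n)]
    rng.shuffle(labels)
    parts, i = [], 0
    while n - i >= 2:
        size = int(rng.integers(2, max(3, min(n - i - 1, 8)) + 1))
        if n - i - size == 1:
            size += 1
        parts.append(labels[i:i + size])
        i += size
    ds = make_identical_sorters(parts, m)
    net = similarity.build_network(ds)
    clustering, _ = communities.detect_themes(net)
    assert clustering.as_partition() == tuple(
        sorted((frozenset(p) for p in parts), key=min)
    )
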