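"""Shared fixtures and independent brute-force oracles.

The oracles deliberately take the dumbest correct route — exhaustive
simple-path enumeration for betweenness, exhaustive set-partition
enumeration for modularity maximisation, O(n^2) pair concordance for the
adjusted Rand index — so they share no code with the implementation
they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pte.sort_io import SortDataset

settings.register_profile(
    "pte",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pte")


# ---------------------------------------------------------------- fixtures

FIG3_RECORDS = [
    # person 1: {raspberry, tomato, grapes}, {seaweed}
    ("p1", "raspberry", "A"), ("p1", "tomato", "A"),
    ("p1", "grapes", "A"), ("p1", "seaweed", "B"),
    # person 2: {raspberry, tomato}, {grapes, seaweed}
    ("p2", "raspberry", "X"), ("p2", "tomato", "X"),
    ("p2", "grapes", "Y"), ("p2", "seaweed", "Y"),
]

TABLE1_RECORDS = [
    ("P1", "ID1", "Gp5"), ("P1", "ID2", "Gp5"), ("P1", "ID3", "Gp7"),
    ("P1", "ID4", "Gp7"), ("P1", "ID5", "Gp5"),
    ("P2", "ID1", "Gp2"), ("P2", "ID2", "Gp6"), ("P2", "ID3", "Gp6"),
    ("P2", "ID4", "Gp2"), ("P2", "ID5", "Gp2"),
    ("P3", "ID1", "Gp2"), ("P3", "ID2", "Gp2"), ("P3", "ID3", "Gp6"),
    ("P3", "ID4", "Gp6"), ("P3", "ID5", "Gp7"),
]


@pytest.fixture
def fig3_dataset() -> SortDataset:
    """The two-sorter fruit example (raspberry/tomato/grapes/seaweed)."""
    return SortDataset.from_records(FIG3_RECORDS)


@pytest.fixture
def table1_dataset() -> SortDataset:
    """Three sorters x five excerpts, as entered in the example spreadsheet."""
    return SortDataset.from_records(TABLE1_RECORDS)


def make_identical_sorters(partition: list[list[str]], m: int) -> SortDataset:
    """Dataset where m sorters all submit exactly `partition`."""
    records = []
    for s in range(m):
        for g, pile in enumerate(partition):
            for e in pile:
                records.append((f"P{s + 1}", e, f"Gp{g + 1}"))
    return SortDataset.from_records(records)


def random_dataset(rng: np.random.Generator, n=None, m=None) -> SortDataset:
    """Random complete sort dataset (piles need not respect any protocol)."""
    n = n if n is not None else int(rng.integers(2, 10))
    m = m if m is not None else int(rng.integers(1, 6))
    records = []
    for s in range(m):
        n_piles = int(rng.integers(1, n + 1))
        labels = rng.integers(0, n_piles, size=n)
        for i in range(n):
            records.append((f"P{s + 1}", f"E{i + 1}", f"g{labels[i]}"))
    return SortDataset.from_records(records)


# ----------------------------------------------------------------- oracles

def brute_force_betweenness(net: nx.Graph, weight: str = "distance",
                            tol: float = 1e-9):
    """Edge and node betweenness by exhaustive simple-path enumeration.

    Counts each unordered pair once, splits ties fractionally, excludes
    endpoints from node betweenness, ignores unreachable pairs.
    """
    nodes = sorted(net.nodes)
    edge_bt = {tuple(sorted(e)): 0.0 for e in net.edges}
    node_bt = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(net, s, t):
            continue
        paths = list(nx.all_simple_paths(net, s, t))
        lengths = [
            sum(net[u][v][weight] for u, v in zip(p, p[1:])) for p in paths
        ]
        dmin = min(lengths)
        shortest = [
            p for p, L in zip(paths, lengths)
            if L <= dmin + tol * (1.0 + abs(dmin))
        ]
        k = len(shortest)
        for p in shortest:
            for u, v in zip(p, p[1:]):
                edge_bt[tuple(sorted((u, v)))] += 1.0 / k
            for v in p[1:-1]:
                node_bt[v] += 1.0 / k
    return edge_bt, node_bt


def set_partitions(items):
    """All set partitions of a small collection (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from raw pair concordance counts."""
    n = len(labels_a)
    ss = sd = ds = 0
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        ss += same_a and same_b
        sd += same_a and not same_b
        ds += same_b and not same_a
        total += 1
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2.0
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


def random_weighted_graph(rng: np.random.Generator, max_nodes: int = 8,
                          reciprocal_weights: bool = True) -> nx.Graph:
    """Random connected-ish graph with positive weights on 'distance'.

    Reciprocal weights (1/k for small integers k) deliberately provoke
    equal-length alternative paths; continuous weights make ties almost
    surely absent.
    """
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.3, 0.9))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    for u, v in g.edges:
        if reciprocal_weights:
            score = int(rng.integers(1, 9))
            g[u][v]["score"] = score
            g[u][v]["distance"] = 1.0 / score
        else:
            g[u][v]["score"] = 1
            g[u][v]["distance"] = float(rng.uniform(0.1, 2.0))
    return g
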