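"""Pairwise similarity scores and the weighted conceptual-distance network.

For each unordered pair of excerpts the similarity score is the number of
sorters who placed both excerpts in the same pile (0..m).  Scores convert
to a conceptual distance of 1/score, so with m sorters distances live in
[1/m, 1]: a pair everyone co-piled is conceptually closest, a pair only
one person co-piled is maximally distant among connected pairs.  Pairs
nobody co-piled carry no edge at all — there is no infinite-distance
sentinel; unreachable pairs are simply unreachable for path algorithms.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedDistanceError
from .sort_io import SortDataset

#: networkx graph attribute holding the number of sorters
N_SORTERS_KEY = "n_sorters"

# fixed qualitative palette for DOT rendering (cycled when groups exceed it)
_PALETTE = [
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
    "#e6ab02", "#a6761d", "#666666", "#1f78b4", "#b2df8a",
]
_UNASSIGNED_COLOR = "#d9d9d9"


def to_distance(score: int) -> float:
    """Conceptual distance 1/score for a similarity score >= 1."""
    if score < 1:
        raise UndefinedDistanceError(
            "conceptual distance is undefined for score 0 (no edge exists)"
        )
    return 1.0 / score


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def co_assignment_counts(ds: SortDataset) -> Counter:
    """Raw co-assignment counter: (a, b) lexicographic pair -> score >= 1."""
    counts: Counter = Counter()
    for p in ds.participant_ids:
        for members in ds.piles(p).values():
            for a, b in combinations(sorted(members), 2):
                counts[(a, b)] += 1
    return counts


def pair_similarity(ds: SortDataset) -> pd.DataFrame:
    """Evaluate all n(n-1)/2 unordered excerpt pairs.

    Returns a DataFrame with one row per pair, lexicographically ordered,
    with columns ``excerpt_a``, ``excerpt_b``, ``score`` and ``distance``
    (NaN where the score is 0 and the distance is undefined).
    """
    counts = co_assignment_counts(ds)
    rows = []
    for a, b in combinations(sorted(ds.excerpt_ids), 2):
        s = counts.get((a, b), 0)
        rows.append((a, b, s, 1.0 / s if s >= 1 else np.nan))
    return pd.DataFrame(rows, columns=["excerpt_a", "excerpt_b", "score", "distance"])


def build_network(ds: SortDataset) -> nx.Graph:
    """Build the similarity network.

    Nodes are all excerpts (isolated nodes retained, in first-appearance
    order); an undirected edge joins a pair iff at least one sorter
    co-piled it, carrying integer ``score`` and float ``distance`` (=
    1/score) attributes.  The number of sorters is stored as a graph
    attribute so downstream code knows the attainable score range.
    """
    g = nx.Graph()
    g.graph[N_SORTERS_KEY] = ds.m
    g.add_nodes_from(ds.excerpt_ids)
    for (a, b), s in sorted(co_assignment_counts(ds).items()):
        g.add_edge(a, b, score=int(s), distance=to_distance(s))
    return g


def network_edge_table(net: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame in canonical (min label, max label) order."""
    rows = sorted(
        (*_canonical_pair(u, v), d["score"], d["distance"])
        for u, v, d in net.edges(data=True)
    )
    return pd.DataFrame(rows, columns=["excerpt_a", "excerpt_b", "score", "distance"])


def _dot_source(net: nx.Graph, clustering=None) -> str:
    """Graphviz DOT text: edge pen width tracks the score (more sorters →
    thicker line), node fill colour tracks the theme when a clustering is
    supplied, neutral grey for unassigned excerpts."""
    lines = ["graph similarity {", "  node [style=filled, fillcolor=white];"]
    colors: dict[str, str] = {}
    if clustering is not None:
        gids = sorted({gid for gid in clustering.groups.values()})
        for i, gid in enumerate(gids):
            colors[gid] = _PALETTE[i % len(_PALETTE)]
    for node in net.nodes:
        attrs = []
        if clustering is not None:
            gid = clustering.groups.get(node)
            fill = colors[gid] if gid is not None else _UNASSIGNED_COLOR
            attrs.append(f'fillcolor="{fill}"')
        lines.append(f'  "{node}" [{", ".join(attrs)}];' if attrs else f'  "{node}";')
    for u, v, d in sorted(net.edges(data=True), key=lambda e: _canonical_pair(e[0], e[1])):
        a, b = _canonical_pair(u, v)
        lines.append(f'  "{a}" -- "{b}" [penwidth={d["score"]}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_network(
    net: nx.Graph,
    path: str | Path,
    format: str = "edgelist",
    clustering=None,
) -> Path:
    """Write the network to ``path`` as GraphML, an edge-list table, or DOT.

    GraphML and the edge list carry score and distance as edge attributes;
    DOT maps score to pen width and, when a clustering is supplied, group
    membership to node colour.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt in ("edgelist", "edge-list", "csv"):
        network_edge_table(net).to_csv(path, index=False)
    elif fmt == "dot":
        path.write_text(_dot_source(net, clustering))
    else:
        raise FormatError(f"unknown network export format {format!r}")
    return path
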