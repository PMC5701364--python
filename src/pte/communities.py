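"""Community detection on the similarity network by iterative edge removal.

The algorithm repeatedly removes the edge with the highest weighted
betweenness (conceptual distances as path lengths), recomputing
betweenness after every removal, which gradually fragments the network
into communities.  Every fragmentation event is recorded as one level of
a dendrogram; the final grouping is the level that maximises weighted
modularity, computed with the raw similarity *scores* as affinities.

The weight semantics deliberately split: betweenness uses distances
(1/score) because it measures conceptual separation along paths, while
modularity uses scores because it rewards keeping strongly co-sorted
pairs together — feeding distances into modularity would reward cutting
exactly the ties most sorters agreed on.

Determinism: when several edges tie for the maximum betweenness (within
a 1e-9 relative tolerance) the lexicographically smallest (min label,
max label) edge is removed, so identical input always yields an
identical dendrogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._betweenness import PATH_TOL, TIE_TOL, _gn_kernel, betweenness_arrays, graph_to_csr
from .errors import ConsistencyError, SelectionError

#: sentinel used for unassigned excerpts in exported tables
UNASSIGNED = "UNASSIGNED"

Partition = tuple[frozenset, ...]


def _canonical_partition(communities: Iterable[Iterable[str]]) -> Partition:
    comms = [frozenset(c) for c in communities]
    return tuple(sorted(comms, key=lambda c: min(c)))


@dataclass(frozen=True)
class Dendrogram:
    """Nested partitions produced by iterative edge removal.

    ``levels[0]`` is the connected-component partition of the input
    network; each later level records one component split; the last level
    is all singletons.  ``quality[i]`` is the weighted modularity of
    ``levels[i]`` against the *original* network.
    """

    levels: tuple[Partition, ...]
    removed_edges: tuple[tuple[tuple[str, str], float], ...]
    quality: tuple[float, ...]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def community_counts(self) -> tuple[int, ...]:
        return tuple(len(level) for level in self.levels)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "levels": [
                {
                    "communities": [sorted(c) for c in level],
                    "n_communities": len(level),
                    "modularity": q,
                }
                for level, q in zip(self.levels, self.quality)
            ],
            "removed_edges": [
                {"edge": list(edge), "betweenness": bt}
                for edge, bt in self.removed_edges
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class Clustering:
    """Final excerpt -> group assignment.

    Groups have >= 2 members and integer ids 1.. assigned in decreasing
    size (ties towards the group with the smallest member label);
    singleton communities and isolated excerpts are flagged unassigned —
    they were sorted too inconsistently to belong to any theme.
    """

    groups: Mapping[str, int]
    unassigned: frozenset

    @property
    def group_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.groups.values())))

    def members(self, group_id: int) -> frozenset:
        return frozenset(e for e, g in self.groups.items() if g == group_id)

    def as_partition(self) -> Partition:
        comms = [set(self.members(g)) for g in self.group_ids]
        comms.extend({e} for e in self.unassigned)
        return _canonical_partition(comms)

    def excerpts(self) -> frozenset:
        return frozenset(self.groups) | self.unassigned

    def to_frame(self) -> pd.DataFrame:
        rows = [(e, g) for e, g in self.groups.items()]
        rows += [(e, UNASSIGNED) for e in self.unassigned]
        rows.sort(key=lambda r: r[0])
        return pd.DataFrame(rows, columns=["excerpt_id", "group_id"])


def edge_betweenness(net: nx.Graph, weight: str = "distance") -> dict[tuple[str, str], float]:
    """Weighted edge betweenness, one count per unordered node pair.

    Path lengths are the edge ``distance`` attributes; equal-length
    alternatives share the count fractionally; unreachable pairs
    contribute nothing.
    """
    _, pairs, edge_bt, _ = betweenness_arrays(net, weight=weight)
    return {pair: float(v) for pair, v in zip(pairs, edge_bt)}


def girvan_newman(net: nx.Graph) -> Dendrogram:
    """Run iterative highest-betweenness edge removal to exhaustion.

    Recomputes betweenness after each single-edge removal and records a
    dendrogram level every time the removal splits a component.  An
    edgeless network yields the one-level dendrogram of isolated nodes.
    """
    labels, edge_u, edge_v, edge_w, indptr, indices, arc_w, arc_edge = graph_to_csr(net)
    n = len(labels)
    m = len(edge_u)
    if m == 0:
        level0 = _canonical_partition([{lab} for lab in labels])
        return Dendrogram((level0,), (), (partition_quality(net, level0),))
    rem_e, rem_bt, snaps = _gn_kernel(
        n, indptr, indices, arc_w, arc_edge, edge_u, edge_v, m, PATH_TOL, TIE_TOL
    )
    levels = []
    for row in snaps:
        comms: dict[int, set[str]] = {}
        for i, lab in enumerate(row):
            comms.setdefault(int(lab), set()).add(labels[i])
        levels.append(_canonical_partition(comms.values()))
    removed = tuple(
        ((labels[edge_u[e]], labels[edge_v[e]]), float(bt))
        for e, bt in zip(rem_e, rem_bt)
    )
    quality = tuple(partition_quality(net, level) for level in levels)
    return Dendrogram(tuple(levels), removed, quality)


def partition_quality(net: nx.Graph, partition: Iterable[Iterable[str]]) -> float:
    """Weighted modularity Q of a partition, scores as edge strengths.

    Q = sum over communities of [W_in/W - (S/2W)^2] where W is the total
    score over all edges, W_in the score within the community and S the
    summed strength (incident score) of its nodes.  An edgeless network
    has Q = 0 for every partition.
    """
    comms = [set(c) for c in partition]
    covered: set = set()
    for c in comms:
        if covered & c:
            raise ConsistencyError("partition communities overlap")
        covered |= c
    if covered != set(net.nodes):
        raise ConsistencyError("partition does not cover the node set exactly")
    w_total = sum(d["score"] for _, _, d in net.edges(data=True))
    if w_total == 0:
        return 0.0
    strength = {v: 0.0 for v in net.nodes}
    for u, v, d in net.edges(data=True):
        strength[u] += d["score"]
        strength[v] += d["score"]
    member = {v: i for i, c in enumerate(comms) for v in c}
    w_in = [0.0] * len(comms)
    for u, v, d in net.edges(data=True):
        if member[u] == member[v]:
            w_in[member[u]] += d["score"]
    q = 0.0
    for i, c in enumerate(comms):
        s = sum(strength[v] for v in c)
        q += w_in[i] / w_total - (s / (2.0 * w_total)) ** 2
    return q


def select_partition(
    dendro: Dendrogram,
    net: nx.Graph,
    k: int | None = None,
    tol: float = 1e-12,
) -> Partition:
    """Choose a dendrogram level.

    Default: the level maximising weighted modularity (earliest level on
    ties within ``tol``).  With ``k`` given: the first level with exactly
    k communities, erroring if no level has that count.
    """
    if k is not None:
        for level in dendro.levels:
            if len(level) == k:
                return level
        raise SelectionError(
            f"no dendrogram level has {k} communities "
            f"(available: {sorted(set(dendro.community_counts()))})"
        )
    qmax = max(dendro.quality)
    thr = qmax - tol * (1.0 + abs(qmax))
    for level, q in zip(dendro.levels, dendro.quality):
        if q >= thr:
            return level
    raise AssertionError("unreachable: maximum not found")


def finalize_clustering(partition: Iterable[Iterable[str]]) -> Clustering:
    """Turn a selected partition into the final clustering.

    Communities of size >= 2 become groups; size-1 communities (including
    isolated excerpts) are reported as unassigned rather than as themes.
    """
    comms = [frozenset(c) for c in partition]
    groups_sorted = sorted(
        (c for c in comms if len(c) >= 2), key=lambda c: (-len(c), min(c))
    )
    assignment: dict[str, int] = {}
    for gid, comm in enumerate(groups_sorted, start=1):
        for e in comm:
            assignment[e] = gid
    unassigned = frozenset(next(iter(c)) for c in comms if len(c) == 1)
    return Clustering(assignment, unassigned)


def detect_themes(net: nx.Graph, k: int | None = None) -> tuple[Clustering, Dendrogram]:
    """End-to-end grouping: dendrogram, level selection, clustering."""
    dendro = girvan_newman(net)
    partition = select_partition(dendro, net, k=k)
    return finalize_clustering(partition), dendro


def write_clustering(clustering: Clustering, path: str | Path) -> Path:
    path = Path(path)
    clustering.to_frame().to_csv(path, index=False)
    return path


def read_clustering(path: str | Path) -> Clustering:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"excerpt_id", "group_id"} <= set(df.columns):
        raise ConsistencyError(f"{path}: expected columns excerpt_id, group_id")
    groups: dict[str, int] = {}
    unassigned = set()
    for _, row in df.iterrows():
        if row["group_id"] == UNASSIGNED:
            unassigned.add(row["excerpt_id"])
        else:
            groups[row["excerpt_id"]] = int(row["group_id"])
    return Clustering(groups, frozenset(unassigned))
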