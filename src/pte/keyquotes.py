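"""Key-quote identification: central and bridging excerpts per theme.

Two complementary centralities pick out the quotes worth reading first:

* within-cluster closeness — the excerpt whose mean weighted
  shortest-path distance to the other members of its group is lowest is
  the group's most representative quote;
* bridging betweenness — the excerpt lying on the most weighted shortest
  paths of the full network links subthemes and groups together.

Closeness is computed on the subgraph induced by the group by default (a
quote competes only against the other quotes of its cluster), while
betweenness is computed on the full network (bridging happens *across*
themes).  Both scopes are switchable because either reading is
defensible.  Ties are reported in full as sets, never broken.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._betweenness import betweenness_arrays
from .communities import UNASSIGNED, Clustering
from .errors import CatalogMismatchError, DisconnectedGroupError
from .sort_io import ExcerptCatalog

KEY_CLOSENESS = "KEY_CLOSENESS"
KEY_BETWEENNESS = "KEY_BETWEENNESS"


def cluster_closeness(
    net: nx.Graph,
    clustering: Clustering,
    scope: str = "cluster",
) -> dict[str, float]:
    """Mean weighted distance from each assigned excerpt to its group mates.

    With ``scope="cluster"`` (default) distances are shortest paths on the
    subgraph induced by the group; with ``scope="global"`` paths may
    detour through other groups.  Raises if some group member cannot be
    reached (possible only for hand-supplied clusterings; dendrogram
    levels are connected by construction).
    """
    if scope not in ("cluster", "global"):
        raise ValueError(f"unknown closeness scope {scope!r}")
    means: dict[str, float] = {}
    for gid in clustering.group_ids:
        members = sorted(clustering.members(gid))
        g = net.subgraph(members) if scope == "cluster" else net
        for e in members:
            lengths = nx.single_source_dijkstra_path_length(g, e, weight="distance")
            others = [x for x in members if x != e]
            missing = [x for x in others if x not in lengths]
            if missing:
                raise DisconnectedGroupError(
                    f"group {gid}: excerpt {e!r} cannot reach {missing} "
                    f"within scope {scope!r}"
                )
            means[e] = float(np.mean([lengths[x] for x in others]))
    return means


def node_betweenness(
    net: nx.Graph,
    clustering: Clustering | None = None,
    scope: str = "global",
) -> dict[str, float]:
    """Weighted node betweenness (endpoints excluded, fractional counting).

    Default scope is the full network; ``scope="cluster"`` restricts paths
    to each group's induced subgraph (requires a clustering, and excerpts
    outside any group score 0).
    """
    if scope not in ("global", "cluster"):
        raise ValueError(f"unknown betweenness scope {scope!r}")
    if scope == "global":
        labels, _, _, node_bt = betweenness_arrays(net)
        return {lab: float(v) for lab, v in zip(labels, node_bt)}
    if clustering is None:
        raise ValueError("cluster-scoped betweenness needs a clustering")
    values = {e: 0.0 for e in net.nodes}
    for gid in clustering.group_ids:
        sub = net.subgraph(sorted(clustering.members(gid)))
        labels, _, _, node_bt = betweenness_arrays(sub)
        for lab, v in zip(labels, node_bt):
            values[lab] = float(v)
    return values


def _argopt_set(values: dict[str, float], members, best) -> frozenset:
    vals = {e: values[e] for e in members}
    opt = best(vals.values())
    return frozenset(e for e, v in vals.items() if np.isclose(v, opt, rtol=1e-12, atol=0))


def key_quotes(
    net: nx.Graph,
    clustering: Clustering,
    closeness_scope: str = "cluster",
    betweenness_scope: str = "global",
) -> dict[int, dict[str, frozenset]]:
    """Per group: the argmin-closeness set and argmax-betweenness set."""
    close = cluster_closeness(net, clustering, scope=closeness_scope)
    between = node_betweenness(net, clustering, scope=betweenness_scope)
    out: dict[int, dict[str, frozenset]] = {}
    for gid in clustering.group_ids:
        members = clustering.members(gid)
        out[gid] = {
            "closeness": _argopt_set(close, members, min),
            "betweenness": _argopt_set(between, members, max),
        }
    return out


def report(
    net: nx.Graph,
    clustering: Clustering,
    catalog: ExcerptCatalog | None = None,
    path: str | Path | None = None,
    closeness_scope: str = "cluster",
    betweenness_scope: str = "global",
) -> pd.DataFrame:
    """One row per excerpt: group, centralities, key-quote flags, text.

    Unassigned excerpts appear with group ``UNASSIGNED``, an undefined
    (NaN) closeness and no key-quote flags.
    """
    unknown = [e for e in net.nodes if e not in clustering.excerpts()]
    if unknown:
        raise CatalogMismatchError(f"clustering is missing excerpts: {sorted(unknown)}")
    close = cluster_closeness(net, clustering, scope=closeness_scope)
    between = node_betweenness(net, clustering, scope=betweenness_scope)
    keys = key_quotes(net, clustering, closeness_scope, betweenness_scope)
    if catalog is not None:
        missing = [e for e in net.nodes if e not in catalog]
        if missing:
            raise CatalogMismatchError(
                "catalogue is missing excerpt ids: " + ", ".join(sorted(missing))
            )
    rows = []
    for e in sorted(net.nodes):
        gid = clustering.groups.get(e)
        row = {
            "excerpt_id": e,
            "group_id": gid if gid is not None else UNASSIGNED,
            "mean_within_distance": close.get(e, np.nan),
            "betweenness": between.get(e, 0.0),
            KEY_CLOSENESS: gid is not None and e in keys[gid]["closeness"],
            KEY_BETWEENNESS: gid is not None and e in keys[gid]["betweenness"],
        }
        if catalog is not None:
            row["text"] = catalog.texts[e]
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
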