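"""Weighted shortest-path betweenness kernels (Brandes-style accumulation).

These kernels back both the per-edge betweenness driving the iterative
edge-removal community algorithm and the per-node bridging centrality of
the key-quote report.  Two path lengths are treated as equal when they
differ by at most ``PATH_TOL`` relative to 1 + the length, so alternative
equal-length routes built from reciprocal scores (e.g. 1/2 + 1/2 vs 1)
share the count fractionally even under floating-point rounding.

Graphs are passed as CSR adjacency with one *arc* per direction of each
undirected edge; ``arc_edge`` maps an arc back to its undirected edge id
so edges can be switched off in O(1) during iterative removal.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: relative tolerance for equality of alternative shortest-path lengths
PATH_TOL = 1e-12
#: relative tolerance for "tied with the maximum betweenness"
TIE_TOL = 1e-9


@njit(cache=True)
def _heap_push(hd, hv, size, key, val):
    i = size
    hd[i] = key
    hv[i] = val
    while i > 0:
        p = (i - 1) >> 1
        if hd[p] > hd[i]:
            hd[p], hd[i] = hd[i], hd[p]
            hv[p], hv[i] = hv[i], hv[p]
            i = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(hd, hv, size):
    key = hd[0]
    val = hv[0]
    size -= 1
    hd[0] = hd[size]
    hv[0] = hv[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        s = i
        if l < size and hd[l] < hd[s]:
            s = l
        if r < size and hd[r] < hd[s]:
            s = r
        if s == i:
            break
        hd[s], hd[i] = hd[i], hd[s]
        hv[s], hv[i] = hv[i], hv[s]
        i = s
    return key, val, size


@njit(cache=True)
def _brandes(n, indptr, indices, weights, arc_edge, active, sources, m_edges, tol):
    """Raw (doubled) edge and node betweenness from the given sources.

    Running from every node of a component counts each unordered pair
    twice, so callers halve the result.  Unreachable pairs contribute 0.
    """
    edge_bt = np.zeros(m_edges)
    node_bt = np.zeros(n)
    d = np.empty(n)
    sigma = np.empty(n)
    settled = np.empty(n, np.bool_)
    delta = np.empty(n)
    order = np.empty(n, np.int64)
    cap = n + indices.shape[0] + 1
    hd = np.empty(cap)
    hv = np.empty(cap, np.int64)
    for si in range(sources.shape[0]):
        s = sources[si]
        for i in range(n):
            d[i] = np.inf
            sigma[i] = 0.0
            settled[i] = False
            delta[i] = 0.0
        d[s] = 0.0
        sigma[s] = 1.0
        size = _heap_push(hd, hv, 0, 0.0, s)
        cnt = 0
        while size > 0:
            _, u, size = _heap_pop(hd, hv, size)
            if settled[u]:
                continue
            settled[u] = True
            order[cnt] = u
            cnt += 1
            for a in range(indptr[u], indptr[u + 1]):
                if not active[arc_edge[a]]:
                    continue
                v = indices[a]
                if settled[v]:
                    continue
                dn = d[u] + weights[a]
                t = tol * (1.0 + abs(dn))
                if dn < d[v] - t:
                    d[v] = dn
                    sigma[v] = sigma[u]
                    size = _heap_push(hd, hv, size, dn, v)
                elif dn <= d[v] + t:
                    sigma[v] += sigma[u]
        # dependency accumulation in reverse settlement order; the
        # predecessor test re-checks d[v] + w == d[w] instead of storing
        # predecessor lists
        for i in range(cnt - 1, 0, -1):
            w = order[i]
            coeff = (1.0 + delta[w]) / sigma[w]
            t = tol * (1.0 + abs(d[w]))
            for a in range(indptr[w], indptr[w + 1]):
                e = arc_edge[a]
                if not active[e]:
                    continue
                v = indices[a]
                if settled[v] and abs(d[v] + weights[a] - d[w]) <= t:
                    c = sigma[v] * coeff
                    delta[v] += c
                    edge_bt[e] += c
            node_bt[w] += delta[w]
    return edge_bt, node_bt


@njit(cache=True)
def _components(n, indptr, indices, arc_edge, active, comp, stack):
    """Label connected components over active edges; returns their count."""
    for i in range(n):
        comp[i] = -1
    nc = 0
    for i in range(n):
        if comp[i] < 0:
            comp[i] = nc
            sp = 1
            stack[0] = i
            while sp > 0:
                sp -= 1
                u = stack[sp]
                for a in range(indptr[u], indptr[u + 1]):
                    if active[arc_edge[a]]:
                        v = indices[a]
                        if comp[v] < 0:
                            comp[v] = nc
                            stack[sp] = v
                            sp += 1
            nc += 1
    return nc


@njit(cache=True)
def _mark_from(start, indptr, indices, arc_edge, active, visited, stamp, stack):
    visited[start] = stamp
    sp = 1
    stack[0] = start
    while sp > 0:
        sp -= 1
        u = stack[sp]
        for a in range(indptr[u], indptr[u + 1]):
            if active[arc_edge[a]]:
                v = indices[a]
                if visited[v] != stamp:
                    visited[v] = stamp
                    stack[sp] = v
                    sp += 1


@njit(cache=True)
def _gn_kernel(n, indptr, indices, weights, arc_edge, edge_u, edge_v, m_edges,
               path_tol, tie_tol):
    """Iterative highest-betweenness edge removal.

    Removes the maximum-betweenness edge (ties broken towards the
    lexicographically smallest (u, v) in the caller's node ordering),
    recomputing betweenness after each removal — only within the affected
    component, since shortest paths never cross components.  Records a
    component-label snapshot whenever a removal splits a component.

    Returns (removed edge ids, their betweenness at removal, snapshots)
    where snapshots[0] is the initial component labelling.
    """
    active = np.ones(m_edges, np.bool_)
    comp = np.empty(n, np.int64)
    stack = np.empty(n, np.int64)
    visited = np.zeros(n, np.int64)
    nc = _components(n, indptr, indices, arc_edge, active, comp, stack)
    next_label = nc
    snaps = np.empty((n + 1, n), np.int64)
    snaps[0, :] = comp
    nsnaps = 1
    removal_edge = np.empty(m_edges, np.int64)
    removal_bt = np.empty(m_edges)
    all_sources = np.arange(n)
    edge_bt, _ = _brandes(n, indptr, indices, weights, arc_edge, active,
                          all_sources, m_edges, path_tol)
    for e in range(m_edges):
        edge_bt[e] *= 0.5
    stamp = 0
    nactive = m_edges
    nrem = 0
    srcs = np.empty(n, np.int64)
    while nactive > 0:
        bmax = -1.0
        for e in range(m_edges):
            if active[e] and edge_bt[e] > bmax:
                bmax = edge_bt[e]
        thr = bmax - tie_tol * (1.0 + abs(bmax))
        best = -1
        for e in range(m_edges):
            if active[e] and edge_bt[e] >= thr:
                if best < 0 or edge_u[e] < edge_u[best] or (
                    edge_u[e] == edge_u[best] and edge_v[e] < edge_v[best]
                ):
                    best = e
        removal_edge[nrem] = best
        removal_bt[nrem] = edge_bt[best]
        nrem += 1
        active[best] = False
        edge_bt[best] = 0.0
        nactive -= 1
        u = edge_u[best]
        v = edge_v[best]
        stamp += 1
        s_a = stamp
        _mark_from(u, indptr, indices, arc_edge, active, visited, s_a, stack)
        split = visited[v] != s_a
        s_b = s_a
        if split:
            stamp += 1
            s_b = stamp
            _mark_from(v, indptr, indices, arc_edge, active, visited, s_b, stack)
        nsrc = 0
        for i in range(n):
            if visited[i] == s_a or visited[i] == s_b:
                srcs[nsrc] = i
                nsrc += 1
        for e in range(m_edges):
            if active[e] and (visited[edge_u[e]] == s_a or visited[edge_u[e]] == s_b):
                edge_bt[e] = 0.0
        if nsrc > 1:
            add, _ = _brandes(n, indptr, indices, weights, arc_edge, active,
                              srcs[:nsrc], m_edges, path_tol)
            for e in range(m_edges):
                if add[e] != 0.0:
                    edge_bt[e] += 0.5 * add[e]
        if split:
            for i in range(n):
                if visited[i] == s_b:
                    comp[i] = next_label
            next_label += 1
            snaps[nsnaps, :] = comp
            nsnaps += 1
    return removal_edge[:nrem], removal_bt[:nrem], snaps[:nsnaps]


def graph_to_csr(net, weight: str = "distance", node_order=None):
    """Convert a networkx graph to the CSR arc arrays the kernels expect.

    Nodes are indexed in ``node_order`` (default: sorted by label, which
    makes the kernel's index-lexicographic tie-break a label-lexicographic
    one).  Returns (labels, edge_u, edge_v, edge_w, indptr, indices,
    arc_w, arc_edge).
    """
    labels = list(node_order) if node_order is not None else sorted(net.nodes)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    edges = []
    for u, v, data in net.edges(data=True):
        iu, iv = idx[u], idx[v]
        if iu > iv:
            iu, iv = iv, iu
        edges.append((iu, iv, float(data[weight])))
    edges.sort()
    m = len(edges)
    edge_u = np.array([e[0] for e in edges], dtype=np.int64)
    edge_v = np.array([e[1] for e in edges], dtype=np.int64)
    edge_w = np.array([e[2] for e in edges], dtype=np.float64)
    deg = np.zeros(n + 1, dtype=np.int64)
    for iu, iv, _ in edges:
        deg[iu + 1] += 1
        deg[iv + 1] += 1
    indptr = np.cumsum(deg)
    fill = indptr[:-1].copy()
    indices = np.empty(2 * m, dtype=np.int64)
    arc_w = np.empty(2 * m, dtype=np.float64)
    arc_edge = np.empty(2 * m, dtype=np.int64)
    for e, (iu, iv, w) in enumerate(edges):
        for a, b in ((iu, iv), (iv, iu)):
            pos = fill[a]
            indices[pos] = b
            arc_w[pos] = w
            arc_edge[pos] = e
            fill[a] += 1
    return labels, edge_u, edge_v, edge_w, indptr, indices, arc_w, arc_edge


def betweenness_arrays(net, weight: str = "distance"):
    """Edge and node betweenness of a networkx graph via the kernel.

    Returns (labels, edge pairs as label tuples, edge values, node values),
    with each unordered node pair counted once and endpoints excluded from
    node betweenness.
    """
    labels, edge_u, edge_v, _, indptr, indices, arc_w, arc_edge = graph_to_csr(
        net, weight=weight
    )
    n = len(labels)
    m = len(edge_u)
    if n == 0:
        return labels, [], np.empty(0), np.empty(0)
    active = np.ones(m, dtype=np.bool_)
    sources = np.arange(n, dtype=np.int64)
    edge_bt, node_bt = _brandes(
        n, indptr, indices, arc_w, arc_edge, active, sources, m, PATH_TOL
    )
    pairs = [(labels[u], labels[v]) for u, v in zip(edge_u, edge_v)]
    return labels, pairs, 0.5 * edge_bt, 0.5 * node_bt
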