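"""Compiled kernels for dense undirected graphs.

All kernels take dense float64 adjacency/length matrices (symmetric, zero
diagonal). An entry of 0 means "no edge". Shortest-path kernels expect a
*length* matrix (1/weight for correlation-weighted networks, 1 for binary);
they are O(N^3) linear-scan Dijkstra, which beats heap-based variants for
the dense N <= ~1000 graphs used here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "dijkstra_all",
    "betweenness",
    "betweenness_and_distances",
    "local_efficiency_nodes",
    "double_edge_swap",
]


@njit(cache=True)
def dijkstra_all(lengths):
    """All-pairs shortest path lengths; unreachable pairs are +inf.

    Linear-scan Dijkstra on the dense matrix: for the dense N <= ~1000
    graphs used here this beats heap- and adjacency-list variants.
    """
    n = lengths.shape[0]
    out = np.empty((n, n))
    for s in range(n):
        dist = np.full(n, np.inf)
        done = np.zeros(n, np.bool_)
        dist[s] = 0.0
        for _ in range(n):
            u = -1
            best = np.inf
            for v in range(n):
                if not done[v] and dist[v] < best:
                    best = dist[v]
                    u = v
            if u < 0:
                break
            done[u] = True
            for v in range(n):
                w = lengths[u, v]
                if w > 0.0 and not done[v]:
                    nd = best + w
                    if nd < dist[v]:
                        dist[v] = nd
        dist[s] = 0.0
        out[s] = dist
    return out


@njit(cache=True)
def betweenness_and_distances(lengths):
    """Brandes betweenness plus the all-pairs distance matrix.

    Betweenness is raw (unnormalized) with fractional credit for
    equal-length paths; each unordered pair is counted once. The distance
    matrix falls out of the same Dijkstra sweeps, so callers needing both
    avoid a second all-pairs pass.
    """
    n = lengths.shape[0]
    bc = np.zeros(n)
    dmat = np.empty((n, n))
    # predecessor lists stored row-wise
    preds = np.empty((n, n), np.int64)
    npred = np.empty(n, np.int64)
    order = np.empty(n, np.int64)
    for s in range(n):
        dist = np.full(n, np.inf)
        done = np.zeros(n, np.bool_)
        sigma = np.zeros(n)
        delta = np.zeros(n)
        npred[:] = 0
        dist[s] = 0.0
        sigma[s] = 1.0
        nsettled = 0
        for _ in range(n):
            u = -1
            best = np.inf
            for v in range(n):
                if not done[v] and dist[v] < best:
                    best = dist[v]
                    u = v
            if u < 0:
                break
            done[u] = True
            order[nsettled] = u
            nsettled += 1
            for v in range(n):
                w = lengths[u, v]
                if w > 0.0 and not done[v]:
                    nd = best + w
                    if nd < dist[v]:
                        dist[v] = nd
                        sigma[v] = sigma[u]
                        preds[v, 0] = u
                        npred[v] = 1
                    elif nd == dist[v]:
                        sigma[v] += sigma[u]
                        preds[v, npred[v]] = u
                        npred[v] += 1
        for k in range(nsettled - 1, -1, -1):
            w = order[k]
            for t in range(npred[w]):
                v = preds[w, t]
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
        dist[s] = 0.0
        dmat[s] = dist
    return bc / 2.0, dmat


@njit(cache=True)
def betweenness(lengths):
    """Brandes betweenness alone (see ``betweenness_and_distances``)."""
    bc, _ = betweenness_and_distances(lengths)
    return bc


@njit(cache=True)
def _subgraph_efficiency(lengths, idx):
    """Global efficiency of the induced subgraph on ``idx``."""
    k = idx.shape[0]
    if k < 2:
        return 0.0
    sub = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            if a != b:
                sub[a, b] = lengths[idx[a], idx[b]]
    d = dijkstra_all(sub)
    tot = 0.0
    for a in range(k):
        for b in range(k):
            if a != b and np.isfinite(d[a, b]) and d[a, b] > 0.0:
                tot += 1.0 / d[a, b]
    return tot / (k * (k - 1))


@njit(cache=True)
def local_efficiency_nodes(lengths):
    """Per-node local efficiency: E_glob of each node's neighbor subgraph."""
    n = lengths.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = 0
        for j in range(n):
            if lengths[i, j] > 0.0:
                k += 1
        if k < 2:
            continue
        idx = np.empty(k, np.int64)
        t = 0
        for j in range(n):
            if lengths[i, j] > 0.0:
                idx[t] = j
                t += 1
        out[i] = _subgraph_efficiency(lengths, idx)
    return out


@njit(cache=True)
def double_edge_swap(adj, iu, ju, n_attempts, seed):
    """Maslov–Sneppen degree-preserving rewiring, in place.

    ``adj`` is a boolean adjacency matrix and ``(iu, ju)`` the matching edge
    list; both are modified in place. Returns the number of successful swaps.
    """
    np.random.seed(seed)
    m = iu.shape[0]
    nsucc = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = iu[e1], ju[e1]
        c, d = iu[e2], ju[e2]
        if np.random.randint(2) == 1:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        iu[e1], ju[e1] = a, d
        iu[e2], ju[e2] = c, b
        nsucc += 1
    return nsucc
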