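"""Independent brute-force oracles for graph metrics.

Deliberately naive: Floyd–Warshall distances, DFS path enumeration for
betweenness on tiny graphs, a dynamic-programming shortest-path counter for
slightly larger ones, and literal triple loops for clustering. These share
no code with the package kernels.
"""

import numpy as np

TOL = 1e-9


def floyd_warshall(lengths):
    n = lengths.shape[0]
    d = np.where(lengths > 0, lengths, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(dist):
    n = dist.shape[0]
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                tot += 1.0 / dist[i, j]
    return tot / (n * (n - 1))


def harmonic_path_length(dist):
    e = global_efficiency(dist)
    return np.inf if e == 0 else 1.0 / e


def clustering_onnela(w):
    n = w.shape[0]
    mx = w.max()
    c = np.zeros(n)
    if mx == 0:
        return c
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        tot = 0.0
        for j in range(n):
            for h in range(n):
                if w[i, j] > 0 and w[i, h] > 0 and w[j, h] > 0:
                    tot += ((w[i, j] / mx) * (w[i, h] / mx) * (w[j, h] / mx)) ** (1.0 / 3.0)
        c[i] = tot / (k * (k - 1))
    return c


def clustering_barrat(w):
    n = w.shape[0]
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        s = w[i].sum()
        if k < 2 or s == 0:
            continue
        tot = 0.0
        for j in range(n):
            for h in range(n):
                if w[i, j] > 0 and w[i, h] > 0 and w[j, h] > 0:
                    tot += (w[i, j] + w[i, h]) / 2.0
        c[i] = tot / (s * (k - 1))
    return c


def local_efficiency(w):
    n = w.shape[0]
    out = np.zeros(n)
    lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    for i in range(n):
        nb = np.nonzero(w[i] > 0)[0]
        if nb.size < 2:
            continue
        sub = lengths[np.ix_(nb, nb)]
        out[i] = global_efficiency(floyd_warshall(sub))
    return out


def betweenness_enumeration(w):
    """Betweenness by exhaustive simple-path enumeration (tiny graphs only)."""
    n = w.shape[0]
    lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = []

            def dfs(node, visited, length):
                if node == t:
                    paths.append((length, tuple(visited)))
                    return
                for nxt in range(n):
                    if np.isfinite(lengths[node, nxt]) and nxt not in visited:
                        dfs(nxt, visited + [nxt], length + lengths[node, nxt])

            dfs(s, [s], 0.0)
            if not paths:
                continue
            best = min(p[0] for p in paths)
            shortest = [p[1] for p in paths if p[0] <= best + TOL]
            for path in shortest:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def betweenness_counting(w):
    """Betweenness via Floyd–Warshall distances and path counting."""
    n = w.shape[0]
    lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    dist = floyd_warshall(np.where(np.isfinite(lengths), lengths, 0.0))
    # sigma[s, t]: number of shortest s-t paths, by DP over distance order
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for v in np.argsort(dist[s]):
            if v == s or not np.isfinite(dist[s, v]):
                continue
            tot = 0.0
            for u in range(n):
                if np.isfinite(lengths[u, v]) and abs(
                    dist[s, u] + lengths[u, v] - dist[s, v]
                ) <= TOL:
                    tot += sigma[s, u]
            sigma[s, v] = tot
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(dist[s, v] + dist[v, t] - dist[s, t]) <= TOL:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc
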