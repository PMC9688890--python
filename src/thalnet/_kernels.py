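"""Compiled inner loops for graph distances and sparsity-grid curves.

The permutation tests rebuild both group networks and walk the whole density
grid for every relabeling, so the breadth-first search over the grid is the
pipeline's hot loop.  These kernels keep that loop in compiled code; they are
pinned to brute-force oracles (Floyd-Warshall, exhaustive enumeration) in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances of a boolean adjacency matrix.

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    n = adj.shape[0]
    nbr = np.empty((n, n), np.int32)
    deg = np.zeros(n, np.int32)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                nbr[i, deg[i]] = j
                deg[i] += 1
    out = np.full((n, n), np.inf)
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for t in range(deg[u]):
                v = nbr[u, t]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for i in range(n):
            if dist[i] >= 0:
                out[s, i] = dist[i]
    return out


@njit(cache=False)
def grid_curves(edge_i: np.ndarray, edge_j: np.ndarray, edge_counts: np.ndarray,
                n: int, want_cp: bool):
    """Global and nodal distance metrics at every density of a nested grid.

    ``edge_i``/``edge_j`` list node pairs ranked by descending |correlation|
    (ties already broken); density g keeps the first ``edge_counts[g]`` pairs.
    Because the grid is nested, edges are inserted incrementally and a BFS
    from every source is run per density.

    Returns ``(lp, unreachable, eglob, cp, degree, nodal_eff)`` where the
    first four are length-G arrays and the last two are (G, n).  ``lp`` is
    the mean over finite off-diagonal distances (NaN if none exist) and
    ``cp`` is only filled when ``want_cp``.
    """
    G = len(edge_counts)
    nbr = np.zeros((n, n), np.int32)
    deg = np.zeros(n, np.int32)
    adj = np.zeros((n, n), np.uint8)
    lp = np.full(G, np.nan)
    unreachable = np.zeros(G)
    eglob = np.zeros(G)
    cp = np.zeros(G)
    degree = np.zeros((G, n))
    nodal_eff = np.zeros((G, n))
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    prev = 0
    for g in range(G):
        for e in range(prev, edge_counts[g]):
            a = edge_i[e]
            b = edge_j[e]
            nbr[a, deg[a]] = b
            deg[a] += 1
            nbr[b, deg[b]] = a
            deg[b] += 1
            adj[a, b] = 1
            adj[b, a] = 1
        prev = edge_counts[g]
        fin_sum = 0.0
        fin_cnt = 0
        inv_tot = 0.0
        for s in range(n):
            for i in range(n):
                dist[i] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                for t in range(deg[u]):
                    v = nbr[u, t]
                    if dist[v] < 0:
                        dist[v] = du + 1
                        queue[tail] = v
                        tail += 1
            inv_s = 0.0
            for i in range(n):
                if i != s and dist[i] > 0:
                    fin_sum += dist[i]
                    fin_cnt += 1
                    inv_s += 1.0 / dist[i]
            nodal_eff[g, s] = inv_s / (n - 1)
            inv_tot += inv_s
            degree[g, s] = deg[s]
        if fin_cnt > 0:
            lp[g] = fin_sum / fin_cnt
        unreachable[g] = 1.0 - fin_cnt / (n * (n - 1))
        eglob[g] = inv_tot / (n * (n - 1))
        if want_cp:
            csum = 0.0
            for v in range(n):
                kv = deg[v]
                if kv >= 2:
                    tri = 0
                    for a_ in range(kv):
                        for b_ in range(a_ + 1, kv):
                            if adj[nbr[v, a_], nbr[v, b_]] == 1:
                                tri += 1
                    csum += 2.0 * tri / (kv * (kv - 1))
            cp[g] = csum / n
    return lp, unreachable, eglob, cp, degree, nodal_eff
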