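"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (Floyd-Warshall, exhaustive
enumeration, hand-expanded formulas) and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    for i in range(n):
        D[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                D[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def clustering_oracle(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive triangle count over all node triples."""
    n = A.shape[0]
    per = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if A[v, u]]
        k = len(nb)
        if k < 2:
            continue
        tri = sum(1 for a, b in itertools.combinations(nb, 2) if A[a, b])
        per[v] = 2.0 * tri / (k * (k - 1))
    return per, float(per.mean())


def lp_oracle(A: np.ndarray) -> tuple[float, float]:
    D = floyd_warshall(A)
    n = A.shape[0]
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j])]
    total = n * (n - 1)
    if not vals:
        raise ValueError("no finite distance")
    return float(np.mean(vals)), 1.0 - len(vals) / total


def eglob_oracle(A: np.ndarray) -> float:
    D = floyd_warshall(A)
    n = A.shape[0]
    s = sum(1.0 / D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j]))
    return s / (n * (n - 1)) if n > 1 else 0.0


def nodal_eff_oracle(A: np.ndarray) -> np.ndarray:
    D = floyd_warshall(A)
    n = A.shape[0]
    out = np.zeros(n)
    for v in range(n):
        out[v] = sum(1.0 / D[v, j] for j in range(n)
                     if j != v and np.isfinite(D[v, j])) / (n - 1)
    return out


def eloc_oracle(A: np.ndarray) -> tuple[np.ndarray, float]:
    n = A.shape[0]
    per = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if A[v, u]]
        if len(nb) < 2:
            continue
        sub = A[np.ix_(nb, nb)]
        per[v] = eglob_oracle(sub)
    return per, float(per.mean())


def _count_shortest_paths(A: np.ndarray, D: np.ndarray, s: int, t: int):
    """All shortest s-t paths by depth-first enumeration along descent of D."""
    if not np.isfinite(D[s, t]):
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(list(path))
            return
        for nxt in range(A.shape[0]):
            if A[node, nxt] and D[nxt, t] == D[node, t] - 1:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    walk(s, [s])
    return paths


def betweenness_oracle(A: np.ndarray) -> np.ndarray:
    """Fractional-credit betweenness, ordered pairs halved (unordered scale)."""
    n = A.shape[0]
    D = floyd_warshall(A)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(D[s, t]):
                continue
            paths = _count_shortest_paths(A, D, s, t)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc / 2.0


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by literal sort / cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def anova_oracle(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F from hand-expanded sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    A = rng.random((n, n)) < p
    A = np.triu(A, 1)
    return (A | A.T).astype(bool)
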