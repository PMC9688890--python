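"""Binary-graph metrics: small-world, efficiency and nodal measures.

All metrics operate on unweighted undirected graphs given as boolean
adjacency matrices (or :class:`~thalnet.network.BinaryAdjacency`).
Conventions, fixed for disconnected graphs:

* characteristic path length Lp averages the *finite* off-diagonal hop
  distances and the fraction of unreachable pairs is reported alongside;
* efficiencies use 1/inf = 0;
* clustering of a node with degree < 2 is 0;
* betweenness is unnormalized, with fractional credit split across tied
  shortest paths, on the unordered-pair scale (ordered sums halved).

gamma, lambda and sigma normalize Cp and Lp by their means over
degree-preserving (double-edge-swap) randomized networks; sigma = gamma/lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._kernels import bfs_distances
from .network import BinaryAdjacency

log = logging.getLogger(__name__)


class UndefinedPathLengthError(ValueError):
    """The graph has no finite off-diagonal distance at all."""


def _adj(A) -> np.ndarray:
    if isinstance(A, BinaryAdjacency):
        A = A.matrix
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    A = A.astype(bool)
    if not np.array_equal(A, A.T) or A.diagonal().any():
        raise ValueError("adjacency must be symmetric with zero diagonal")
    return A


def all_pairs_shortest_paths(A) -> np.ndarray:
    """Hop-distance matrix (inf for unreachable pairs, 0 on the diagonal)."""
    return bfs_distances(_adj(A))


def degrees(A) -> np.ndarray:
    return _adj(A).sum(axis=1).astype(float)


def clustering_coefficient(A) -> tuple[np.ndarray, float]:
    """Per-node clustering and its unweighted mean Cp.

    Node value = 2 * triangles / (k * (k - 1)); nodes with degree < 2
    contribute 0.
    """
    A = _adj(A)
    Af = A.astype(float)
    tri2 = np.einsum("ij,jk,ki->i", Af, Af, Af)  # 2 * triangles per node
    k = Af.sum(axis=1)
    denom = k * (k - 1)
    per_node = np.where(denom > 0, tri2 / np.where(denom > 0, denom, 1.0), 0.0)
    return per_node, float(per_node.mean())


def characteristic_path_length(A) -> tuple[float, float]:
    """(Lp, unreachable-pair fraction).

    Lp is the mean hop distance over reachable ordered pairs; raises
    :class:`UndefinedPathLengthError` if no pair is reachable.
    """
    A = _adj(A)
    D = bfs_distances(A)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        raise UndefinedPathLengthError("no finite off-diagonal distance")
    unreachable = 1.0 - finite.sum() / off.sum()
    return float(D[finite].mean()), float(unreachable)


def _efficiency_from_distances(D: np.ndarray) -> float:
    n = D.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & off, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(A) -> float:
    """Mean inverse hop distance over ordered pairs (1/inf = 0)."""
    return _efficiency_from_distances(bfs_distances(_adj(A)))


def nodal_efficiency(A, v: int | None = None):
    """Mean inverse distance from each node (or node ``v``) to all others."""
    A = _adj(A)
    D = bfs_distances(A)
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    inv = np.where(np.isfinite(D) & off, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    eff = inv.sum(axis=1) / (n - 1)
    return eff if v is None else float(eff[v])


def local_efficiency(A) -> tuple[np.ndarray, float]:
    """Per-node global efficiency of the neighbor-induced subgraph; mean Eloc."""
    A = _adj(A)
    n = A.shape[0]
    per_node = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(A[v])
        if nb.size < 2:
            continue
        per_node[v] = _efficiency_from_distances(bfs_distances(A[np.ix_(nb, nb)]))
    return per_node, float(per_node.mean())


def betweenness_centrality(A) -> np.ndarray:
    """Unnormalized betweenness with tie-splitting shortest-path credit
    (Brandes, unordered-pair convention)."""
    A = _adj(A)
    G = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(A.shape[0])])


# -- degree-preserving null model -------------------------------------------


def rewire_preserving_degree(A, n_swaps: int | None = None,
                             rng: np.random.Generator | None = None,
                             max_tries_factor: int = 6):
    """Randomize a graph by double-edge swaps, preserving every degree.

    Candidate swaps creating self-loops or multi-edges are rejected.  The
    default attempts ``10 x edge count`` successful swaps within a bounded
    number of tries; if no valid swap is found the input is returned
    unchanged with a warning.  Returns the same container type it was given.
    """
    from ._rewire_kernel import double_edge_swaps

    wrap = isinstance(A, BinaryAdjacency)
    src = A
    A = _adj(A)
    rng = rng if rng is not None else np.random.default_rng()
    iu, ju = np.nonzero(np.triu(A, 1))
    m = len(iu)
    if m < 2:
        log.warning("fewer than 2 edges; rewiring is a no-op")
        return src
    if n_swaps is None:
        n_swaps = 10 * m
    edge_i = iu.astype(np.int64).copy()
    edge_j = ju.astype(np.int64).copy()
    out = A.copy()
    rand = rng.random(3 * max_tries_factor * n_swaps)
    swaps = double_edge_swaps(edge_i, edge_j, out, n_swaps, rand)
    if swaps == 0:
        log.warning("no valid double-edge swap found in bounded attempts; "
                    "returning the input graph")
        return src
    if wrap:
        return BinaryAdjacency(labels=src.labels, matrix=out, density=src.density)
    return out


@dataclass
class SmallWorldResult:
    gamma: float
    lam: float
    sigma: float
    cp: float
    lp: float
    cp_rand: float
    lp_rand: float
    n_null_used: int
    n_null_undefined: int


def normalized_small_world(A, n_null: int = 200,
                           rng: np.random.Generator | None = None) -> SmallWorldResult:
    """gamma = Cp/<Cp_rand>, lambda = Lp/<Lp_rand>, sigma = gamma/lambda.

    Null means are taken over ``n_null`` degree-preserving rewired networks;
    nulls with undefined Lp are excluded from the means and counted.
    """
    A = _adj(A)
    rng = rng if rng is not None else np.random.default_rng()
    _, cp = clustering_coefficient(A)
    lp, _ = characteristic_path_length(A)
    cps, lps = [], []
    undefined = 0
    for _i in range(n_null):
        null = rewire_preserving_degree(A, rng=rng)
        _, cpn = clustering_coefficient(null)
        try:
            lpn, _ = characteristic_path_length(null)
        except UndefinedPathLengthError:
            undefined += 1
            continue
        cps.append(cpn)
        lps.append(lpn)
    if not lps:
        raise UndefinedPathLengthError("all null networks had undefined Lp")
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.mean(lps))
    gamma = cp / cp_rand if cp_rand > 0 else np.nan
    lam = lp / lp_rand
    return SmallWorldResult(
        gamma=float(gamma), lam=float(lam), sigma=float(gamma / lam),
        cp=cp, lp=lp, cp_rand=cp_rand, lp_rand=lp_rand,
        n_null_used=len(lps), n_null_undefined=undefined,
    )


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    eglob: float
    eloc: float
    gamma: float
    lam: float
    sigma: float
    n_null_used: int
    unreachable_fraction: float


def global_metrics(A, n_null: int = 200,
                   rng: np.random.Generator | None = None) -> GlobalMetrics:
    """All global metrics of one binary graph, including the normalized ones."""
    A = _adj(A)
    sw = normalized_small_world(A, n_null=n_null, rng=rng)
    _, unreachable = characteristic_path_length(A)
    _, eloc = local_efficiency(A)
    return GlobalMetrics(
        cp=sw.cp, lp=sw.lp, eglob=global_efficiency(A), eloc=eloc,
        gamma=sw.gamma, lam=sw.lam, sigma=sw.sigma,
        n_null_used=sw.n_null_used, unreachable_fraction=unreachable,
    )
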