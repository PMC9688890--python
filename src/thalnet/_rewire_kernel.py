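"""Compiled double-edge-swap loop.

Randomness is supplied as a pre-drawn array from the caller's
``numpy.random.Generator``, so rewiring stays on the package's seeded
streams while the rejection loop itself runs compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def double_edge_swaps(edge_i: np.ndarray, edge_j: np.ndarray, adj: np.ndarray,
                      n_swaps: int, rand: np.ndarray) -> int:
    """Apply up to ``n_swaps`` successful swaps in place; returns the count.

    ``rand`` holds uniforms consumed three per attempt (two edge picks, one
    orientation flip); its length bounds the number of attempts.
    """
    m = edge_i.shape[0]
    swaps = 0
    t = 0
    n_attempts = rand.shape[0] // 3
    for _ in range(n_attempts):
        if swaps >= n_swaps:
            break
        i = int(rand[t] * m)
        j = int(rand[t + 1] * m)
        flip = rand[t + 2] < 0.5
        t += 3
        if i == j:
            continue
        a = edge_i[i]
        b = edge_j[i]
        c = edge_i[j]
        d = edge_j[j]
        if flip:
            c, d = d, c
        if a == d or c == b:
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
        if a < d:
            edge_i[i], edge_j[i] = a, d
        else:
            edge_i[i], edge_j[i] = d, a
        if c < b:
            edge_i[j], edge_j[j] = c, b
        else:
            edge_i[j], edge_j[j] = b, c
        swaps += 1
    return swaps
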