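"""Hot loops of the degree-preserving edge-swap chain.

Jitted with numba when available; the pure-Python definitions are the
fallback and the reference semantics. Both kernels advance the chain in
place: ``adj`` is the 0/1 adjacency matrix (square and symmetric for
unipartite graphs, left×right for bipartite ones) and ``eu``/``ev`` are
the endpoint arrays of the current edge list. Randomness is pre-drawn by
the caller (edge indices and, for the unipartite move, an orientation
bit), so the kernels are deterministic and need no RNG state.

A proposal that would create a self-edge or a duplicate edge is rejected
but still consumes its attempt (lazy chain), which keeps the stationary
distribution uniform over all simple graphs with the fixed degree
sequence.
"""

from __future__ import annotations


def _swap_chain_unipartite(adj, eu, ev, idx1, idx2, orient):
    """Double-edge swaps (a,b),(c,d) -> (a,d),(c,b) on a unipartite graph."""
    for t in range(idx1.shape[0]):
        i = idx1[t]
        j = idx2[t]
        if i == j:
            continue
        a = eu[i]
        b = ev[i]
        c = eu[j]
        d = ev[j]
        if orient[t] == 1:
            c, d = d, c
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        eu[i] = a
        ev[i] = d
        eu[j] = c
        ev[j] = b


def _swap_chain_bipartite(adj, eu, ev, idx1, idx2):
    """Checkerboard swaps (a,x),(b,y) -> (a,y),(b,x); eu left, ev right."""
    for t in range(idx1.shape[0]):
        i = idx1[t]
        j = idx2[t]
        if i == j:
            continue
        a = eu[i]
        x = ev[i]
        b = eu[j]
        y = ev[j]
        if a == b or x == y:
            continue
        if adj[a, y] or adj[b, x]:
            continue
        adj[a, x] = 0
        adj[b, y] = 0
        adj[a, y] = 1
        adj[b, x] = 1
        ev[i] = y
        ev[j] = x


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    swap_chain_unipartite = njit(cache=True)(_swap_chain_unipartite)
    swap_chain_bipartite = njit(cache=True)(_swap_chain_bipartite)
except ImportError:  # pragma: no cover
    swap_chain_unipartite = _swap_chain_unipartite
    swap_chain_bipartite = _swap_chain_bipartite
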