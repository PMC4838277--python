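"""Shared fixtures and independent brute-force oracles.

The oracles are deliberately written from first principles on raw
neighbor sets (and exact rational arithmetic for the hypergeometric
tail) so they share no code path with the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from linksig import Graph

# ---------------------------------------------------------------------
# small named graphs


@pytest.fixture
def triangle() -> Graph:
    return Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star4() -> Graph:
    """Hub h with leaves x, y, z."""
    return Graph([("h", "x"), ("h", "y"), ("h", "z")])


@pytest.fixture
def path3() -> Graph:
    return Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def k22() -> Graph:
    """Complete bipartite graph: movies m1, m2 x users u1, u2."""
    side = {"m1": "left", "m2": "left", "u1": "right", "u2": "right"}
    return Graph(
        [("m1", "u1"), ("m1", "u2"), ("m2", "u1"), ("m2", "u2")],
        mode="bipartite",
        side=side,
    )


# ---------------------------------------------------------------------
# random graph factories


def random_unipartite(n: int, p: float, seed: int) -> Graph:
    gx = nx.gnp_random_graph(n, p, seed=seed)
    return Graph([(f"n{u:03d}", f"n{v:03d}") for u, v in gx.edges()],
                 nodes=[f"n{u:03d}" for u in gx.nodes()])


def random_bipartite(nl: int, nr: int, p: float, seed: int) -> Graph:
    rng = np.random.default_rng(seed)
    left = [f"L{i:03d}" for i in range(nl)]
    right = [f"R{j:03d}" for j in range(nr)]
    mask = rng.random((nl, nr)) < p
    edges = [(left[i], right[j]) for i in range(nl) for j in range(nr) if mask[i, j]]
    side = {u: "left" for u in left} | {u: "right" for u in right}
    return Graph(edges, mode="bipartite", side=side, nodes=left + right)


# ---------------------------------------------------------------------
# brute-force oracles (set arithmetic only)


def neighbor_sets(g: Graph) -> dict[str, set[str]]:
    return {u: set(g.neighbors(u)) for u in g.node_ids}


def oracle_population(g: Graph, v: str) -> list[str]:
    """The adjacency-vector positions of node v."""
    if g.mode == "bipartite":
        opposite = "right" if g.side[v] == "left" else "left"
        return list(g.nodes_on_side(opposite))
    return list(g.node_ids)


def exact_hypergeom_tail(n: int, m: int, dv: int, dw: int) -> float:
    """Upper tail by exact rational summation of the hypergeometric pmf."""
    total = Fraction(0)
    denom = math.comb(m, dw)
    for c in range(n, min(dv, dw) + 1):
        total += Fraction(math.comb(dv, c) * math.comb(m - dv, dw - c), denom)
    return float(total)


def oracle_scores(g: Graph, v: str, w: str) -> dict[str, float]:
    """All eight measures computed directly from neighbor sets."""
    nbr = neighbor_sets(g)
    nv, nw = nbr[v], nbr[w]
    common = nv & nw
    n = len(common)
    dv, dw = len(nv), len(nw)
    pop = oracle_population(g, v)
    m = len(pop)
    xv = np.array([1.0 if u in nv else 0.0 for u in pop])
    xw = np.array([1.0 if u in nw else 0.0 for u in pop])
    if xv.std() > 0 and xw.std() > 0:
        pear = float(np.corrcoef(xv, xw)[0, 1])
    else:
        pear = math.nan
    return {
        "jaccard": n / len(nv | nw),
        "cosine": float(xv @ xw / (np.linalg.norm(xv) * np.linalg.norm(xw))),
        "pearson": pear,
        "adamic_adar": sum(1.0 / math.log(len(nbr[u])) for u in common),
        "rai": sum(1.0 / len(nbr[u]) for u in common),
        "leverage": (n - dv * dw / m) / m,
        "lhn": n / (dv * dw),
        "hypergeom": exact_hypergeom_tail(n, m, dv, dw),
    }


def oracle_auc(scores_gt: list[float], scores_non: list[float]) -> float:
    """Brute-force double loop over all (ground-truth, other) comparisons."""
    wins = 0.0
    for a in scores_gt:
        for b in scores_non:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(scores_gt) * len(scores_non))
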