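"""Classic structural-similarity measures on candidate pairs.

All eight measures are functions of the common-neighbor count n(v, w),
the degrees d(v), d(w) and — for the three null-model-based measures
(leverage, lhn, hypergeom) and the Pearson coefficient — a population
size M:

* unipartite graphs: M = |V|, the number of nodes, exactly as the
  measures are conventionally printed;
* bipartite graphs: M = the size of the opposite side, since the shared
  neighbors of a same-side pair are drawn from the opposite partition.

Only candidate pairs (n ≥ 1, same side in bipartite mode) are scored.
The Pearson coefficient is undefined when an adjacency vector has zero
variance (d = 0 or d = M); undefined values are marked NaN and rank
below every defined value downstream.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph import BIPARTITE, LEFT, RIGHT, Graph, candidate_pairs, common_neighbors
from .table import ScoreTable

MEASURE_NAMES = (
    "jaccard",
    "cosine",
    "pearson",
    "adamic_adar",
    "rai",
    "leverage",
    "lhn",
    "hypergeom",
)

__all__ = ["MEASURE_NAMES", "population_size", "score_all", "hypergeom_tail", *MEASURE_NAMES]


def population_size(g: Graph, ranked_side: str = "all") -> int:
    """The null-model population M for the given ranking side."""
    if g.mode == BIPARTITE:
        if ranked_side not in (LEFT, RIGHT):
            raise ValueError("bipartite graphs require ranked_side 'left' or 'right'")
        opposite = RIGHT if ranked_side == LEFT else LEFT
        return len(g.nodes_on_side(opposite))
    return g.num_nodes


def _pair_inputs(g: Graph, v: str, w: str) -> tuple[int, frozenset[str], int, int]:
    n, members = common_neighbors(g, v, w)
    if n == 0:
        raise ValueError(
            f"({v!r}, {w!r}) is not a candidate pair: no common neighbors"
        )
    return n, members, g.degree(v), g.degree(w)


def _side_of(g: Graph, v: str) -> str:
    if g.mode == BIPARTITE:
        assert g.side is not None
        return g.side[v]
    return "all"


def jaccard(g: Graph, v: str, w: str) -> float:
    """n / |N(v) ∪ N(w)|."""
    n, _, dv, dw = _pair_inputs(g, v, w)
    return n / (dv + dw - n)


def cosine(g: Graph, v: str, w: str) -> float:
    """n normalized by the geometric mean of the degrees."""
    n, _, dv, dw = _pair_inputs(g, v, w)
    return n / math.sqrt(dv * dw)


def pearson(g: Graph, v: str, w: str) -> float:
    """Phi coefficient of the two binary adjacency vectors.

    Population moments over the M adjacency positions; NaN when either
    vector is constant (zero variance).
    """
    n, _, dv, dw = _pair_inputs(g, v, w)
    m = population_size(g, _side_of(g, v))
    var_v = dv * (m - dv)
    var_w = dw * (m - dw)
    if var_v == 0 or var_w == 0:
        return math.nan
    return (n * m - dv * dw) / math.sqrt(var_v * var_w)


def adamic_adar(g: Graph, v: str, w: str) -> float:
    """Σ 1/ln d(u) over common neighbors u (each has d(u) ≥ 2)."""
    _, members, _, _ = _pair_inputs(g, v, w)
    return sum(1.0 / math.log(g.degree(u)) for u in members)


def rai(g: Graph, v: str, w: str) -> float:
    """Resource allocation index: Σ 1/d(u) over common neighbors."""
    _, members, _, _ = _pair_inputs(g, v, w)
    return sum(1.0 / g.degree(u) for u in members)


def leverage(g: Graph, v: str, w: str) -> float:
    """Observed minus configuration-model-expected common neighbors, /M."""
    n, _, dv, dw = _pair_inputs(g, v, w)
    m = population_size(g, _side_of(g, v))
    return (n - dv * dw / m) / m


def lhn(g: Graph, v: str, w: str) -> float:
    """Leicht–Holme–Newman index (lift): n / (d(v)·d(w))."""
    n, _, dv, dw = _pair_inputs(g, v, w)
    return n / (dv * dw)


def hypergeom_tail(n: int, m: int, dv: int, dw: int) -> float:
    """P[X ≥ n] for X ~ Hypergeometric(M, d(v), d(w))."""
    if dv > m or dw > m:
        raise ValueError(f"degrees ({dv}, {dw}) exceed population {m}")
    return float(stats.hypergeom.sf(n - 1, m, dv, dw))


def hypergeom(g: Graph, v: str, w: str) -> float:
    """Upper-tail probability of n under a hypergeometric null.

    P[X ≥ n] for X ~ Hypergeometric(M, d(v), d(w)); smaller is stronger.
    """
    n, _, dv, dw = _pair_inputs(g, v, w)
    m = population_size(g, _side_of(g, v))
    return hypergeom_tail(n, m, dv, dw)


_DISPATCH = {
    "jaccard": jaccard,
    "cosine": cosine,
    "pearson": pearson,
    "adamic_adar": adamic_adar,
    "rai": rai,
    "leverage": leverage,
    "lhn": lhn,
    "hypergeom": hypergeom,
}


def score_all(
    g: Graph,
    measures: Sequence[str] | None = None,
    ranked_side: str | None = None,
) -> ScoreTable:
    """Compute the requested measures for every candidate pair.

    Parameters
    ----------
    measures
        Subset of :data:`MEASURE_NAMES`; all eight by default.
    ranked_side
        Defaults to ``"left"`` on bipartite graphs (the product/sample
        side of a rating network) and ``"all"`` on unipartite graphs.
    """
    if measures is None:
        measures = MEASURE_NAMES
    unknown = [m for m in measures if m not in _DISPATCH]
    if unknown:
        raise ValueError(f"unknown measure(s): {unknown}; valid: {list(MEASURE_NAMES)}")
    if ranked_side is None:
        ranked_side = LEFT if g.mode == BIPARTITE else "all"

    pairs = candidate_pairs(g, ranked_side)
    records: dict[str, list] = {"node_u": [], "node_v": [], "n_common": []}
    for m in measures:
        records[m] = []
    for u, v in pairs:
        n, _ = common_neighbors(g, u, v)
        records["node_u"].append(u)
        records["node_v"].append(v)
        records["n_common"].append(n)
        for m in measures:
            records[m].append(_DISPATCH[m](g, u, v))
    df = pd.DataFrame(records)
    if not len(df):
        df = df.astype({m: float for m in measures} | {"n_common": int})
    meta = {
        "mode": g.mode,
        "ranked_side": ranked_side,
        "population_size": population_size(g, ranked_side),
        "n_candidate_pairs": len(pairs),
    }
    return ScoreTable(df, meta=meta)
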