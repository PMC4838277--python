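"""Seeded benchmark generators with planted ground truth.

Two families:

* :func:`generate` builds rating-network-like benchmarks with planted
  same-side groups — the bipartite mode emulates movie-series structure
  (each group of left nodes shares a dedicated right-side audience, plus
  uniform background noise), the unipartite mode plants groups that
  share a dedicated neighborhood. The ground truth is the set of
  within-group pairs. Background noise attaches uniformly, without
  preferential attachment, so that correcting for degree heterogeneity
  (the FDSM's job) is the discriminating mechanism; heterogeneous
  degrees can be induced by per-group audience-size overrides.

* :func:`fixture_enumerations` exhaustively enumerates every simple
  graph with a tiny fixed degree sequence and the exact co-occurrence
  statistics of every same-side pair — the independent oracle for the
  FDSM sampler (uniformity, ⟨n⟩, σ[n], empirical p).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph import BIPARTITE, LEFT, RIGHT, UNIPARTITE, Graph, GroundTruth

__all__ = ["BenchmarkSpec", "generate", "FixtureEnumeration", "fixture_enumerations"]

_MAX_STATES = 10**5


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of a planted-group benchmark.

    Defaults describe a bipartite rating network with a strong planted
    signal: 10 groups ("series") of 5 left nodes ("movies"), each group
    sharing a dedicated audience of 20 right nodes ("users") attached
    with probability 0.9, plus 200 background right nodes attached
    uniformly with probability 0.01. In unipartite mode
    ``audience_size`` is the size of each group's dedicated shared
    neighborhood.
    """

    mode: str = BIPARTITE
    n_groups: int = 10
    group_size: int = 5
    audience_size: int | Sequence[int] = 20
    p_within: float = 0.9
    p_background: float = 0.01
    n_background_nodes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (BIPARTITE, UNIPARTITE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_groups < 1 or self.group_size < 2:
            raise ValueError("need n_groups >= 1 and group_size >= 2")
        if self.n_background_nodes < 0:
            raise ValueError("n_background_nodes must be non-negative")
        for p in (self.p_within, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        sizes = self.audience_sizes
        if len(sizes) != self.n_groups or any(a < 1 for a in sizes):
            raise ValueError("audience_size must be >= 1 (one value or one per group)")

    @property
    def audience_sizes(self) -> tuple[int, ...]:
        if isinstance(self.audience_size, int):
            return (self.audience_size,) * self.n_groups
        return tuple(self.audience_size)


def generate(spec: BenchmarkSpec) -> tuple[Graph, GroundTruth]:
    """Build the benchmark graph and its planted ground truth.

    Deterministic given the spec (seeded numpy PCG64). Nodes that end up
    with no edge are omitted from the graph; ground-truth pairs whose
    endpoint was lost that way are dropped, mirroring ground-truth links
    not contained in the network data.
    """
    rng = np.random.default_rng(spec.seed)
    bip = spec.mode == BIPARTITE
    edges: list[tuple[str, str]] = []
    side: dict[str, str] = {}

    members: list[list[str]] = []
    for gi in range(spec.n_groups):
        members.append([f"g{gi:02d}m{j:02d}" for j in range(spec.group_size)])
    background = [f"bg{j:03d}" for j in range(spec.n_background_nodes)]

    for gi, group in enumerate(members):
        audience = [f"g{gi:02d}a{j:02d}" for j in range(spec.audience_sizes[gi])]
        for m in group:
            side[m] = LEFT
        for a in audience:
            side[a] = RIGHT
        draw = rng.random((len(group), len(audience)))
        for i, m in enumerate(group):
            for j, a in enumerate(audience):
                if draw[i, j] < spec.p_within:
                    edges.append((m, a))
    for b in background:
        side[b] = RIGHT
    if background:
        left_all = [m for group in members for m in group]
        draw = rng.random((len(left_all), len(background)))
        for i, m in enumerate(left_all):
            for j, b in enumerate(background):
                if draw[i, j] < spec.p_background:
                    edges.append((m, b))

    graph = Graph(edges, mode=spec.mode, side=side if bip else None)
    gt_pairs = [
        (u, v)
        for group in members
        for u, v in itertools.combinations(group, 2)
        if u in graph and v in graph
    ]
    return graph, GroundTruth(gt_pairs, graph=graph)


# -- exhaustive FDSM enumeration (test oracle) ---------------------------


class FixtureEnumeration:
    """All simple graphs with one tiny degree sequence, plus exact
    co-occurrence statistics of every same-side pair under the uniform
    distribution over those graphs."""

    def __init__(
        self,
        name: str,
        mode: str,
        graph: Graph,
        ranked_nodes: Sequence[str],
        states: list[frozenset[tuple[str, str]]],
    ) -> None:
        self.name = name
        self.mode = mode
        self.graph = graph  # a representative observed graph
        self.ranked_nodes = list(ranked_nodes)
        self.states = states
        # per-pair common-neighbor count in every state
        self._n: dict[tuple[str, str], np.ndarray] = {}
        for u, v in itertools.combinations(sorted(self.ranked_nodes), 2):
            counts = []
            for st in states:
                nbr_u = {b if a == u else a for a, b in st if u in (a, b)}
                nbr_v = {b if a == v else a for a, b in st if v in (a, b)}
                counts.append(len(nbr_u & nbr_v))
            self._n[(u, v)] = np.asarray(counts, dtype=np.int64)

    @property
    def num_states(self) -> int:
        return len(self.states)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._n)

    def counts(self, pair: tuple[str, str]) -> np.ndarray:
        u, v = pair
        return self._n[(u, v) if u < v else (v, u)]

    def exact_mean(self, pair: tuple[str, str]) -> float:
        return float(self.counts(pair).mean())

    def exact_sd(self, pair: tuple[str, str]) -> float:
        """Population deviation over the uniform state distribution."""
        return float(self.counts(pair).std())

    def exact_moment(self, pair: tuple[str, str], order: int) -> float:
        c = self.counts(pair).astype(float)
        return float(np.mean((c - c.mean()) ** order))

    def exact_p(self, pair: tuple[str, str], observed: int) -> float:
        c = self.counts(pair)
        return float(np.mean(c >= observed))

    def state_index(self, edges: frozenset[tuple[str, str]]) -> int:
        return self.states.index(edges)


def _enumerate_bipartite(dl: Sequence[int], dr: Sequence[int]) -> list[list[tuple[int, int]]]:
    """All bipartite simple graphs with left/right degree sequences."""
    nr = len(dr)
    states: list[list[tuple[int, int]]] = []

    def rec(i: int, remaining: tuple[int, ...], acc: list[tuple[int, int]]) -> None:
        if len(states) > _MAX_STATES:
            raise ValueError("degree sequence has too many states to enumerate")
        if i == len(dl):
            if all(r == 0 for r in remaining):
                states.append(list(acc))
            return
        avail = [j for j in range(nr) if remaining[j] > 0]
        if dl[i] > len(avail):
            return
        for combo in itertools.combinations(avail, dl[i]):
            rem = list(remaining)
            for j in combo:
                rem[j] -= 1
            rec(i + 1, tuple(rem), acc + [(i, j) for j in combo])

    rec(0, tuple(dr), [])
    return states


def _enumerate_unipartite(degrees: Sequence[int]) -> list[list[tuple[int, int]]]:
    """All simple graphs on len(degrees) labeled nodes with the sequence."""
    n = len(degrees)
    total = sum(degrees)
    if total % 2:
        return []
    m = total // 2
    possible = list(itertools.combinations(range(n), 2))
    if math.comb(len(possible), m) > 5 * _MAX_STATES:
        raise ValueError("degree sequence has too many states to enumerate")
    states = []
    for combo in itertools.combinations(possible, m):
        deg = [0] * n
        for a, b in combo:
            deg[a] += 1
            deg[b] += 1
        if deg == list(degrees):
            states.append(list(combo))
    if len(states) > _MAX_STATES:
        raise ValueError("degree sequence has too many states to enumerate")
    return states


def _bipartite_fixture(name: str, dl: Sequence[int], dr: Sequence[int]) -> FixtureEnumeration:
    left = [f"L{i}" for i in range(len(dl))]
    right = [f"R{j}" for j in range(len(dr))]
    raw = _enumerate_bipartite(dl, dr)
    if not raw:
        raise ValueError(f"degree sequence {dl}/{dr} is not realizable")
    states = [
        frozenset(tuple(sorted((left[i], right[j]))) for i, j in st) for st in raw
    ]
    side = {u: LEFT for u in left} | {u: RIGHT for u in right}
    rep = Graph(
        [tuple(sorted((left[i], right[j]))) for i, j in raw[0]],
        mode=BIPARTITE,
        side=side,
        nodes=left + right,
    )
    return FixtureEnumeration(name, BIPARTITE, rep, left, states)


def _unipartite_fixture(name: str, degrees: Sequence[int]) -> FixtureEnumeration:
    nodes = [f"v{i}" for i in range(len(degrees))]
    raw = _enumerate_unipartite(degrees)
    if not raw:
        raise ValueError(f"degree sequence {degrees} is not realizable")
    states = [
        frozenset(tuple(sorted((nodes[a], nodes[b]))) for a, b in st) for st in raw
    ]
    rep = Graph(
        [tuple(sorted((nodes[a], nodes[b]))) for a, b in raw[0]],
        mode=UNIPARTITE,
        nodes=nodes,
    )
    return FixtureEnumeration(name, UNIPARTITE, rep, nodes, states)


def fixture_enumerations() -> list[FixtureEnumeration]:
    """Catalog of tiny degree sequences with fully enumerated FDSM state
    spaces — the exact oracle used by the sampler tests."""
    return [
        _bipartite_fixture("bip-1,1/1,1", (1, 1), (1, 1)),
        _bipartite_fixture("bip-K22", (2, 2), (2, 2)),
        _bipartite_fixture("bip-2,1,1/2,1,1", (2, 1, 1), (2, 1, 1)),
        _bipartite_fixture("bip-2,2,1/2,2,1", (2, 2, 1), (2, 2, 1)),
        _unipartite_fixture("uni-path3", (1, 2, 1)),
        _unipartite_fixture("uni-path4", (1, 2, 2, 1)),
        _unipartite_fixture("uni-5cycle-ish", (2, 2, 2, 2, 2)),
    ]
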