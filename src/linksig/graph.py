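"""Undirected simple graphs, ground truths, and their TSV I/O.

The package works on two kinds of networks:

* **unipartite** graphs (e.g. protein-protein interaction or friendship
  networks), where any node pair may be scored, and
* **bipartite** graphs (e.g. user-item rating networks), where only
  same-side pairs are scored and common neighbors necessarily lie on the
  opposite side.

Node identifiers are opaque strings; the canonical order of a pair is
lexicographic (smaller identifier first), which fixes tie-breaking and
output order everywhere downstream.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("linksig")

UNIPARTITE = "unipartite"
BIPARTITE = "bipartite"
LEFT = "left"
RIGHT = "right"

__all__ = [
    "Graph",
    "GroundTruth",
    "canonical_pair",
    "read_graph",
    "write_graph",
    "read_ground_truth",
    "write_ground_truth",
    "common_neighbors",
    "candidate_pairs",
]


def canonical_pair(u: str, v: str) -> tuple[str, str]:
    """Order a pair lexicographically; reject self-pairs."""
    if u == v:
        raise ValueError(f"self-pair {u!r} is not allowed")
    return (u, v) if u < v else (v, u)


class Graph:
    """An undirected simple graph, optionally bipartite.

    Parameters
    ----------
    edges
        Iterable of identifier pairs. Duplicates are collapsed and the
        endpoint order is normalized; self-edges are rejected.
    mode
        ``"unipartite"`` or ``"bipartite"``.
    side
        Mapping node -> ``"left"``/``"right"``; required in bipartite mode
        for every endpoint. Ignored in unipartite mode.
    nodes
        Optional extra node identifiers (e.g. isolated nodes).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        mode: str = UNIPARTITE,
        side: Mapping[str, str] | None = None,
        nodes: Iterable[str] = (),
    ) -> None:
        if mode not in (UNIPARTITE, BIPARTITE):
            raise ValueError(f"unknown graph mode {mode!r}")
        self.mode = mode
        edge_set: set[tuple[str, str]] = set()
        node_set: set[str] = set(nodes)
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-edge {u!r}-{v!r} is not allowed")
            edge_set.add(canonical_pair(u, v))
            node_set.add(u)
            node_set.add(v)
        self.node_ids: tuple[str, ...] = tuple(sorted(node_set))
        self._index: dict[str, int] = {u: i for i, u in enumerate(self.node_ids)}

        if mode == BIPARTITE:
            if side is None:
                raise ValueError("bipartite graphs require a side mapping")
            self.side: dict[str, str] | None = {}
            for u in self.node_ids:
                s = side.get(u)
                if s not in (LEFT, RIGHT):
                    raise ValueError(f"node {u!r} has no valid side (got {s!r})")
                self.side[u] = s
            for u, v in edge_set:
                if self.side[u] == self.side[v]:
                    raise ValueError(
                        f"edge {u!r}-{v!r} joins two {self.side[u]} nodes; "
                        "bipartite edges must cross sides"
                    )
        else:
            self.side = None

        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self._adj: list[set[int]] = [set() for _ in self.node_ids]
        for u, v in edge_set:
            iu, iv = self._index[u], self._index[v]
            self._adj[iu].add(iv)
            self._adj[iv].add(iu)

    # -- basic queries ---------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"node {node!r} not in graph") from None

    def degree(self, node: str) -> int:
        return len(self._adj[self.index(node)])

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self.node_ids[i] for i in self._adj[self.index(node)])

    def neighbor_indices(self, i: int) -> set[int]:
        return self._adj[i]

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_pair(u, v) in self.edges

    def nodes_on_side(self, side: str) -> tuple[str, ...]:
        if self.mode != BIPARTITE:
            raise ValueError("nodes_on_side requires a bipartite graph")
        assert self.side is not None
        return tuple(u for u in self.node_ids if self.side[u] == side)

    def degree_sequence(self) -> dict[str, int]:
        return {u: len(self._adj[i]) for i, u in enumerate(self.node_ids)}

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(mode={self.mode!r}, |V|={self.num_nodes}, |E|={self.num_edges})"


class GroundTruth:
    """A set of externally validated node pairs used only for evaluation.

    Provides ``t`` (the number of ground-truth pairs) and ``t_of(v)`` (the
    number of pairs incident to ``v``), the quantities that set the top-k
    cutoffs of the global and local assessment tasks.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]], graph: Graph | None = None) -> None:
        pair_set: set[tuple[str, str]] = set()
        for u, v in pairs:
            p = canonical_pair(str(u), str(v))
            if graph is not None and graph.mode == BIPARTITE:
                assert graph.side is not None
                su, sv = graph.side.get(p[0]), graph.side.get(p[1])
                if su is not None and sv is not None and su != sv:
                    raise ValueError(
                        f"ground-truth pair {p[0]!r}-{p[1]!r} crosses the bipartition"
                    )
            pair_set.add(p)
        self.pairs: frozenset[tuple[str, str]] = frozenset(pair_set)
        self._t_of: dict[str, int] = {}
        for u, v in self.pairs:
            self._t_of[u] = self._t_of.get(u, 0) + 1
            self._t_of[v] = self._t_of.get(v, 0) + 1

    @property
    def t(self) -> int:
        """Total number of ground-truth pairs."""
        return len(self.pairs)

    def t_of(self, node: str) -> int:
        """Number of ground-truth pairs incident to ``node``."""
        return self._t_of.get(node, 0)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))


# -- neighborhood queries ------------------------------------------------


def _check_same_mode_pair(g: Graph, v: str, w: str) -> None:
    if v == w:
        raise ValueError(f"pair ({v!r}, {w!r}) is a self-pair")
    if g.mode == BIPARTITE:
        assert g.side is not None
        if g.side[v] != g.side[w]:
            raise ValueError(
                f"pair ({v!r}, {w!r}) crosses the bipartition; only same-side "
                "pairs have a common-neighbor count"
            )


def common_neighbors(g: Graph, v: str, w: str) -> tuple[int, frozenset[str]]:
    """Count and return the common neighbors N(v) ∩ N(w).

    In bipartite mode both nodes must lie on the same side; the common
    neighbors then lie on the opposite side.
    """
    _check_same_mode_pair(g, v, w)
    shared = g.neighbor_indices(g.index(v)) & g.neighbor_indices(g.index(w))
    members = frozenset(g.node_ids[i] for i in shared)
    return len(members), members


def candidate_pairs(g: Graph, ranked_side: str = "all") -> list[tuple[str, str]]:
    """All unordered same-mode pairs with at least one common neighbor.

    These are the only pairs any similarity measure scores. Returned in
    canonical lexicographic order.

    Parameters
    ----------
    ranked_side
        ``"all"`` for unipartite graphs; ``"left"`` or ``"right"`` for
        bipartite graphs (the side whose pairs are ranked).
    """
    if g.mode == BIPARTITE:
        if ranked_side not in (LEFT, RIGHT):
            raise ValueError("bipartite graphs require ranked_side 'left' or 'right'")
        assert g.side is not None
        hub_side = RIGHT if ranked_side == LEFT else LEFT
        hubs = (g.index(u) for u in g.nodes_on_side(hub_side))
    else:
        if ranked_side != "all":
            raise ValueError("unipartite graphs require ranked_side 'all'")
        hubs = iter(range(g.num_nodes))

    pairs: set[tuple[str, str]] = set()
    for h in hubs:
        members = sorted(g.neighbor_indices(h))
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pairs.add((g.node_ids[members[a]], g.node_ids[members[b]]))
    return sorted(pairs)


# -- TSV I/O -------------------------------------------------------------


def _parse_tsv_lines(path: str):
    """Yield (line_number, fields) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield ln, line.split("\t")


def read_graph(path: str, mode: str = UNIPARTITE, side_file: str | None = None) -> Graph:
    """Read an edge-list TSV into a :class:`Graph`.

    The file holds one edge per line: ``node_u <TAB> node_v``, with
    ``#``-prefixed comment/header lines. Bipartite graphs declare the
    partition either through a third column on each line (the side of
    ``node_u``) or through a separate two-column node/side file.
    """
    sides: dict[str, str] = {}
    if side_file is not None:
        for ln, fields in _parse_tsv_lines(side_file):
            if len(fields) < 2 or fields[1] not in (LEFT, RIGHT):
                raise ValueError(f"{side_file}:{ln}: expected 'node<TAB>left|right'")
            sides[fields[0]] = fields[1]

    edges: list[tuple[str, str]] = []
    for ln, fields in _parse_tsv_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{ln}: expected two tab-separated node identifiers")
        u, v = fields[0].strip(), fields[1].strip()
        if u == v:
            raise ValueError(f"{path}:{ln}: self-edge {u!r}-{v!r}")
        if mode == BIPARTITE and len(fields) >= 3 and fields[2].strip():
            s = fields[2].strip()
            if s not in (LEFT, RIGHT):
                raise ValueError(f"{path}:{ln}: side column must be 'left' or 'right'")
            prev_u = sides.setdefault(u, s)
            if prev_u != s:
                raise ValueError(f"{path}:{ln}: node {u!r} declared on both sides")
            other = LEFT if s == RIGHT else RIGHT
            prev_v = sides.setdefault(v, other)
            if prev_v != other:
                raise ValueError(f"{path}:{ln}: node {v!r} declared on both sides")
        edges.append((u, v))

    if mode == BIPARTITE and not sides:
        raise ValueError(
            f"{path}: bipartite mode requires a side declaration "
            "(third column or side_file)"
        )
    return Graph(edges, mode=mode, side=sides if mode == BIPARTITE else None)


def write_graph(g: Graph, path: str) -> None:
    """Write an edge-list TSV (with a side column in bipartite mode)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mode={g.mode} nodes={g.num_nodes} edges={g.num_edges}\n")
        if g.mode == BIPARTITE:
            fh.write("# node_u\tnode_v\tside_of_u\n")
            assert g.side is not None
            for u, v in sorted(g.edges):
                fh.write(f"{u}\t{v}\t{g.side[u]}\n")
        else:
            fh.write("# node_u\tnode_v\n")
            for u, v in sorted(g.edges):
                fh.write(f"{u}\t{v}\n")


def read_ground_truth(path: str, g: Graph) -> GroundTruth:
    """Read a two-column pair-list TSV as a :class:`GroundTruth`.

    Pairs with an endpoint absent from the graph are dropped with a logged
    warning (their nodes were filtered out of, or never present in, the
    network data); duplicates and endpoint order are normalized.
    """
    pairs: list[tuple[str, str]] = []
    dropped = 0
    for ln, fields in _parse_tsv_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{ln}: expected two tab-separated node identifiers")
        u, v = fields[0].strip(), fields[1].strip()
        if u not in g or v not in g:
            dropped += 1
            continue
        pairs.append((u, v))
    if dropped:
        logger.warning(
            "%s: dropped %d ground-truth pair(s) with endpoints absent from the graph",
            path,
            dropped,
        )
    gt = GroundTruth(pairs, graph=g)
    return gt


def write_ground_truth(gt: GroundTruth, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ground truth: t={gt.t}\n")
        for u, v in gt:
            fh.write(f"{u}\t{v}\n")
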