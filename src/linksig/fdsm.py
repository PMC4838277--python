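"""The fixed degree sequence model (FDSM) and the z* statistic.

The FDSM is the uniform distribution over all *simple* graphs that share
the observed graph's exact degree sequence (and bipartition, for
bipartite graphs). Sampling from it calibrates the common-neighbor count
n(v, w) of each candidate pair against what degree heterogeneity alone
would produce:

* ⟨n(v, w)⟩ and the sample deviation σ[n(v, w)] give the z-score
  z = (n − ⟨n⟩) / σ[n];
* the empirical p-value is the fraction of sampled graphs in which the
  pair has at least its observed number of common neighbors.

With a finite number of samples, very small p-values collapse to 0 and
cannot be told apart, while the z-score is unreliable for low-degree
pairs whose null distribution is far from normal. The composite z*
ranking — p ascending, ties broken by z descending — uses each statistic
where it is informative.

Sampling uses a lazy Markov chain of degree-preserving edge swaps
(checkerboard swaps in bipartite mode): two edges are picked uniformly
at random and the swap is applied unless it would create a self-edge or
a duplicate edge; a rejected proposal still consumes one attempt.
Burn-in and spacing are expressed in attempts and default to 100·|E| and
5·|E|. Co-occurrence statistics are streamed (O(#pairs) memory,
independent of the number of samples).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from . import _kernels
from .graph import BIPARTITE, LEFT, RIGHT, Graph, common_neighbors
from .table import ScoreTable

logger = logging.getLogger("linksig")

_CHUNK = 1 << 18  # attempts per pre-drawn randomness block

__all__ = [
    "SamplerConfig",
    "CoOccurrenceStats",
    "randomize",
    "accumulate",
    "z_score",
    "empirical_p",
    "z_star_ranking",
    "ZStarEntry",
    "add_fdsm_scores",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Settings of the FDSM swap-chain sampler.

    ``burn_in_attempts``/``spacing_attempts`` of ``None`` resolve to
    100·|E| and 5·|E|. Identical config and input graph give a
    bit-identical sample sequence.
    """

    num_samples: int = 1000
    burn_in_attempts: int | None = None
    spacing_attempts: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_samples < 1:
            raise ValueError("num_samples must be positive")
        for name in ("burn_in_attempts", "spacing_attempts"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"{name} must be non-negative")

    def resolve(self, num_edges: int) -> tuple[int, int, int]:
        burn = self.burn_in_attempts if self.burn_in_attempts is not None else 100 * num_edges
        spacing = self.spacing_attempts if self.spacing_attempts is not None else 5 * num_edges
        return self.num_samples, burn, spacing


class _Chain:
    """In-place swap chain over one graph's adjacency matrix."""

    def __init__(self, g: Graph, seed: int) -> None:
        self.mode = g.mode
        self.rng = np.random.default_rng(seed)
        if g.mode == BIPARTITE:
            self.left = list(g.nodes_on_side(LEFT))
            self.right = list(g.nodes_on_side(RIGHT))
            lidx = {u: i for i, u in enumerate(self.left)}
            ridx = {u: i for i, u in enumerate(self.right)}
            self.adj = np.zeros((len(self.left), len(self.right)), dtype=np.uint8)
            eu, ev = [], []
            assert g.side is not None
            for u, v in sorted(g.edges):
                if g.side[u] == RIGHT:
                    u, v = v, u
                eu.append(lidx[u])
                ev.append(ridx[v])
                self.adj[lidx[u], ridx[v]] = 1
            self.eu = np.asarray(eu, dtype=np.int64)
            self.ev = np.asarray(ev, dtype=np.int64)
        else:
            self.nodes = list(g.node_ids)
            n = len(self.nodes)
            self.adj = np.zeros((n, n), dtype=np.uint8)
            eu, ev = [], []
            for u, v in sorted(g.edges):
                iu, iv = g.index(u), g.index(v)
                self.adj[iu, iv] = 1
                self.adj[iv, iu] = 1
                eu.append(iu)
                ev.append(iv)
            self.eu = np.asarray(eu, dtype=np.int64)
            self.ev = np.asarray(ev, dtype=np.int64)
        self.m = len(self.eu)

    def advance(self, attempts: int) -> None:
        remaining = attempts
        while remaining > 0:
            block = min(remaining, _CHUNK)
            idx1 = self.rng.integers(0, self.m, size=block)
            idx2 = self.rng.integers(0, self.m, size=block)
            if self.mode == BIPARTITE:
                _kernels.swap_chain_bipartite(self.adj, self.eu, self.ev, idx1, idx2)
            else:
                orient = self.rng.integers(0, 2, size=block)
                _kernels.swap_chain_unipartite(
                    self.adj, self.eu, self.ev, idx1, idx2, orient
                )
            remaining -= block

    def edge_list(self) -> list[tuple[str, str]]:
        if self.mode == BIPARTITE:
            return [
                (self.left[a], self.right[x]) for a, x in zip(self.eu, self.ev)
            ]
        return [(self.nodes[a], self.nodes[b]) for a, b in zip(self.eu, self.ev)]


def randomize(g: Graph, config: SamplerConfig) -> Iterator[Graph]:
    """Yield FDSM samples: simple graphs with g's exact degree sequence.

    Emits ``config.num_samples`` graphs, the first after the burn-in and
    each subsequent one after the spacing interval. A graph with fewer
    than two edges has a single-state model; the input is emitted
    unchanged with a warning.
    """
    num_samples, burn, spacing = config.resolve(g.num_edges)
    if g.num_edges < 2:
        logger.warning(
            "graph has %d edge(s); FDSM state space is a single graph", g.num_edges
        )
        for _ in range(num_samples):
            yield g
        return
    chain = _Chain(g, config.seed)
    chain.advance(burn)
    for k in range(num_samples):
        if k > 0:
            chain.advance(spacing)
        yield Graph(chain.edge_list(), mode=g.mode, side=g.side, nodes=g.node_ids)


class CoOccurrenceStats:
    """Streaming per-pair co-occurrence statistics over FDSM samples.

    For each candidate pair the accumulator keeps the observed count,
    the running sum and sum of squares of the sampled counts, and the
    number of samples in which the sampled count reached the observed
    one (the numerator of the empirical p-value).
    """

    def __init__(self, pairs: Sequence[tuple[str, str]], observed: Sequence[int]) -> None:
        self.pairs: list[tuple[str, str]] = list(pairs)
        self._row = {p: i for i, p in enumerate(self.pairs)}
        self.observed = np.asarray(observed, dtype=np.int64)
        self.sum_n = np.zeros(len(self.pairs), dtype=np.int64)
        self.sum_n_sq = np.zeros(len(self.pairs), dtype=np.int64)
        self.exceed_count = np.zeros(len(self.pairs), dtype=np.int64)
        self.num_samples = 0

    def update(self, counts: np.ndarray) -> None:
        """Fold in one sample's per-pair common-neighbor counts."""
        counts = np.asarray(counts, dtype=np.int64)
        self.sum_n += counts
        self.sum_n_sq += counts * counts
        self.exceed_count += counts >= self.observed
        self.num_samples += 1

    # -- derived statistics ---------------------------------------------

    def index(self, pair: tuple[str, str]) -> int:
        u, v = pair
        key = (u, v) if u < v else (v, u)
        try:
            return self._row[key]
        except KeyError:
            raise KeyError(f"pair {key!r} not tracked") from None

    def mean(self) -> np.ndarray:
        return self.sum_n / self.num_samples

    def sd(self) -> np.ndarray:
        """Sample deviation with divisor S−1 (exact integer numerator)."""
        s = self.num_samples
        if s < 2:
            raise ValueError("sample deviation requires at least 2 samples")
        num = s * self.sum_n_sq - self.sum_n * self.sum_n
        return np.sqrt(np.maximum(num, 0) / (s * (s - 1.0)))

    def p_values(self) -> np.ndarray:
        if self.num_samples == 0:
            raise ValueError("empirical p-value requires at least 1 sample")
        return self.exceed_count / self.num_samples

    def z_values(self) -> np.ndarray:
        mean = self.mean()
        sd = self.sd()
        z = np.zeros(len(self.pairs))
        nonzero = sd > 0
        z[nonzero] = (self.observed[nonzero] - mean[nonzero]) / sd[nonzero]
        degenerate = ~nonzero
        above = degenerate & (self.observed > mean)
        below = degenerate & (self.observed < mean)
        z[above] = np.inf
        z[below] = -np.inf
        return z


def z_score(stats: CoOccurrenceStats, pair: tuple[str, str]) -> float:
    """z = (n − ⟨n⟩)/σ[n]; 0 when σ=0 and n=⟨n⟩, ±inf otherwise."""
    return float(stats.z_values()[stats.index(pair)])


def empirical_p(stats: CoOccurrenceStats, pair: tuple[str, str]) -> float:
    """Fraction of samples whose count reached the observed one; may be 0."""
    return float(stats.p_values()[stats.index(pair)])


def accumulate(
    g: Graph,
    pairs: Sequence[tuple[str, str]],
    config: SamplerConfig,
) -> CoOccurrenceStats:
    """Run the sampler and stream per-pair co-occurrence statistics.

    ``pairs`` must be candidate pairs of ``g`` (same side in bipartite
    mode). Memory is proportional to the number of pairs, not to the
    number of samples.
    """
    observed = [common_neighbors(g, u, v)[0] for u, v in pairs]
    stats = CoOccurrenceStats([tuple(sorted(p)) for p in pairs], observed)
    num_samples, burn, spacing = config.resolve(g.num_edges)

    if g.num_edges < 2:
        logger.warning(
            "graph has %d edge(s); FDSM statistics are degenerate", g.num_edges
        )
        base = np.asarray(observed, dtype=np.int64)
        for _ in range(num_samples):
            stats.update(base)
        return stats

    if g.mode == BIPARTITE:
        assert g.side is not None
        sides = {g.side[u] for p in stats.pairs for u in p}
        if len(sides) > 1:
            raise ValueError("all pairs must lie on the same side of the bipartition")
        pair_side = sides.pop() if sides else LEFT
    chain = _Chain(g, config.seed)

    if g.mode == BIPARTITE:
        node_list = chain.left if pair_side == LEFT else chain.right
        idx = {u: i for i, u in enumerate(node_list)}
    else:
        idx = {u: i for i, u in enumerate(chain.nodes)}
    iu = np.asarray([idx[u] for u, _ in stats.pairs], dtype=np.intp)
    iv = np.asarray([idx[v] for _, v in stats.pairs], dtype=np.intp)

    def pair_counts() -> np.ndarray:
        a = chain.adj.astype(np.int64)
        if g.mode == BIPARTITE and pair_side == RIGHT:
            a = a.T
        c = a @ a.T
        return c[iu, iv]

    chain.advance(burn)
    stats.update(pair_counts())
    for _ in range(num_samples - 1):
        chain.advance(spacing)
        stats.update(pair_counts())
    return stats


class ZStarEntry(NamedTuple):
    node_u: str
    node_v: str
    p_emp: float
    z: float


def z_star_ranking(stats: CoOccurrenceStats) -> list[ZStarEntry]:
    """Pairs ordered by empirical p ascending, z descending within ties.

    Double ties fall back to canonical lexicographic pair order, so the
    ranking is deterministic and invariant under input permutation. The
    rank of a pair is its position + 1.
    """
    p = stats.p_values()
    z = stats.z_values()
    order = sorted(
        range(len(stats.pairs)), key=lambda i: (p[i], -z[i], stats.pairs[i])
    )
    return [
        ZStarEntry(stats.pairs[i][0], stats.pairs[i][1], float(p[i]), float(z[i]))
        for i in order
    ]


def add_fdsm_scores(
    table: ScoreTable, g: Graph, config: SamplerConfig
) -> CoOccurrenceStats:
    """Augment a ScoreTable with FDSM columns.

    Adds ``fdsm_mean``, ``fdsm_sd``, ``z``, ``p_emp`` and the composite
    ``z_star_rank`` (1 = most significant) and records the sampler
    settings in the table metadata. Returns the accumulator.
    """
    stats = accumulate(g, table.pairs, config)
    table.add_column("fdsm_mean", stats.mean())
    table.add_column("fdsm_sd", stats.sd())
    table.add_column("z", stats.z_values())
    table.add_column("p_emp", stats.p_values())
    ranking = z_star_ranking(stats)
    rank = np.empty(len(table), dtype=np.int64)
    for pos, entry in enumerate(ranking, start=1):
        rank[table.row_of(entry.node_u, entry.node_v)] = pos
    table.add_column("z_star_rank", rank)
    num_samples, burn, spacing = config.resolve(g.num_edges)
    table.meta.update(
        sampler_num_samples=num_samples,
        sampler_burn_in_attempts=burn,
        sampler_spacing_attempts=spacing,
        sampler_seed=config.seed,
    )
    logger.info(
        "FDSM sampling: S=%d burn_in=%d spacing=%d seed=%d",
        num_samples,
        burn,
        spacing,
        config.seed,
    )
    return stats
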