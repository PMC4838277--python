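"""FDSM sampler, streaming co-occurrence statistics, z, p and z*."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from linksig import (
    CoOccurrenceStats,
    Graph,
    SamplerConfig,
    accumulate,
    candidate_pairs,
    empirical_p,
    randomize,
    z_score,
    z_star_ranking,
)
from linksig.synthetic import fixture_enumerations

from conftest import random_bipartite, random_unipartite


def stats_from_samples(observed: int, samples: list[int]) -> CoOccurrenceStats:
    st = CoOccurrenceStats([("a", "b")], [observed])
    for n in samples:
        st.update(np.array([n]))
    return st


class TestSamplerConfig:
    def test_defaults_scale_with_edges(self):
        s, burn, spacing = SamplerConfig(seed=0).resolve(50)
        assert (s, burn, spacing) == (1000, 5000, 250)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(num_samples=0)
        with pytest.raises(ValueError):
            SamplerConfig(burn_in_attempts=-1)


class TestRandomize:
    @pytest.mark.parametrize(
        "graph_factory",
        [
            lambda: random_unipartite(15, 0.25, seed=8),
            lambda: random_bipartite(8, 10, 0.3, seed=8),
        ],
        ids=["unipartite", "bipartite"],
    )
    def test_samples_preserve_degrees_and_simplicity(self, graph_factory):
        g = graph_factory()
        degrees = g.degree_sequence()
        cfg = SamplerConfig(num_samples=25, seed=1)
        for sample in randomize(g, cfg):
            # Graph construction itself enforces simplicity and the
            # bipartition; equal degree maps rule out collapsed duplicates.
            assert sample.degree_sequence() == degrees
            assert sample.num_edges == g.num_edges
            assert sample.mode == g.mode

    def test_single_state_space_returns_input(self, k22):
        cfg = SamplerConfig(num_samples=10, seed=0)
        for sample in randomize(k22, cfg):
            assert sample.edges == k22.edges

    def test_two_state_space_visits_both(self):
        side = {"L0": "left", "L1": "left", "R0": "right", "R1": "right"}
        g = Graph([("L0", "R0"), ("L1", "R1")], mode="bipartite", side=side)
        cfg = SamplerConfig(num_samples=200, seed=2)
        seen = {frozenset(s.edges) for s in randomize(g, cfg)}
        assert len(seen) == 2

    def test_under_two_edges_emits_input_with_warning(self, caplog):
        g = Graph([("a", "b")])
        with caplog.at_level("WARNING", logger="linksig"):
            samples = list(randomize(g, SamplerConfig(num_samples=3, seed=0)))
        assert len(samples) == 3 and all(s.edges == g.edges for s in samples)
        assert any("single graph" in rec.getMessage() for rec in caplog.records)

    def test_identical_seed_identical_sequence(self):
        g = random_unipartite(12, 0.3, seed=9)
        cfg = SamplerConfig(num_samples=10, seed=42)
        seq1 = [frozenset(s.edges) for s in randomize(g, cfg)]
        seq2 = [frozenset(s.edges) for s in randomize(g, cfg)]
        assert seq1 == seq2


class TestAccumulate:
    def test_k22_movie_pair_degenerate(self, k22):
        cfg = SamplerConfig(num_samples=50, seed=0)
        st = accumulate(k22, [("m1", "m2")], cfg)
        assert st.observed[0] == 2
        assert st.mean()[0] == 2.0 and st.sd()[0] == 0.0
        assert st.exceed_count[0] == st.num_samples == 50

    def test_sum_bounded_by_min_degree(self):
        g = random_bipartite(8, 8, 0.4, seed=3)
        pairs = candidate_pairs(g, "left")
        cfg = SamplerConfig(num_samples=40, seed=1)
        st = accumulate(g, pairs, cfg)
        for i, (u, v) in enumerate(st.pairs):
            assert st.sum_n[i] <= 40 * min(g.degree(u), g.degree(v))

    def test_reproducible_for_identical_seed(self):
        g = random_unipartite(14, 0.3, seed=6)
        pairs = candidate_pairs(g)
        cfg = SamplerConfig(num_samples=60, seed=7)
        a, b = accumulate(g, pairs, cfg), accumulate(g, pairs, cfg)
        assert np.array_equal(a.sum_n, b.sum_n)
        assert np.array_equal(a.sum_n_sq, b.sum_n_sq)
        assert np.array_equal(a.exceed_count, b.exceed_count)

    def test_two_state_enumeration_oracle(self):
        # left degrees (1,1)/right (1,1): two states; the left pair has
        # n=0 in both, so mean 0, sd 0, p=1 regardless of the state.
        side = {"L0": "left", "L1": "left", "R0": "right", "R1": "right"}
        g = Graph([("L0", "R0"), ("L1", "R1")], mode="bipartite", side=side)
        st = accumulate(g, [("L0", "L1")], SamplerConfig(num_samples=30, seed=0))
        assert st.mean()[0] == 0.0 and st.sd()[0] == 0.0
        assert st.p_values()[0] == 1.0


class TestZAndP:
    def test_z_score_hand_computed(self):
        st = stats_from_samples(3, [1, 1, 2, 2])
        # mean 1.5, sample sd sqrt(1/3) -> z = 1.5*sqrt(3)
        assert z_score(st, ("a", "b")) == pytest.approx(1.5 * math.sqrt(3.0))

    def test_z_zero_when_constant_and_equal(self):
        st = stats_from_samples(2, [2, 2, 2])
        assert z_score(st, ("a", "b")) == 0.0

    def test_z_infinite_when_constant_and_above(self):
        st = stats_from_samples(3, [2, 2, 2])
        assert z_score(st, ("a", "b")) == math.inf
        st = stats_from_samples(1, [2, 2, 2])
        assert z_score(st, ("a", "b")) == -math.inf

    def test_z_requires_two_samples(self):
        st = stats_from_samples(1, [1])
        with pytest.raises(ValueError):
            z_score(st, ("a", "b"))

    def test_empirical_p_examples(self):
        assert empirical_p(stats_from_samples(2, [1, 1, 2, 2]), ("a", "b")) == 0.5
        assert empirical_p(stats_from_samples(3, [1, 1, 2, 2]), ("a", "b")) == 0.0
        assert empirical_p(stats_from_samples(0, [1, 1, 2, 2]), ("a", "b")) == 1.0

    def test_empirical_p_requires_samples(self):
        st = CoOccurrenceStats([("a", "b")], [1])
        with pytest.raises(ValueError):
            empirical_p(st, ("a", "b"))

    def test_empirical_p_nonincreasing_in_observed(self):
        samples = [0, 1, 1, 2, 3, 3, 3, 5]
        ps = [
            empirical_p(stats_from_samples(obs, samples), ("a", "b"))
            for obs in range(0, 7)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestZStarRanking:
    def make_stats(self, entries):
        """entries: list of (pair, p, z) realized through raw counters."""
        pairs = [e[0] for e in entries]
        st = CoOccurrenceStats(pairs, [0] * len(pairs))
        st.num_samples = 10
        for i, (_, p, z) in enumerate(entries):
            st.exceed_count[i] = round(p * 10)
        self._z = np.array([e[2] for e in entries], dtype=float)
        st.z_values = lambda: self._z  # direct (p, z) table
        return st

    def test_p_then_z_then_canonical(self):
        st = self.make_stats(
            [(("c", "d"), 0.1, 9.0), (("a", "b"), 0.0, 5.0), (("a", "c"), 0.0, 3.0)]
        )
        ranked = z_star_ranking(st)
        assert [(e.node_u, e.node_v) for e in ranked] == [
            ("a", "b"),
            ("a", "c"),
            ("c", "d"),
        ]

    def test_all_tied_falls_back_to_canonical(self):
        st = self.make_stats(
            [(("b", "c"), 0.2, 1.0), (("a", "b"), 0.2, 1.0), (("a", "c"), 0.2, 1.0)]
        )
        assert [(e.node_u, e.node_v) for e in z_star_ranking(st)] == [
            ("a", "b"),
            ("a", "c"),
            ("b", "c"),
        ]

    def test_permutation_invariant(self):
        entries = [
            (("a", "b"), 0.3, 2.0),
            (("a", "c"), 0.0, 1.0),
            (("b", "c"), 0.0, 4.0),
            (("b", "d"), 0.1, -1.0),
        ]
        base = z_star_ranking(self.make_stats(entries))
        for perm in itertools.permutations(entries):
            assert z_star_ranking(self.make_stats(list(perm))) == base


def _candidate_fixture_pairs(f):
    g = f.graph
    return [p for p in f.pairs if g.neighbors(p[0]) & g.neighbors(p[1])]


class TestEnumerationConsistency:
    """Sampled moments against exhaustive state-space enumeration."""

    @pytest.mark.parametrize(
        "fixture",
        [
            f for f in fixture_enumerations()
            if f.num_states > 1 and _candidate_fixture_pairs(f)
        ],
        ids=lambda f: f.name,
    )
    def test_sampled_moments_match_enumeration(self, fixture):
        g = fixture.graph
        pairs = _candidate_fixture_pairs(fixture)
        s = 2000
        cfg = SamplerConfig(num_samples=s, spacing_attempts=20 * g.num_edges, seed=5)
        st = accumulate(g, pairs, cfg)
        for i, pair in enumerate(st.pairs):
            mu = fixture.exact_mean(pair)
            sigma = fixture.exact_sd(pair)
            se_mean = sigma / math.sqrt(s)
            if sigma == 0:
                assert st.mean()[i] == mu and st.sd()[i] == 0.0
            else:
                assert abs(st.mean()[i] - mu) <= max(4 * se_mean, 1e-12)
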