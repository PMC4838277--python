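# Methods

## Problem and containers

The link-assessment problem: given an undirected simple graph G = (V, E)
— unipartite, or bipartite with a left/right partition — and a ground
truth E_GT of validated same-side pairs, rank node pairs so ground-truth
pairs come first. Only *candidate pairs* (unordered same-side pairs with
n(v, w) ≥ 1 common neighbors) are scored; a pair sharing no neighbor
carries no structural evidence and is unrankable by construction. Node
identifiers are opaque strings and the canonical order of a pair is
lexicographic, which fixes every tie-break and makes all outputs
deterministic. Ground-truth pairs whose endpoints are missing from the
graph are dropped with a logged count when read from disk (they can occur
legitimately: in rating networks the ground truth is disjoint from the
observed edges, and nodes may be absent altogether).

## Similarity measures

The eight classic measures are functions of n(v, w), the degrees, and a
population size M. Conventions fixed here:

* **M** is |V| for unipartite graphs — the measures are implemented as
  conventionally printed, including counting v and w themselves in the
  population — and the size of the *opposite* side for bipartite graphs,
  because the shared neighbors of a same-side pair live entirely in the
  opposite partition. M is recorded in the score-table metadata.
* **Pearson** is the population φ-coefficient of the binary adjacency
  vectors over the M positions, equivalently
  (nM − d(v)d(w)) / √(d(v)(M−d(v)) d(w)(M−d(w))). It is undefined (NaN)
  when a vector is constant (d = 0 or d = M); undefined values sort below
  every defined value in any ranking — unrankable evidence must not
  outrank evidence.
* **Adamic–Adar** uses the natural logarithm. Any fixed base is a uniform
  rescaling and leaves rankings unchanged. The sum is always finite: a
  common neighbor of a candidate pair is adjacent to both endpoints, so
  d(u) ≥ 2.
* **hypergeom** is the upper tail P[X ≥ n] for
  X ~ Hypergeometric(M, d(v), d(w)), computed through scipy's stable
  survival function; the test suite cross-checks it against exact
  rational summation for every M ≤ 30. Smaller values are stronger, and
  the evaluation layer keeps an explicit per-measure direction registry
  (`hypergeom` and `p_emp` ascend, everything else descends) because a
  silently inverted p-value is the most likely implementation bug in this
  area.

## The FDSM sampler and z*

The fixed degree sequence model is the uniform distribution over all
simple graphs with the observed degree sequence (and bipartition).
Sampling uses a Markov chain of degree-preserving edge swaps: two edges
are drawn uniformly at random; the unipartite move rewires
(a,b),(c,d) → (a,d),(c,b) with a uniformly chosen orientation of the
second edge, the bipartite move is the checkerboard swap
(a,x),(b,y) → (a,y),(b,x). A proposal that would create a self-edge or a
duplicate edge is rejected *but still consumes an attempt* — the lazy
chain has a symmetric proposal kernel and therefore a uniform stationary
distribution. For undirected simple graphs the plain swap chain is
irreducible for every degree sequence, so no auxiliary move is needed;
the test suite nevertheless gates this empirically with chi-square
uniformity tests against exhaustively enumerated state spaces.

Defaults, all configurable in `SamplerConfig`: S = 1000 samples, burn-in
100·|E| attempts, spacing 5·|E| attempts between samples, following
common swap-chain practice; settings are echoed in output metadata. All
randomness comes from one seeded numpy PCG64 generator; random numbers
are pre-drawn in blocks and fed to a numba-jitted kernel, so identical
seed and input give a bit-identical sample sequence.

Per candidate pair the accumulator streams Σn, Σn², and the count of
samples with n_sample ≥ n_observed — O(#pairs) memory independent of S.
Derived statistics:

* z = (n − ⟨n⟩)/σ[n] with σ the **sample** deviation (divisor S−1). When
  σ = 0 the convention is z = 0 if n = ⟨n⟩ and ±∞ otherwise.
* empirical p = exceed_count / S, deliberately without a pseudo-count:
  p = 0 is allowed and meaningful, because the z* tie-break exists
  precisely to resolve pairs whose p-value saturates below the Monte
  Carlo resolution 1/S.
* **z\***: sort by p ascending, break ties by z descending, break double
  ties by canonical pair order.

## Evaluation

* `rank_global` + `ppv_at_k`: PPV over the top k, default k = t. With
  k = t this equals the recall TP/t. Ground-truth pairs that are not
  candidate pairs cannot appear in any top-k and thus count against the
  measure; they are reported as `n_gt_uncovered`.
* `auc`: Mann–Whitney rank probability with average ranks (ties = 1/2);
  ground-truth pairs without a score are excluded (no comparison exists)
  and logged. A globally optimal table gives PPV_t = AUC = 1 and, as a
  consequence asserted constructively in the tests, a perfect local
  assessment too.
* `evaluate_llap`: each node v with t(v) ≥ 1 selects its top t(v)
  candidate partners. The default aggregation is **micro**: total
  ground-truth selections over total selections, each selection counted
  from its anchor node (a ground-truth pair may be counted from both
  endpoints). Macro averaging (mean over anchors of hits/t(v)) is also
  implemented; micro is the default because a single pooled PPV per data
  set is reported.

## Synthetic benchmarks

`generate(BenchmarkSpec)` plants group structure analogous to movie
series in rating data: each group of left nodes shares a dedicated
audience of right nodes (membership edges with probability `p_within`),
and every left node additionally attaches to each of
`n_background_nodes` background right nodes with probability
`p_background`, uniformly — no preferential attachment, so the degree
correction of the FDSM is the mechanism under test rather than a
confound; heterogeneous degrees can be induced explicitly with per-group
audience-size overrides. The unipartite mode is the same construction
with the audience embedded in the single node set. Ground truth =
within-group pairs. Defaults (10 groups × 5, audience 20, p_within 0.9,
p_background 0.01, 200 background nodes) give a strongly planted signal:
within-group pairs share ≈ 16 of 20 dedicated neighbors while cross-group
pairs share only occasional background raters.

What the generator does *not* emulate: the heavy-tailed degree
distributions, rating-threshold effects and correlated user behavior of
real rating or interaction data, nor ground truths that are orders of
magnitude sparser than the candidate set. Passing the planted-recovery
tests therefore shows the pipeline is correct and self-consistent, not
that z* will dominate on any particular real data set.

`fixture_enumerations()` exhaustively enumerates all simple graphs for a
catalog of tiny degree sequences (2–12 states each) with exact per-pair
⟨n⟩, σ[n], central moments and tail probabilities; it is the independent
oracle behind the sampler tests. Sequences with more than 10⁵ states are
refused.

## Numerical and testing choices

* Score TSVs store floats via `repr` (17 significant digits) so a
  write→read round trip is exact; `#` header lines carry the metadata
  needed to reproduce the file.
* Sampler consistency tests compare S = 10,000 estimates against exact
  enumerated values within 3 Monte-Carlo standard errors, with the SE of
  the sample deviation computed from the exact fourth central moment;
  these tests use spacing 20·|E| so consecutive samples are effectively
  independent, while the pipeline default (5·|E|) favors throughput.
* Uniformity tests draw 100,000 samples per fixture and require
  chi-square goodness-of-fit p > 0.001 against the uniform distribution
  over enumerated states.
* The planted-recovery check (10 replicate seeds, S = 1000) requires the
  z* global PPV_t to average ≥ 0.9 and the local PPV to be at least the
  global one; problem sizes (≈ 330 nodes, ≈ 1000 edges, ≈ 120 candidate
  pairs) were chosen so the whole suite runs in minutes on one CPU.

## Limitations

* The swap chain's mixing is assessed only on enumerable fixtures;
  burn-in/spacing defaults are heuristics, and strongly constrained
  degree sequences (near-complete graphs) mix slowly.
* Exact FDSM moments are only available by enumeration at toy scale;
  everything else is Monte Carlo with resolution 1/S in p.
* Dense adjacency matrices inside the sampler are quadratic in node
  count; the implementation targets networks up to a few thousand nodes,
  not web-scale graphs.
* Weighted, directed and multi-edge networks are out of scope, as is
  parsing raw primary-source formats; inputs are plain edge-list TSVs.
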