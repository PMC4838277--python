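"""Rank node pairs by z*: the degree-preserving null-model statistic.

Generates a small planted benchmark (4 movie groups of 3, each sharing a
dedicated audience, plus uniform background noise), samples 500 graphs
with the same degree sequence, and prints the top of the z* ranking:
empirical p-value ascending, ties broken by z-score descending.
"""

from linksig import BenchmarkSpec, SamplerConfig, generate, score_all
from linksig.fdsm import add_fdsm_scores, accumulate, z_star_ranking

spec = BenchmarkSpec(n_groups=4, group_size=3, audience_size=10,
                     p_within=0.9, p_background=0.05,
                     n_background_nodes=40, seed=7)
g, gt = generate(spec)
print(f"benchmark: |V|={g.num_nodes} |E|={g.num_edges}, planted pairs t={gt.t}")

table = score_all(g, [])
stats = add_fdsm_scores(table, g, SamplerConfig(num_samples=500, seed=1))

print("\ntop 8 pairs by z* (p ascending, z descending):")
for entry in z_star_ranking(stats)[:8]:
    planted = "planted" if (entry.node_u, entry.node_v) in gt else "noise"
    print(f"  {entry.node_u}-{entry.node_v}  p={entry.p_emp:.3f}  "
          f"z={entry.z:6.2f}  [{planted}]")
print("\nPairs whose shared audience cannot be explained by their degrees")
print("alone get p=0; the z-score then separates them further.")
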