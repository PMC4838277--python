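"""Score all candidate pairs of a small rating network.

Builds a bipartite graph of 4 movies and 5 users, then computes the
eight classic structural-similarity measures for every movie pair that
shares at least one rater. Movies m1/m2 share two raters, m3/m4 only
one, so m1-m2 scores higher on every measure.
"""

from linksig import Graph, score_all

side = {f"m{i}": "left" for i in range(1, 5)} | {f"u{j}": "right" for j in range(1, 6)}
edges = [
    ("m1", "u1"), ("m1", "u2"), ("m2", "u1"), ("m2", "u2"),
    ("m3", "u3"), ("m3", "u4"), ("m4", "u4"), ("m4", "u5"),
]
g = Graph(edges, mode="bipartite", side=side)

table = score_all(g)  # ranked side defaults to "left" (the movies)
print(table.df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print()
print("Each row is one movie pair with >= 1 shared rater; jaccard/cosine")
print("are overlap fractions, hypergeom is a p-value (smaller = stronger).")
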