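"""Collaborative-filtering densification on the 5-protein / 4-domain toy network.

Builds the small bipartite network p1={d1,d2}, p2={d1,d3}, p3={d2},
p4={d3,d4}, p5={d4}, runs the protein-side recommendation step and prints
the quantities that drive each new edge.
"""

import numpy as np

from essrank import cf, toy_pdi

pdi, expected = toy_pdi()
print("adjacency (proteins x domains):")
print(pdi.adjacency)

sm = cf.similarity(pdi.adjacency)
rm = cf.recommend_matrix(sm, pdi.adjacency)
std = cf.recommendation_standard(rm)

print("\nprotein-protein similarity (cosine of annotation profiles):")
print(np.round(sm, 4))
print("\nrecommendation matrix (similarity-weighted votes per domain):")
print(np.round(rm, 4))
print("\nper-domain recommendation standard (column means):", np.round(std, 4))

# an unannotated (protein, domain) cell becomes a new edge when its
# recommendation score strictly exceeds the domain's standard
print(f"\nRM(p3,d1) = {rm[2, 0]:.4f} > Std(d1) = {std[0]:.4f} "
      f"-> recommend p3 to d1")
print(f"RM(p4,d1) = {rm[3, 0]:.4f} > Std(d1) = {std[0]:.4f} "
      f"-> recommend p4 to d1")

res = cf.run_cf(pdi)
added = sorted(
    (pdi.proteins[i], pdi.domains[j])
    for i, j in zip(*np.nonzero(res.mrm != pdi.adjacency))
)
print("\nedges added by the two-sided pass (union of both directions):", added)
print("the densified network keeps every original edge:",
      bool((res.mrm >= pdi.adjacency).all()))
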