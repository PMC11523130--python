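"""Beta diversity: Bray-Curtis distances, PCoA, and ANOSIM.

Simulates two community structures (treatment-structured vs null),
ordinates each by principal coordinate analysis of the Bray-Curtis
matrix, and tests group separation with ANOSIM.  R near 1 means
between-treatment dissimilarities dominate within-treatment ones;
R near 0 means no separation.
"""

from mycodiv import anosim, bray_curtis, default_truth, gen_community, pcoa

for label, effect in [("treatment-structured", 1.0), ("null", 0.0)]:
    truth = default_truth(n_features=200, depth=4000, effect=effect, seed=7)
    table, meta = gen_community(truth, reps=3, seed=8)
    dm = bray_curtis(table)
    ordination = pcoa(dm)
    res = anosim(dm, meta, permutations=999, seed=9)
    pc1, pc2 = ordination.proportion_explained[:2] * 100
    print(f"{label} communities:")
    print(f"  PCoA axis 1 explains {pc1:.1f}%, axis 2 {pc2:.1f}% "
          "of positive eigenvalue sum")
    print(f"  ANOSIM R = {res.r:.3f}, p = {res.p_value:.3f} "
          f"({res.permutations} permutations)\n")
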