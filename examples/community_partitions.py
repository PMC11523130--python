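"""Shared/unique feature partitions, taxonomic collapse, rarefaction.

Simulates a study, maps treatments onto management supersets (farmer
practice vs conservation agriculture), and prints the Venn partition of
feature presence, a phylum-level abundance table, and the expected
rarefaction curve for one sample (expected richness at subsampled read
depths; saturation indicates adequate sequencing depth).
"""

import numpy as np

from mycodiv import (
    TaxonomyMap,
    collapse_taxonomy,
    default_truth,
    filter_low_count,
    gen_community,
    rarefaction_curve,
    relative_abundance,
    venn_partition,
)

truth = default_truth(n_features=150, depth=3000, effect=1.2, seed=3)
table, meta = gen_community(truth, reps=3, seed=4)
filtered = filter_low_count(table, 4)

grouping = {"T1": "FP", "T2": "FP", "T3": "pCA", "T4": "CA",
            "T5": "pCA", "T6": "CA", "T7": "CA"}
venn = venn_partition(filtered, meta, grouping=grouping)
print("Feature presence partition across management supersets:")
for labels, size in sorted(venn.sizes().items(),
                           key=lambda kv: (len(kv[0]), sorted(kv[0]))):
    print(f"  {'&'.join(sorted(labels)):>12s}: {size} features")

phyla = ["Ascomycota", "Basidiomycota", "Mortierellomycota", "Mucoromycota"]
rng = np.random.default_rng(5)
tax = TaxonomyMap({fid: ("Fungi", rng.choice(phyla))
                   for fid in filtered.feature_ids[::2]})  # half unmapped
rel = relative_abundance(filtered)
collapsed = collapse_taxonomy(rel, tax, "phylum")
print("\nPhylum-level mean relative abundance (%):")
print((collapsed.data.mean(axis=1) * 100).round(2).to_string())

sample = filtered.data.iloc[:, 0]
depths = [10, 100, 500, 1000, 2000, int(sample.sum())]
curve = rarefaction_curve(sample.to_numpy(), depths)
print(f"\nExpected richness for sample {filtered.sample_ids[0]} by depth:")
for d, s in zip(depths, curve):
    print(f"  depth {d:>5d}: {s:7.2f} taxa")
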