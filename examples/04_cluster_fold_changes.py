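"""UPGMA clustering of fold-change profiles with Pearson distance.

Patients are clustered by their fold-change profiles over the selected
miRNAs (d = 1 - Pearson r, average linkage), and the miRNAs by their
behavior across patients. The tree is ultrametric; cutting it at k = 3
reports the three main co-regulation groups.
"""

import mirpair as mp

params = mp.SimParams(seed=1)
ct, cohort, truth = mp.generate_paired_cohort(params)
detection = mp.call_detection(ct)
fc = mp.paired_fold_changes(mp.delta_ct(ct), cohort)
expressed = [m for m in mp.filter_expressed(detection, 2) if m in fc.log2fc.index]
selected = mp.select_significant(mp.differential_screen(fc, expressed=expressed))

block = fc.log2fc.loc[selected.index].dropna(axis=0, how="any")

# patients clustered by fold-change profile
tree = mp.upgma(mp.pearson_distance(block.T))
print("patient clusters (k = 3):")
labels = tree.cut(3)
for label in sorted(labels.unique()):
    members = sorted(labels.index[labels == label])
    print(f"  {label}: {', '.join(members)}")
print(f"merge heights range: {tree.heights[0]:.3f} .. {tree.heights[-1]:.3f}")

# miRNAs clustered across patients; the Newick string can feed any tree viewer
mirna_tree = mp.upgma(mp.pearson_distance(block))
print(f"\nmiRNA tree over {mirna_tree.n_leaves} selected miRNAs (Newick):")
print(mirna_tree.to_newick()[:120] + "...")
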