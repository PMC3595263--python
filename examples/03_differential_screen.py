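"""The paired differential screen: filter, paired t-test, selection.

miRNAs detected in at least two samples are tested with a paired t-test on
the per-patient log2 fold changes; miRNAs with two-sided p < 0.05 are
selected (uncorrected, as in a discovery screen; a Benjamini-Hochberg column
is carried along for reference).
"""

import mirpair as mp

params = mp.SimParams(seed=1)
ct, cohort, truth = mp.generate_paired_cohort(params)

detection = mp.call_detection(ct)
fc = mp.paired_fold_changes(mp.delta_ct(ct), cohort)
expressed = [m for m in mp.filter_expressed(detection, min_samples=2)
             if m in fc.log2fc.index]
print(f"{len(expressed)} of {params.n_mirnas} miRNAs expressed in >=2 samples")

table = mp.differential_screen(fc, expressed=expressed)
selected = mp.select_significant(table, alpha=0.05)
print(f"{len(table)} tested, {len(selected)} selected at p < 0.05")

hits = set(selected.index) & set(truth.index)
print(f"planted miRNAs recovered: {len(hits)} of {len(truth)}")

print("\ntop of the selection (mean fold change +/- s.e.m.):")
cols = ["n_pairs", "mean_fc", "sem_fc", "mean_log2fc", "t", "p", "direction"]
print(selected[cols].head(8).round(4).to_string())
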