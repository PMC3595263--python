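"""Generate a synthetic paired tumor cohort with planted fold changes.

Builds the default study-scale cohort: 9 patients, each with one primary and
one metastatic sample, 377 miRNA assays plus a U6 snRNA reference well, and
17 miRNAs planted with real metastasis-vs-primary log2 fold changes (three of
them down-regulated). Wells whose latent Ct drifts past the dropout cutoff
are undetected, so roughly half the assays behave like unexpressed miRNAs.
"""

import mirpair as mp

params = mp.SimParams(seed=1)
ct, cohort, truth = mp.generate_paired_cohort(params)

print(f"cohort: {len(cohort.patients)} patients, {len(ct.samples)} samples")
print(f"assays: {len(ct.assays)} (reference: {ct.reference_assay})")
undetected = int(ct.undetected.to_numpy().sum())
print(f"undetected wells: {undetected} of {ct.ct.size}")
print("\nplanted truth (log2 fold change, metastasis vs primary):")
print(truth.round(2).to_string())

# The truth table is what downstream stages should recover: positive values
# are miRNAs up-regulated in the omental lesion, negative ones down-regulated.
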