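"""Differential analysis of labeled eluates across culture models.

Spikes 10% of human proteins with a known log2 fold change of 3 between
the two culture models, runs the cross-model workflow (normalize, log2,
QRILC imputation of left-censored zeros, Welch t-test, permutation-FDR
q-values, volcano categories) and reports how much of the spiked truth
was recovered.
"""

from newsecm import LfqSimConfig, run_search1_cross_model, simulate_lfq

cfg = LfqSimConfig(n_proteins_human=800, n_proteins_rat=0,
                   n_samples_per_group=5, within_protein_sd=0.5,
                   frac_true_differential=0.1, true_log2fc=3.0,
                   differential_axis="model", censor_quantile=0.2, seed=7)
matrix, truth = simulate_lfq(cfg)
res = run_search1_cross_model(matrix, seed=7)

print("volcano partition:", res.venn)
spiked = set(truth.proteins.accession[truth.proteins.is_differential])
hits = set(res.table.index[res.table["category"] == "high_in_dECM-tumor"])
print(f"recall of spiked proteins: {len(hits & spiked) / len(spiked):.2f}")
print("\ntop proteins by q-value:")
cols = ["log2FC", "FC", "t", "p", "q", "category"]
print(res.table.nsmallest(5, "q")[cols].round(4).to_string())
# a recall near 1 with few false calls means the imputation + permutation
# FDR pipeline recovers the planted effects at the stated thresholds
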