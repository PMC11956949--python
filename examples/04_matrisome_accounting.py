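"""Matrisome category accounting for input vs eluate fractions.

Annotates simulated proteins against a synthetic matrisome lookup and
summarizes, per category, protein-group counts and intensity
proportions in each fraction, with eluate-vs-input differences.
A real matrisome CSV (columns gene, division, category) can be loaded
with MatrisomeAnnotation.from_csv and used identically.
"""

import pandas as pd

from newsecm import (LfqSimConfig, category_summary, make_matrisome_fixture,
                     simulate_lfq)

ann = make_matrisome_fixture(5)  # 30 synthetic matrisome genes
matrix, _ = simulate_lfq(LfqSimConfig(n_proteins_human=60, n_proteins_rat=0,
                                      n_samples_per_group=3, seed=2))
# adopt matrisome symbols for half the simulated proteins
genes = list(ann.table.index) + list(matrix.proteins["gene"][30:])
matrix.proteins["gene"] = genes

summary = category_summary(matrix.select_samples(fraction="input"),
                           matrix.select_samples(fraction="eluate"), ann)
cols = ["input_count", "eluate_count", "count_difference", "intensity_ratio"]
print(summary[cols].round(2).to_string())
# count_difference > 0 means more protein groups of that category were
# identified in the enriched eluate than in the bulk input
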