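"""The two custom azido-glycan modification masses for the open search.

The GalNAz glycan residue (C8H12N4O5) modifies Ser/Thr; after CuAAC
click with alkyne-PEG4-desthiobiotin (C21H37N3O6) the full adduct
remains on the peptide. CuAAC conserves every atom, so the clicked
composition is the element-wise sum.
"""

from newsecm import modification_specs

for spec in modification_specs():
    print(spec.to_text())
# the two monoisotopic delta masses (244.0808 and 671.3490 Da) are what
# the search engine needs as custom modifications on S/T
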