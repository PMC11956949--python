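"""Matrisome annotation and per-category accounting.

The matrisome is the curated inventory of extracellular-matrix and
ECM-associated proteins. It is organized in two divisions — the core
matrisome (collagens, ECM glycoproteins, proteoglycans) and
matrisome-associated proteins (ECM regulators, ECM-affiliated proteins,
secreted factors). Annotation is by gene symbol, case-insensitively;
anything not in the lookup is "non-matrisome".

The category summary compares the input (bulk ECM) and eluate (newly
synthesized, enriched ECM) fractions: per category it counts identified
protein groups, sums intensities, and reports eluate-minus-input count
differences and eluate/input intensity ratios. A protein counts as
"identified" in a fraction when it has at least one nonzero intensity
there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

__all__ = ["CORE_CATEGORIES", "ASSOCIATED_CATEGORIES", "CATEGORY_DIVISION",
           "MatrisomeAnnotation", "annotate_matrisome", "category_summary"]

CORE_CATEGORIES = ("collagens", "ECM glycoproteins", "proteoglycans")
ASSOCIATED_CATEGORIES = ("ECM regulators", "ECM-affiliated proteins",
                         "secreted factors")
CATEGORY_DIVISION = {
    **{c: "core matrisome" for c in CORE_CATEGORIES},
    **{c: "matrisome-associated" for c in ASSOCIATED_CATEGORIES},
}
NON_MATRISOME = "non-matrisome"


@dataclass
class MatrisomeAnnotation:
    """Gene symbol -> (division, category) lookup.

    Gene symbols are stored upper-cased; lookups are case-insensitive.
    """

    table: pd.DataFrame  # index: gene (upper); columns: division, category

    def __post_init__(self) -> None:
        t = self.table.copy()
        t.index = t.index.astype(str).str.upper()
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate genes in matrisome annotation: {dups[:5]}")
        bad = set(t["category"]) - set(CATEGORY_DIVISION)
        if bad:
            raise ValueError(f"unknown matrisome categories: {sorted(bad)}")
        expected = t["category"].map(CATEGORY_DIVISION)
        wrong = t.index[t["division"] != expected]
        if len(wrong):
            raise ValueError(
                f"division inconsistent with category for: {list(wrong)[:5]}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path) -> "MatrisomeAnnotation":
        """Load from a CSV with columns gene, division, category."""
        df = pd.read_csv(path)
        return cls(df.set_index("gene")[["division", "category"]])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path)


def annotate_matrisome(genes, annotation: MatrisomeAnnotation) -> pd.DataFrame:
    """Per-gene matrisome category and division (or non-matrisome).

    Matching is exact on the upper-cased symbol.
    """
    genes = pd.Series(genes).astype(str)
    upper = genes.str.upper()
    cat = upper.map(annotation.table["category"]).fillna(NON_MATRISOME)
    div = upper.map(annotation.table["division"]).fillna(NON_MATRISOME)
    return pd.DataFrame({"gene": genes.to_numpy(), "category": cat.to_numpy(),
                         "division": div.to_numpy()})


def _fraction_stats(matrix: IntensityMatrix, categories: pd.Series) -> pd.DataFrame:
    identified = (matrix.values > 0).any(axis=1)
    totals = matrix.values.sum(axis=1)
    df = pd.DataFrame({"category": categories.to_numpy(),
                       "identified": identified.to_numpy(),
                       "total": totals.to_numpy()})
    agg = df.groupby("category").agg(count=("identified", "sum"),
                                     intensity=("total", "sum"))
    return agg


def category_summary(input_matrix: IntensityMatrix,
                     eluate_matrix: IntensityMatrix,
                     annotation: MatrisomeAnnotation) -> pd.DataFrame:
    """Matrisome category accounting for input vs eluate fractions.

    Returns one row per category (the six matrisome categories plus
    non-matrisome) with protein-group counts, summed intensities,
    intensity proportions of all identified proteins in the fraction,
    the eluate-minus-input count difference, and the eluate/input
    intensity ratio (NaN when the input intensity is zero).
    """
    order = list(CORE_CATEGORIES) + list(ASSOCIATED_CATEGORIES) + [NON_MATRISOME]
    parts = {}
    for name, m in (("input", input_matrix), ("eluate", eluate_matrix)):
        cats = annotate_matrisome(m.proteins["gene"], annotation)["category"]
        cats.index = m.proteins.index
        parts[name] = _fraction_stats(m, cats).reindex(order).fillna(0.0)
    out = pd.DataFrame(index=pd.Index(order, name="category"))
    for name, agg in parts.items():
        out[f"{name}_count"] = agg["count"].astype(int)
        out[f"{name}_intensity"] = agg["intensity"]
        tot = agg["intensity"].sum()
        out[f"{name}_proportion"] = agg["intensity"] / tot if tot > 0 else np.nan
    out["count_difference"] = out["eluate_count"] - out["input_count"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["eluate_intensity"] / out["input_intensity"]
    out["intensity_ratio"] = ratio.where(out["input_intensity"] > 0)
    out["division"] = [CATEGORY_DIVISION.get(c, NON_MATRISOME) for c in out.index]
    return out
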