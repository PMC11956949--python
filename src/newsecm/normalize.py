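"""Sum normalization of LFQ intensities and species-level summaries.

Each sample's intensities are rescaled so that its total over a chosen
protein subset equals the average such total across the samples
normalized together (one *scope*):

    X_normalized = X_original * Sum_average / Sum_sample

Three scope conventions are used by the pipeline: per-treatment-group
scopes summing human proteins (within-model eluate comparison), one
scope over all labeled eluates summing human proteins (cross-model
comparison), and one scope over all input samples summing human and rat
proteins together.

The species summary compares total human vs rat intensity between the
paired input and eluate fractions on the *original* (un-normalized)
scale, expressing the eluate-vs-input difference as a percent change —
the selectivity readout for the bioorthogonal enrichment.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix, NormalizedMatrix

__all__ = ["sum_normalize", "species_intensity_summary"]


def _resolve_subset(matrix: IntensityMatrix, summed_subset) -> pd.Index:
    """Protein accessions over which per-sample sums are taken."""
    if summed_subset is None or summed_subset == "all":
        return matrix.proteins.index
    if isinstance(summed_subset, str):
        keep = matrix.proteins["organism"] == summed_subset
        if not keep.any():
            raise ValueError(f"no proteins with organism {summed_subset!r}")
        return matrix.proteins.index[keep]
    idx = pd.Index(list(summed_subset))
    missing = idx.difference(matrix.proteins.index)
    if len(missing):
        raise ValueError(f"unknown accessions in summed subset: {list(missing)[:5]}")
    return idx


def _resolve_scopes(matrix: IntensityMatrix, scope) -> dict[str, list[str]]:
    """Map the scope argument -> {scope name: [sample ids]}, each sample once."""
    if scope is None or scope == "all":
        return {"all": list(matrix.samples.index)}
    if isinstance(scope, str):
        if scope not in matrix.samples.columns:
            raise ValueError(f"unknown sample metadata column {scope!r}")
        groups = matrix.samples.groupby(scope, sort=True).groups
        return {str(k): list(v) for k, v in groups.items()}
    if isinstance(scope, Mapping):
        out = {str(k): list(v) for k, v in scope.items()}
    else:  # sequence of sample-id groups
        out = {f"scope{i}": list(g) for i, g in enumerate(scope)}
    seen: set[str] = set()
    for name, ids in out.items():
        unknown = set(ids) - set(matrix.samples.index)
        if unknown:
            raise ValueError(f"scope {name!r} names unknown samples: {sorted(unknown)}")
        dup = seen & set(ids)
        if dup:
            raise ValueError(f"samples in more than one scope: {sorted(dup)}")
        seen |= set(ids)
    return out


def sum_normalize(matrix: IntensityMatrix, scope="all",
                  summed_subset=None) -> NormalizedMatrix:
    """Scale each sample by Sum_average / Sum_sample within its scope.

    Parameters
    ----------
    matrix
        Raw intensities (zeros = not observed; they contribute 0 to
        sums and remain exactly 0 after scaling).
    scope
        ``"all"`` (every sample in one scope), the name of a sample
        metadata column (one scope per distinct value, e.g.
        ``"treatment"``), a mapping ``{name: [sample ids]}``, or a
        sequence of sample-id lists. Samples not named by an explicit
        scope are left untouched.
    summed_subset
        Proteins whose intensities are summed per sample: ``None``/
        ``"all"``, an organism tag (``"human"``/``"rat"``), or an
        iterable of accessions.

    Returns
    -------
    NormalizedMatrix
        Same shape; per-sample scale factors recorded. Within a scope
        every sample's subset total equals the scope's mean original
        total (relative tolerance ~1e-9 by construction).

    Raises
    ------
    ValueError
        If any sample in a scope has a zero total over the subset.
    """
    subset = _resolve_subset(matrix, summed_subset)
    scopes = _resolve_scopes(matrix, scope)
    values = matrix.values.copy()
    factors = pd.Series(1.0, index=matrix.samples.index)
    scope_info: dict[str, dict] = {}
    for name, ids in scopes.items():
        sums = matrix.values.loc[subset, ids].sum(axis=0)
        zero = sums.index[sums <= 0]
        if len(zero):
            raise ValueError(
                f"sample(s) {list(zero)} have zero total intensity over the "
                f"summed subset in scope {name!r}; cannot sum-normalize")
        avg = sums.mean()
        f = avg / sums
        values[ids] = values[ids].mul(f, axis=1)
        factors[ids] = f
        scope_info[name] = {"samples": list(ids), "sum_average": float(avg),
                            "summed_subset_size": int(len(subset))}
    return NormalizedMatrix(values, matrix.proteins.copy(), matrix.samples.copy(),
                            scale_factors=factors, scopes=scope_info)


def species_intensity_summary(input_matrix: IntensityMatrix,
                              eluate_matrix: IntensityMatrix) -> pd.DataFrame:
    """Total intensity per organism in input vs eluate, with % change.

    Relative change = (eluate_total - input_total) / input_total * 100.
    An organism absent from the input (total 0) has an undefined change,
    reported as NaN. Operates on the matrices as given — the selectivity
    readout uses original, un-normalized values.
    """
    for m in (input_matrix, eluate_matrix):
        if "organism" not in m.proteins.columns or m.proteins["organism"].isna().any():
            raise ValueError("organism tags are required on both matrices")
    orgs = sorted(set(input_matrix.proteins["organism"])
                  | set(eluate_matrix.proteins["organism"]))
    rows = []
    for org in orgs:
        i_tot = float(input_matrix.values
                      [input_matrix.proteins["organism"] == org].sum().sum())
        e_tot = float(eluate_matrix.values
                      [eluate_matrix.proteins["organism"] == org].sum().sum())
        change = (e_tot - i_tot) / i_tot * 100.0 if i_tot > 0 else np.nan
        rows.append({"organism": org, "input_total": i_tot,
                     "eluate_total": e_tot, "percent_change": change})
    return pd.DataFrame(rows).set_index("organism")
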