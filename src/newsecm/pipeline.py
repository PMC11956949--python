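"""End-to-end orchestration of the three search workflows.

The upstream database search quantified 36 runs (18 input lysates, 18
streptavidin eluates) three ways, and each downstream comparison has its
own normalization scope and statistical route:

* **Search 1, within-model** — labeled (GalNAz) vs vehicle eluates of
  one culture model: sum-normalize per treatment group over human
  proteins, pre-filter (>= 2 nonzero per group), log2, Welch t-test +
  permutation FDR on complete cases, volcano categories. Proteins that
  fail the filter are reported separately by group mean intensity.
* **Search 1, cross-model** — labeled eluates of dECM-tumor vs
  tumoroid: sum-normalize all together over human proteins, log2, QRILC
  imputation, Welch + permutation FDR, volcano categories.
* **Search 2, species selectivity** — original (un-normalized) human
  vs rat total intensities, eluate vs input.
* **Search 3, inputs** — all input samples sum-normalized together over
  human and rat proteins; the normalized table feeds annotation.

Every run function is deterministic given its seed, and the run report
records the parameters and seed that produced each output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute import delog, log2_transform, prefilter_min_nonzero, qrilc_impute
from .matrix import IntensityMatrix, NormalizedMatrix
from .normalize import species_intensity_summary, sum_normalize
from .stats import (PermutationPlan, classify_volcano, grubbs_outlier,
                    permutation_fdr, sample_correlation)

__all__ = ["DifferentialResult", "run_search1_within_model",
           "run_search1_cross_model", "run_search2_species",
           "run_search3_inputs", "sample_qc", "report", "report_markdown"]


@dataclass
class DifferentialResult:
    """A differential table plus its volcano partition and audit info."""

    table: pd.DataFrame
    venn: dict
    labels: tuple[str, str]
    excluded: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "Accession"
        out.to_csv(path, sep="\t")


def _differential_table(logvalues: pd.DataFrame, proteins: pd.DataFrame,
                        labels: pd.Series, label_a: str, label_b: str,
                        plan: PermutationPlan, fc_threshold: float,
                        q_threshold: float) -> pd.DataFrame:
    """Welch + permutation FDR + geometric-mean FCs on a complete matrix."""
    mask_a = (labels == label_a).to_numpy()
    stats = permutation_fdr(logvalues, np.where(mask_a, label_a, label_b), plan)
    mean_a = logvalues.loc[:, mask_a].mean(axis=1)
    mean_b = logvalues.loc[:, ~mask_a].mean(axis=1)
    log2fc = mean_a - mean_b
    table = pd.DataFrame({
        "gene": proteins.loc[logvalues.index, "gene"],
        "organism": proteins.loc[logvalues.index, "organism"],
        f"mean_log2_{label_a}": mean_a, f"mean_log2_{label_b}": mean_b,
        "log2FC": log2fc, "FC": 2.0 ** log2fc,
        "t": stats["t"], "df": stats["df"], "p": stats["p"], "q": stats["q"],
    })
    table["category"] = [
        classify_volcano(fc, q, fc_threshold, q_threshold,
                         label_a=f"high_in_{label_a}", label_b=f"high_in_{label_b}")
        for fc, q in zip(table["log2FC"], table["q"])]
    return table


def _venn(table: pd.DataFrame, label_a: str, label_b: str) -> dict:
    counts = table["category"].value_counts().to_dict()
    return {f"high_in_{label_a}": int(counts.get(f"high_in_{label_a}", 0)),
            f"high_in_{label_b}": int(counts.get(f"high_in_{label_b}", 0)),
            "NS": int(counts.get("NS", 0))}


def _group_mean_report(matrix: IntensityMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-group mean decimal intensities (for untestable proteins)."""
    out = {}
    for g in pd.unique(labels):
        cols = labels.index[labels == g]
        out[f"mean_{g}"] = matrix.values[cols].mean(axis=1)
    rep = pd.DataFrame(out, index=matrix.values.index)
    rep.insert(0, "gene", matrix.proteins["gene"])
    return rep


def run_search1_within_model(matrix: IntensityMatrix, model: str, *,
                             min_nonzero: int = 2, fc_threshold: float = 1.0,
                             q_threshold: float = 0.05,
                             plan: PermutationPlan | None = None,
                             seed: int | None = None) -> DifferentialResult:
    """Labeled vs vehicle eluates within one culture model.

    Raises if the matrix is empty or either treatment arm is missing.
    """
    if matrix.n_proteins == 0:
        raise ValueError("empty intensity matrix")
    sub = matrix.select_samples(model=model, fraction="eluate")
    present = set(sub.samples["treatment"])
    if not {"GalNAz", "vehicle"} <= present:
        raise ValueError(f"model {model!r} is missing a treatment arm "
                         f"(have {sorted(present)})")
    plan = plan or PermutationPlan(seed=seed)
    normed = sum_normalize(sub, scope="treatment", summed_subset="human")
    labels = normed.samples["treatment"]
    filtered = prefilter_min_nonzero(normed, labels, min_nonzero)
    logmat = log2_transform(filtered)
    complete = logmat.values.dropna()
    table = _differential_table(complete, filtered.proteins, labels,
                                "GalNAz", "vehicle", plan,
                                fc_threshold, q_threshold)
    excl_idx = normed.values.index.difference(complete.index)
    if len(excl_idx):
        untested = normed.select_proteins(accessions=excl_idx)
        excluded = _group_mean_report(untested, labels)
    else:
        excluded = pd.DataFrame(columns=["gene"])
    params = {"workflow": "search1_within_model", "model": model,
              "min_nonzero": min_nonzero, "fc_threshold": fc_threshold,
              "q_threshold": q_threshold, "seed": plan.seed,
              "n_permutations": plan.n_permutations, "s0": plan.s0}
    return DifferentialResult(table, _venn(table, "GalNAz", "vehicle"),
                              ("GalNAz", "vehicle"), excluded, params)


def run_search1_cross_model(matrix: IntensityMatrix, *,
                            fc_threshold: float = 1.0,
                            q_threshold: float = 0.05,
                            tune_sigma: float = 1.0,
                            plan: PermutationPlan | None = None,
                            seed: int | None = None) -> DifferentialResult:
    """Labeled eluates: dECM-tumor vs tumoroid, with QRILC imputation."""
    if matrix.n_proteins == 0:
        raise ValueError("empty intensity matrix")
    sub = matrix.select_samples(treatment="GalNAz", fraction="eluate")
    present = set(sub.samples["model"])
    if not {"dECM-tumor", "tumoroid"} <= present:
        raise ValueError(f"missing a model arm (have {sorted(present)})")
    plan = plan or PermutationPlan(seed=seed)
    normed = sum_normalize(sub, scope="all", summed_subset="human")
    logmat = log2_transform(normed)
    # drop proteins observed nowhere (all-zero rows carry no information)
    keep = ~logmat.values.isna().all(axis=1)
    logmat.values = logmat.values.loc[keep]
    imputed = qrilc_impute(logmat, tune_sigma=tune_sigma, seed=seed)
    labels = normed.samples["model"]
    table = _differential_table(imputed.values, normed.proteins, labels,
                                "dECM-tumor", "tumoroid", plan,
                                fc_threshold, q_threshold)
    params = {"workflow": "search1_cross_model", "tune_sigma": tune_sigma,
              "fc_threshold": fc_threshold, "q_threshold": q_threshold,
              "seed": seed, "n_permutations": plan.n_permutations,
              "s0": plan.s0}
    return DifferentialResult(table, _venn(table, "dECM-tumor", "tumoroid"),
                              ("dECM-tumor", "tumoroid"),
                              pd.DataFrame(columns=["gene"]), params)


def run_search2_species(matrix: IntensityMatrix,
                        model: str = "dECM-tumor") -> pd.DataFrame:
    """Species selectivity: original-value totals, eluate vs input."""
    inputs = matrix.select_samples(model=model, fraction="input")
    eluates = matrix.select_samples(model=model, fraction="eluate")
    if inputs.n_samples == 0 or eluates.n_samples == 0:
        raise ValueError(f"model {model!r} needs both input and eluate samples")
    return species_intensity_summary(inputs, eluates)


def run_search3_inputs(matrix: IntensityMatrix
                       ) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """All input samples normalized together over human + rat proteins."""
    inputs = matrix.select_samples(fraction="input")
    if inputs.n_samples == 0:
        raise ValueError("no input-fraction samples present")
    normed = sum_normalize(inputs, scope="all", summed_subset=None)
    summary = pd.DataFrame({
        "original_total": inputs.values.sum(axis=0),
        "normalized_total": normed.values.sum(axis=0),
        "scale_factor": normed.scale_factors})
    return normed, summary


def sample_qc(matrix: IntensityMatrix, alpha: float = 0.05) -> dict:
    """Advisory sample QC: pairwise correlation and a Grubbs screen.

    The Grubbs screen tests each sample's protein-identification count
    (nonzero entries) against the others; a flagged sample is reported,
    never removed — removal is an explicit caller decision.
    """
    logv = log2_transform(matrix).values
    r, p = sample_correlation(logv)
    id_counts = (matrix.values > 0).sum(axis=0)
    flagged = None
    if len(id_counts) >= 3 and id_counts.std(ddof=1) > 0:
        idx = grubbs_outlier(id_counts.to_numpy(), alpha)
        if idx is not None:
            flagged = str(id_counts.index[idx])
    return {"correlation_r": r, "correlation_p": p,
            "id_counts": id_counts, "grubbs_flagged_sample": flagged,
            "grubbs_alpha": alpha}


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def report(**results) -> dict:
    """Assemble a JSON-serializable run report from workflow outputs.

    Accepts keyword arguments ``search1_within``, ``search1_cross``
    (DifferentialResult), ``species`` (DataFrame), ``search3_summary``
    (DataFrame), ``matrisome_summary`` (DataFrame), ``qc`` (dict from
    :func:`sample_qc`). At least one must be given.
    """
    known = {"search1_within", "search1_cross", "species", "search3_summary",
             "matrisome_summary", "qc"}
    unknown = set(results) - known
    if unknown:
        raise ValueError(f"unknown report sections: {sorted(unknown)}")
    results = {k: v for k, v in results.items() if v is not None}
    if not results:
        raise ValueError("report needs at least one workflow output")
    out: dict = {}
    for key in ("search1_within", "search1_cross"):
        if key in results:
            res: DifferentialResult = results[key]
            out[key] = {"venn": res.venn, "params": _jsonable(res.params),
                        "n_tested": int(len(res.table)),
                        "n_excluded": int(len(res.excluded))}
    for key in ("species", "search3_summary", "matrisome_summary"):
        if key in results:
            out[key] = _jsonable(results[key])
    if "qc" in results:
        qc = results["qc"]
        out["qc"] = {"grubbs_flagged_sample": qc["grubbs_flagged_sample"],
                     "grubbs_alpha": qc["grubbs_alpha"],
                     "id_counts": _jsonable(qc["id_counts"]),
                     "min_pairwise_r": float(np.nanmin(
                         qc["correlation_r"].to_numpy()))}
    return out


def report_markdown(rep: dict) -> str:
    """Render the run report as readable markdown."""
    lines = ["# Run report", ""]
    for key, val in rep.items():
        lines.append(f"## {key}")
        if key in ("search1_within", "search1_cross"):
            lines.append(f"- proteins tested: {val['n_tested']} "
                         f"(excluded from testing: {val['n_excluded']})")
            for cat, n in val["venn"].items():
                lines.append(f"- {cat}: {n}")
            lines.append(f"- parameters: `{val['params']}`")
        else:
            lines.append("```json")
            lines.append(json.dumps(val, indent=2, default=str))
            lines.append("```")
        lines.append("")
    return "\n".join(lines)
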