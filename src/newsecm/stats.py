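"""Differential statistics for label-free proteomics.

Implements the statistical core of the pipeline: Welch's unequal-variance
t-test, SAM-style permutation-based FDR q-values, geometric-mean fold
changes, volcano categorization, pairwise sample Pearson correlation,
Grubbs's single-outlier test, the paired t-test, and one-way ANOVA with
Tukey HSD.

The permutation FDR reshuffles the two group labels (the same shuffle
applied to every protein), recomputes the Welch-style statistic, and for
each observed |t| threshold estimates

    FDR(threshold) = mean permuted count of |t*| >= threshold
                     --------------------------------------
                     observed count of |t| >= threshold

clipped to [0, 1]. A protein's q-value is the smallest FDR level at
which it is called significant: the minimum FDR over all proteins at or
beyond it in p-rank, which makes q monotone non-decreasing in p. When the number of distinct label assignments
is small the enumeration is exhaustive; otherwise a seeded random sample
of assignments is used. An optional SAM fudge factor s0 is added to the
denominator of the statistic (default 0).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PermutationPlan", "welch_t", "permutation_fdr",
           "geometric_fold_change", "classify_volcano", "sample_correlation",
           "grubbs_outlier", "grubbs_critical_value", "paired_t",
           "anova_tukey"]


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test (two-tailed).

    Returns ``(t, df, p)`` with
    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) and
    Welch–Satterthwaite degrees of freedom.

    Degenerate variance handling: if both groups have zero variance and
    equal means the statistic is 0 with p = 1 (warning); zero variance
    with unequal means leaves the statistic undefined and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn("both groups constant and equal; t = 0, p = 1")
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means: "
                         "Welch statistic undefined")
    sa, sb = va / a.size, vb / b.size
    se2 = sa + sb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class PermutationPlan:
    """How the null distribution of the test statistic is generated.

    n_permutations
        Number of random label reshuffles when the exhaustive
        enumeration is too large.
    exhaustive_limit
        Enumerate all C(n, n_a) distinct assignments when their count is
        at most this.
    s0
        SAM fudge factor added to the statistic's denominator.
    seed
        RNG seed for the random scheme (required there for
        reproducibility).
    use_median
        Use the median instead of the mean permuted exceedance count in
        the FDR numerator.
    """

    n_permutations: int = 250
    exhaustive_limit: int = 1000
    s0: float = 0.0
    seed: int | None = None
    use_median: bool = False

    @property
    def exhaustive(self) -> bool | None:
        # resolved per dataset: depends on group sizes
        return None


def _t_matrix(X: np.ndarray, ia: np.ndarray, ib: np.ndarray, s0: float) -> np.ndarray:
    """Welch-style statistic per row for one label assignment."""
    A, B = X[:, ia], X[:, ib]
    na, nb = A.shape[1], B.shape[1]
    se = np.sqrt(A.var(axis=1, ddof=1) / na + B.var(axis=1, ddof=1) / nb)
    return (A.mean(axis=1) - B.mean(axis=1)) / (se + s0)


def permutation_fdr(values, labels, plan: PermutationPlan | None = None
                    ) -> pd.DataFrame:
    """Per-protein q-values from label-reshuffling FDR estimation.

    Parameters
    ----------
    values
        Complete (no missing entries) proteins x samples matrix of log2
        intensities — a DataFrame or 2-D array.
    labels
        Group label per sample (exactly two distinct labels, each with
        >= 2 samples).
    plan
        Permutation scheme; defaults to :class:`PermutationPlan`.

    Returns
    -------
    DataFrame with columns ``t``, ``df``, ``p``, ``q`` (indexed like
    ``values`` if it is a DataFrame).
    """
    plan = plan or PermutationPlan()
    if isinstance(values, pd.DataFrame):
        index = values.index
        X = values.to_numpy(dtype=float)
    else:
        X = np.asarray(values, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute or drop first")
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    ia = np.flatnonzero(labels == uniq[0])
    ib = np.flatnonzero(labels == uniq[1])
    if ia.size < 2 or ib.size < 2:
        raise ValueError("each group needs at least 2 samples")
    n = ia.size + ib.size
    n_distinct = math.comb(n, ia.size)
    if n_distinct < 2:
        raise ValueError("fewer than 2 distinct label assignments possible")

    positions = np.concatenate([ia, ib])
    t_obs = _t_matrix(X, ia, ib, plan.s0)
    abs_obs = np.abs(t_obs)

    if n_distinct <= plan.exhaustive_limit:
        assignments = [np.array(c) for c in
                       itertools.combinations(positions.tolist(), ia.size)]
    else:
        if plan.seed is None:
            raise ValueError("random permutation scheme requires a seed")
        rng = np.random.default_rng(plan.seed)
        assignments = [rng.permutation(positions)[:ia.size]
                       for _ in range(plan.n_permutations)]
    perm_abs = np.empty((len(assignments), X.shape[0]))
    pos_set = set(positions.tolist())
    for k, ga in enumerate(assignments):
        gb = np.array(sorted(pos_set - set(np.asarray(ga).tolist())))
        perm_abs[k] = np.abs(_t_matrix(X, np.asarray(ga), gb, plan.s0))

    # observed count at threshold |t_i|: proteins with |t| >= |t_i| (ties inclusive)
    obs_count = abs_obs.size - np.searchsorted(np.sort(abs_obs), abs_obs, side="left")
    flat = np.sort(perm_abs.reshape(-1))
    exceed_total = flat.size - np.searchsorted(flat, abs_obs, side="left")
    if plan.use_median:
        per_perm = np.stack([
            p.size - np.searchsorted(np.sort(p), abs_obs, side="left")
            for p in perm_abs])
        perm_count = np.median(per_perm, axis=0)
    else:
        perm_count = exceed_total / len(assignments)
    fdr = np.clip(perm_count / obs_count, 0.0, 1.0)

    # per-protein Welch p for reporting (s0 does not enter p)
    df_num = (X[:, ia].var(axis=1, ddof=1) / ia.size
              + X[:, ib].var(axis=1, ddof=1) / ib.size)
    df = df_num ** 2 / (
        (X[:, ia].var(axis=1, ddof=1) / ia.size) ** 2 / (ia.size - 1)
        + (X[:, ib].var(axis=1, ddof=1) / ib.size) ** 2 / (ib.size - 1))
    t_plain = _t_matrix(X, ia, ib, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t_plain), df)

    # q_i = min FDR over proteins at or beyond i in p-rank
    # (enforces q monotone non-decreasing in p)
    p_order = np.argsort(p, kind="stable")
    q = np.empty_like(fdr)
    q[p_order] = np.minimum.accumulate(fdr[p_order][::-1])[::-1]
    return pd.DataFrame({"t": t_obs, "df": df, "p": p, "q": q}, index=index)


def geometric_fold_change(a, b) -> tuple[float, float]:
    """Fold change of geometric means and its log2.

    log2FC = mean(log2 a) - mean(log2 b); FC = 2**log2FC. All values
    must be strictly positive (run after imputation/back-transform).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("geometric fold change requires strictly positive values")
    log2fc = float(np.mean(np.log2(a)) - np.mean(np.log2(b)))
    return 2.0 ** log2fc, log2fc


def classify_volcano(log2fc: float, q: float, fc_threshold: float = 1.0,
                     q_threshold: float = 0.05, label_a: str = "high_in_A",
                     label_b: str = "high_in_B") -> str:
    """Volcano category with inclusive-boundary non-significance.

    ``high_in_A`` iff log2FC > fc_threshold and q < q_threshold;
    ``high_in_B`` iff log2FC < -fc_threshold and q < q_threshold;
    everything else — including exact boundary equality — is ``NS``.
    """
    if not (np.isfinite(log2fc) and np.isfinite(q)):
        raise ValueError("log2FC and q must be finite")
    if q < q_threshold and log2fc > fc_threshold:
        return label_a
    if q < q_threshold and log2fc < -fc_threshold:
        return label_b
    return "NS"


def sample_correlation(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and p) between samples, pairwise-complete.

    Rows with a missing value in either member of a pair are dropped for
    that pair; pairs with < 3 complete rows or a zero-variance member
    get NaN.
    """
    cols = list(values.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            sub = values[[ci, cj]].dropna()
            if len(sub) < 3 or sub[ci].std() == 0 or sub[cj].std() == 0:
                rij, pij = np.nan, np.nan
            else:
                res = sps.pearsonr(sub[ci], sub[cj])
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            p.loc[ci, cj] = p.loc[cj, ci] = pij
    return r, p


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha)."""
    tcrit = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(tcrit ** 2 / (n - 2 + tcrit ** 2))


def grubbs_outlier(values, alpha: float = 0.05) -> int | None:
    """Index of the single most extreme value if it is a Grubbs outlier.

    Two-sided test: G = max|x - mean| / sd compared against the
    t-distribution-based critical value. Returns None when no point
    exceeds the critical value, or when the sample is constant
    (warning).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs's test needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero standard deviation; no outlier definable")
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = dev[idx] / sd
    return idx if G > grubbs_critical_value(x.size, alpha) else None


def paired_t(a, b=None) -> tuple[float, float, float]:
    """Paired t-test: one-sample t on the differences, two-tailed.

    Call with two equal-length sequences, or a single sequence of
    differences. Identical pairs (all differences zero) give t = 0,
    p = 1 with a warning; constant nonzero differences leave the
    statistic undefined and raise.
    """
    if b is not None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
    else:
        d = np.asarray(a, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d[0] == 0:
            warnings.warn("all differences zero; t = 0, p = 1")
            return 0.0, float(d.size - 1), 1.0
        raise ValueError("constant nonzero differences: paired t undefined")
    t = d.mean() / (sd / math.sqrt(d.size))
    df = d.size - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def anova_tukey(groups) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey HSD pairwise comparisons (95% conf.).

    ``groups`` is a sequence of >= 3 value sets (or a mapping name ->
    values). Returns (F, p, pairwise table with columns group_a,
    group_b, mean_diff, p_adj).
    """
    if isinstance(groups, dict):
        names = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(data))]
    if len(data) < 3:
        raise ValueError("need at least 3 groups (use welch_t for two)")
    if any(g.size < 2 for g in data):
        raise ValueError("each group needs at least 2 values")
    F, p = sps.f_oneway(*data)
    tukey = sps.tukey_hsd(*data)
    rows = []
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            rows.append({"group_a": names[i], "group_b": names[j],
                         "mean_diff": float(data[i].mean() - data[j].mean()),
                         "p_adj": float(tukey.pvalue[i, j])})
    return float(F), float(p), pd.DataFrame(rows)
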