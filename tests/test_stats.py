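"""Differential statistics against independent oracles.

Hand-computed values come from the textbook formulas; scipy's
ttest_ind / ttest_rel / pearsonr serve as independent cross-checks of
the in-package implementations; the permutation FDR is compared with a
brute-force enumeration oracle.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from newsecm import (PermutationPlan, anova_tukey, classify_volcano,
                     geometric_fold_change, grubbs_outlier, paired_t,
                     permutation_fdr, sample_correlation, welch_t)
from newsecm.stats import grubbs_critical_value


class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = welch_t([10, 12, 14], [20, 22, 24])
        assert t == pytest.approx(-6.1237, abs=1e-4)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.00363, abs=5e-5)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 8))
            b = rng.normal(0.5, 2, rng.integers(2, 8))
            t, df, p = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_identical_groups_and_antisymmetry(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0
        t1, _, p1 = welch_t([1, 2, 4], [5, 6, 9])
        t2, _, p2 = welch_t([5, 6, 9], [1, 2, 4])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_variances(self):
        with pytest.warns(UserWarning):
            t, _, p = welch_t([2, 2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(ValueError, match="undefined"):
            welch_t([2, 2, 2], [3, 3, 3])

    def test_type_i_error_calibration(self):
        # 10^4 null replicates, 4 vs 4 standard normal, alpha = 0.05
        rng = np.random.default_rng(2024)
        n_rep = 10_000
        a = rng.normal(size=(n_rep, 4))
        b = rng.normal(size=(n_rep, 4))
        p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        # spot-check vectorized oracle against the package implementation
        for i in range(5):
            assert welch_t(a[i], b[i])[2] == pytest.approx(p[i], abs=1e-10)
        rate = float((p < 0.05).mean())
        assert 0.04 <= rate <= 0.06


def brute_force_q(X, na, s0=0.0):
    """Enumerate all label assignments; SAM-style q per protein."""
    n = X.shape[1]
    def tstat(ia, ib):
        A, B = X[:, ia], X[:, ib]
        se = np.sqrt(A.var(axis=1, ddof=1) / len(ia)
                     + B.var(axis=1, ddof=1) / len(ib))
        return (A.mean(axis=1) - B.mean(axis=1)) / (se + s0)

    obs = np.abs(tstat(list(range(na)), list(range(na, n))))
    perms = []
    for comb in itertools.combinations(range(n), na):
        rest = [i for i in range(n) if i not in comb]
        perms.append(np.abs(tstat(list(comb), rest)))
    perms = np.array(perms)
    fdr = np.empty_like(obs)
    for i, thr in enumerate(obs):
        r = (obs >= thr).sum()
        v = (perms >= thr).sum() / len(perms)
        fdr[i] = min(1.0, v / r)
    # q_i = min FDR over proteins at or beyond i in Welch-p rank
    p = sps.ttest_ind(X[:, :na], X[:, na:], axis=1, equal_var=False).pvalue
    order = np.argsort(p, kind="stable")
    qq = np.empty_like(fdr)
    qq[order] = np.minimum.accumulate(fdr[order][::-1])[::-1]
    return obs, qq


class TestPermutationFdr:
    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            X = rng.normal(0, 1, (7, 6))
            X[0, :3] += 4.0  # one strong effect
            res = permutation_fdr(X, ["a"] * 3 + ["b"] * 3)
            _, q_oracle = brute_force_q(X, 3)
            assert np.allclose(res["q"].to_numpy(), q_oracle, atol=1e-12)

    def test_two_protein_toy_exhaustive(self):
        X = np.array([[1.0, 1.1, 0.9, 5.0, 5.2, 4.9],
                      [2.0, 1.0, 3.0, 2.5, 1.5, 2.2]])
        res = permutation_fdr(X, ["a"] * 3 + ["b"] * 3)
        _, q_oracle = brute_force_q(X, 3)
        assert np.allclose(res["q"].to_numpy(), q_oracle, atol=1e-12)

    def test_observed_exceeding_all_permuted_gives_q_zero(self):
        # random scheme with a huge effect: every sampled reshuffle that
        # is not the original labeling mixes the groups and shrinks |t|
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.05, (30, 12))
        X[0, :6] += 50.0
        plan = PermutationPlan(n_permutations=100, exhaustive_limit=10, seed=1)
        res = permutation_fdr(X, ["a"] * 6 + ["b"] * 6, plan)
        assert res["q"].iloc[0] <= 1.0 / 30  # at most self-exceedance
        # with the original labeling excluded by chance the bound is 0;
        # assert the strong protein is called far below any null q
        assert res["q"].iloc[0] < res["q"].iloc[1:].min()

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (1000, 8))
        res = permutation_fdr(X, ["a"] * 4 + ["b"] * 4)  # exhaustive C(8,4)
        assert (res["q"] < 0.05).mean() <= 0.07

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (200, 8))
        X[:20, :4] += 2.0
        res = permutation_fdr(X, ["a"] * 4 + ["b"] * 4)
        ordered = res.sort_values("p")["q"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_requires_seed_for_random_scheme(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (10, 12))
        plan = PermutationPlan(exhaustive_limit=5, seed=None)
        with pytest.raises(ValueError, match="seed"):
            permutation_fdr(X, ["a"] * 6 + ["b"] * 6, plan)

    def test_missing_values_rejected(self):
        X = np.full((3, 6), np.nan)
        with pytest.raises(ValueError, match="missing"):
            permutation_fdr(X, ["a"] * 3 + ["b"] * 3)


class TestFoldChange:
    def test_identity_and_hand_example(self):
        fc, lfc = geometric_fold_change([3, 3], [3, 3])
        assert (fc, lfc) == (1.0, 0.0)
        fc, lfc = geometric_fold_change([4, 16], [1, 1])
        assert fc == pytest.approx(8.0) and lfc == pytest.approx(3.0)

    def test_reciprocity(self):
        a, b = [2.0, 5.0, 9.0], [1.5, 4.0, 7.0]
        fc_ab, _ = geometric_fold_change(a, b)
        fc_ba, _ = geometric_fold_change(b, a)
        assert fc_ab * fc_ba == pytest.approx(1.0, abs=1e-12)

    def test_log2fc_equals_mean_log_difference(self):
        rng = np.random.default_rng(4)
        a, b = rng.lognormal(3, 1, 6), rng.lognormal(2, 1, 5)
        _, lfc = geometric_fold_change(a, b)
        assert lfc == pytest.approx(np.mean(np.log2(a)) - np.mean(np.log2(b)),
                                    abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_fold_change([1, 0], [1, 1])


@pytest.mark.parametrize("log2fc, q, expected", [
    (2.0, 0.01, "high_in_A"),
    (-1.5, 0.2, "NS"),            # q fails
    (1.0, 0.01, "NS"),            # boundary log2FC inclusive to NS
    (-1.0, 0.001, "NS"),
    (1.2, 0.05, "NS"),            # boundary q inclusive to NS
    (-3.0, 0.0, "high_in_B"),
])
def test_volcano_categories(log2fc, q, expected):
    assert classify_volcano(log2fc, q) == expected


class TestCorrelation:
    def test_hand_example_and_symmetry(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        r, p = sample_correlation(df)
        assert r.loc["x", "y"] == pytest.approx(0.8)
        assert r.loc["y", "x"] == pytest.approx(0.8)
        assert np.allclose(np.diag(r), 1.0)

    def test_duplicate_and_negated_sample(self):
        df = pd.DataFrame({"x": [1.0, 2, 5], "dup": [1.0, 2, 5],
                           "neg": [-1.0, -2, -5]})
        r, _ = sample_correlation(df)
        assert r.loc["x", "dup"] == pytest.approx(1.0)
        assert r.loc["x", "neg"] == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "const": [5.0, 5, 5]})
        r, _ = sample_correlation(df)
        assert np.isnan(r.loc["x", "const"])

    def test_pairwise_complete_cases(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, np.nan, 5],
                           "y": [2.0, 4, 6, 8, np.nan]})
        r, _ = sample_correlation(df)
        sub = df.dropna()
        assert r.loc["x", "y"] == pytest.approx(
            sps.pearsonr(sub["x"], sub["y"]).statistic)


class TestGrubbs:
    def test_critical_values(self):
        # standard two-sided table values
        assert grubbs_critical_value(4, 0.05) == pytest.approx(1.481, abs=2e-3)
        assert grubbs_critical_value(3, 0.05) == pytest.approx(1.153, abs=2e-3)

    def test_flags_extreme_value(self):
        assert grubbs_outlier([8, 9, 10, 50]) == 3

    def test_no_outlier_cases(self):
        with pytest.warns(UserWarning):
            assert grubbs_outlier([5, 5, 5, 5]) is None
        assert grubbs_outlier([1, 2, 3]) is None  # G = 1 < 1.153


class TestPairedT:
    def test_hand_example(self):
        t, df, p = paired_t([2, 3, 5], [1, 2, 3])  # differences (1, 1, 2)
        assert t == pytest.approx(4.0)
        assert df == 2
        assert p == pytest.approx(0.0572, abs=5e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(0.3, 1, 8)
        t, _, p = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_pairs_and_sign_flip(self):
        with pytest.warns(UserWarning):
            t, _, p = paired_t([1.0, 2.0], [1.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t1, _, p1 = paired_t([1.0, 1.0, 2.0])
        t2, _, p2 = paired_t([-1.0, -1.0, -2.0])
        assert t1 == -t2 and p1 == p2

    def test_constant_nonzero_differences_raise(self):
        with pytest.raises(ValueError, match="undefined"):
            paired_t([3.0, 3.0, 3.0])


def textbook_anova(groups):
    """Independently coded one-way ANOVA F from sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, sps.f.sf(F, df_b, df_w)


def tukey_p(groups, i, j):
    """Textbook Tukey HSD adjusted p via the studentized range."""
    k = len(groups)
    dfw = sum(len(g) for g in groups) - k
    msw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
              for g in groups) / dfw
    ni, nj = len(groups[i]), len(groups[j])
    se = math.sqrt(msw / 2 * (1 / ni + 1 / nj))
    qstat = abs(np.mean(groups[i]) - np.mean(groups[j])) / se
    return sps.studentized_range.sf(qstat, k, dfw)


class TestAnovaTukey:
    def test_identical_groups(self):
        F, p, _ = anova_tukey([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_ordering_contract(self):
        F, p, pairs = anova_tukey({"g1": [1, 2, 3], "g2": [1, 2, 3],
                                   "g3": [10, 11, 12]})
        byp = pairs.set_index(["group_a", "group_b"])["p_adj"]
        assert byp[("g1", "g2")] > 0.05
        assert byp[("g1", "g3")] < 0.05 and byp[("g2", "g3")] < 0.05

    def test_matches_textbook_formulas(self):
        groups = [[3.1, 2.9, 3.5], [4.0, 4.4, 3.8], [5.1, 4.9, 5.6]]
        F, p, pairs = anova_tukey(groups)
        F_ref, p_ref = textbook_anova(groups)
        assert F == pytest.approx(F_ref, abs=1e-8)
        assert p == pytest.approx(p_ref, abs=1e-8)
        for _, row in pairs.iterrows():
            i, j = int(row["group_a"][5:]), int(row["group_b"][5:])
            assert row["p_adj"] == pytest.approx(tukey_p(groups, i, j),
                                                 abs=1e-8)

    def test_too_few_groups_raise(self):
        with pytest.raises(ValueError, match="3 groups"):
            anova_tukey([[1, 2], [3, 4]])
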