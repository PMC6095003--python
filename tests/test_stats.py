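"""Statistical battery: enumeration and sum-of-squares oracles, adjustment
identities, type-I error calibration, and report assembly."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from atrophyz.exceptions import ValidationError
from atrophyz.stats_report import (anova_bonferroni, bonferroni_adjust,
                                   build_report, dunn_sidak_pairwise,
                                   kruskal_wallis, median_iqr, one_sample_t,
                                   sidak_adjust, wilcoxon_rank_sum)


# ---------------------------------------------------------------------------
# median / IQR
# ---------------------------------------------------------------------------

def brute_force_quantile(values, q):
    """Sort-based linear-interpolation quantile, written independently."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def test_median_iqr_examples():
    assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)
    assert median_iqr([7.0] * 4) == (7.0, 7.0, 7.0)
    with pytest.raises(ValidationError):
        median_iqr([])


def test_median_iqr_against_brute_force_oracle():
    rng = np.random.default_rng(0)
    for n in (3, 10, 57, 128):
        vals = rng.normal(size=n)
        med, q1, q3 = median_iqr(vals)
        assert med == pytest.approx(brute_force_quantile(vals, 0.5))
        assert q1 == pytest.approx(brute_force_quantile(vals, 0.25))
        assert q3 == pytest.approx(brute_force_quantile(vals, 0.75))


# ---------------------------------------------------------------------------
# Wilcoxon rank sum
# ---------------------------------------------------------------------------

def exhaustive_rank_sum_p(x, y):
    """Two-sided p by exhaustive enumeration of all rank assignments."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n1].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in itertools.combinations(range(n), n1)])
    lo = (sums <= obs + 1e-12).mean()
    hi = (sums >= obs - 1e-12).mean()
    return min(1.0, 2 * min(lo, hi))


def test_wilcoxon_identical_samples_p_one():
    res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert res.pvalue == 1.0


def test_wilcoxon_two_vs_two_exact():
    res = wilcoxon_rank_sum([1, 2], [3, 4])
    assert res.pvalue == pytest.approx(1 / 3)
    assert res.statistic == 3.0  # rank sum of the first sample


def test_wilcoxon_matches_enumeration_oracle_small_n():
    rng = np.random.default_rng(3)
    for n1, n2 in [(2, 2), (3, 4), (4, 4), (3, 5)]:
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        assert wilcoxon_rank_sum(x, y).pvalue == pytest.approx(
            exhaustive_rank_sum_p(x, y), abs=1e-12)


def test_wilcoxon_small_n_with_ties_matches_enumeration():
    x = [1.0, 2.0, 2.0]
    y = [2.0, 3.0, 4.0]
    assert wilcoxon_rank_sum(x, y).pvalue == pytest.approx(
        exhaustive_rank_sum_p(x, y), abs=1e-9)


def test_wilcoxon_large_sample_close_to_permutation_p():
    rng = np.random.default_rng(5)
    x = rng.normal(0.0, 1.0, 40)
    y = rng.normal(0.4, 1.0, 40)
    res = wilcoxon_rank_sum(x, y)
    perm = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method=sps.PermutationMethod(n_resamples=100_000,
                                     rng=np.random.default_rng(6)))
    assert res.pvalue == pytest.approx(perm.pvalue, abs=1e-3)


def test_wilcoxon_empty_sample_rejected():
    with pytest.raises(ValidationError):
        wilcoxon_rank_sum([], [1, 2])


# ---------------------------------------------------------------------------
# one-sample t
# ---------------------------------------------------------------------------

def test_one_sample_t_zero_when_mean_equals_mu0():
    res = one_sample_t([-1.0, 0.0, 1.0], 0.0)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_one_sample_t_closed_form():
    vals = [1.0, 2.0, 3.0, 4.0]
    res = one_sample_t(vals, 0.0)
    sd = np.std(vals, ddof=1)
    assert res.statistic == pytest.approx(2.5 / (sd / 2.0))


def test_one_sample_t_degenerate():
    with pytest.raises(ValidationError):
        one_sample_t([3.0, 3.0, 3.0])
    with pytest.raises(ValidationError):
        one_sample_t([1.0])


# ---------------------------------------------------------------------------
# ANOVA + Bonferroni
# ---------------------------------------------------------------------------

def brute_force_anova_f(groups):
    """F from the raw sum-of-squares decomposition."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def test_anova_zero_f_for_identical_groups():
    g = [1.0, 2.0, 3.0]
    res = anova_bonferroni([g, g, g])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_two_groups_equals_pooled_t():
    rng = np.random.default_rng(8)
    x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
    res = anova_bonferroni([x, y])
    t = sps.ttest_ind(x, y, equal_var=True)
    assert res.statistic == pytest.approx(t.statistic ** 2)
    assert res.pvalue == pytest.approx(t.pvalue)


def test_anova_matches_sum_of_squares_oracle():
    groups = [[1.0, 2.0, 4.0], [2.0, 5.0, 7.0, 8.0], [1.5, 2.5]]
    res = anova_bonferroni(groups)
    assert res.statistic == pytest.approx(brute_force_anova_f(groups))


def test_anova_pairwise_bonferroni_capped_and_symmetric():
    rng = np.random.default_rng(9)
    groups = [rng.normal(m, 1, 10) for m in (0.0, 0.1, 0.2)]
    res = anova_bonferroni(groups, labels=["a", "b", "c"])
    assert res.m == 3
    raw = sps.ttest_ind(groups[0], groups[1], equal_var=True).pvalue
    assert res.pairwise.loc["a", "b"] == pytest.approx(min(1.0, raw * 3))
    assert res.pairwise.loc["b", "a"] == res.pairwise.loc["a", "b"]


def test_anova_degenerate_rejected():
    with pytest.raises(ValidationError):
        anova_bonferroni([[1.0, 2.0]])
    with pytest.raises(ValidationError):
        anova_bonferroni([[1.0], [2.0, 3.0]])


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn-Sidak
# ---------------------------------------------------------------------------

def test_kruskal_all_tied_flagged():
    res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
    assert res.statistic == 0.0
    assert res.pvalue == 1.0
    assert "all_values_tied" in res.flags


def test_kruskal_direct_rank_formula():
    groups = [[1, 2], [3, 4], [5, 6]]
    res = kruskal_wallis(groups)
    # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no ties
    n_total = 6
    mean_ranks = [1.5, 3.5, 5.5]
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        2 * (r - (n_total + 1) / 2) ** 2 for r in mean_ranks)
    assert res.statistic == pytest.approx(h)
    assert res.pvalue == pytest.approx(sps.chi2.sf(h, 2))


def test_kruskal_two_groups_equals_rank_sum_normal_approx():
    rng = np.random.default_rng(10)
    x, y = rng.normal(0, 1, 30), rng.normal(0.3, 1, 30)
    kw = kruskal_wallis([x, y])
    mw = wilcoxon_rank_sum(x, y)
    assert kw.pvalue == pytest.approx(mw.pvalue, abs=1e-3)


@pytest.mark.parametrize("p, m, expected", [
    (0.0, 3, 0.0),
    (0.01, 3, 0.029701),
    (1.0, 5, 1.0),
])
def test_sidak_adjustment_values(p, m, expected):
    assert sidak_adjust(p, m) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=200, derandomize=True)
@given(p=st.floats(min_value=0.0, max_value=1.0),
       m=st.integers(min_value=1, max_value=20))
def test_sidak_bounded_by_bonferroni_and_monotone(p, m):
    s = sidak_adjust(p, m)
    assert 0.0 <= s <= 1.0
    assert s <= bonferroni_adjust(p, m) + 1e-12
    assert sidak_adjust(min(1.0, p + 0.01), m) >= s - 1e-12


def test_dunn_sidak_small_example_matches_formula():
    groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    res = dunn_sidak_pairwise(groups, labels=["g0", "g1", "g2"])
    # no ties: variance N(N+1)/12, mean ranks 1.5/3.5/5.5
    var = 6 * 7 / 12.0
    se = math.sqrt(var * (0.5 + 0.5))
    z01 = (1.5 - 3.5) / se
    p01 = 2 * sps.norm.sf(abs(z01))
    assert res.pairwise.loc["g0", "g1"] == pytest.approx(
        1 - (1 - p01) ** 3)
    assert res.m == 3
    assert res.multiplicity == "sidak"


def test_dunn_sidak_tie_correction_changes_p():
    no_ties = dunn_sidak_pairwise([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    with_ties = dunn_sidak_pairwise([[1.0, 2.0], [2.0, 4.0], [4.0, 6.0]])
    assert not np.allclose(no_ties.pairwise.to_numpy(),
                           with_ties.pairwise.to_numpy())


# ---------------------------------------------------------------------------
# type-I error calibration
# ---------------------------------------------------------------------------

def test_type_i_error_of_each_test_under_its_null():
    rng = np.random.default_rng(2024)
    n_sim, alpha = 2000, 0.05
    rejections = {"wilcoxon": 0, "t": 0, "anova": 0, "kw": 0}
    for _ in range(n_sim):
        x, y, w = (rng.normal(size=12) for _ in range(3))
        if wilcoxon_rank_sum(x, y).pvalue < alpha:
            rejections["wilcoxon"] += 1
        if one_sample_t(x, 0.0).pvalue < alpha:
            rejections["t"] += 1
        if anova_bonferroni([x, y, w]).pvalue < alpha:
            rejections["anova"] += 1
        if kruskal_wallis([x, y, w]).pvalue < alpha:
            rejections["kw"] += 1
    for name, count in rejections.items():
        rate = count / n_sim
        assert 0.03 <= rate <= 0.07, f"{name}: {rate}"


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def null_cohort(rng, n_rrms=60, n_spms=30):
    n = n_rrms + n_spms
    ids = [f"p{i}" for i in range(n)]
    cohort = pd.DataFrame({
        "id": ids,
        "cohort": ["RRMS"] * n_rrms + ["SPMS"] * n_spms,
        "age": rng.uniform(20, 70, n),
        "disease_duration": rng.uniform(1, 20, n),
        "edss": np.round(rng.uniform(0, 8, n) * 2) / 2,
        "sdmt": np.round(rng.normal(-1, 1, n) * 4) / 4,
        "lesion_load": rng.lognormal(1.0, 0.8, n),
    })
    z = pd.DataFrame({"id": ids,
                      "thalamus": rng.normal(size=n),
                      "bp": rng.normal(size=n)})
    groups = pd.DataFrame({
        "id": ids,
        "group": rng.choice(["group0", "group1", "group2"], size=n)})
    return cohort, z, groups


def test_build_report_shapes_and_determinism():
    rng = np.random.default_rng(1)
    cohort, z, groups = null_cohort(rng)
    rep1 = build_report(cohort, z, groups)
    rep2 = build_report(cohort, z, groups)
    pd.testing.assert_frame_equal(rep1["phenotype_summary"],
                                  rep2["phenotype_summary"])
    pd.testing.assert_frame_equal(rep1["group_summary"],
                                  rep2["group_summary"])
    assert set(rep1["group_summary"]["phenotype"]) == {"RRMS", "SPMS"}
    assert not rep1["region_tests"].empty


def test_build_report_single_phenotype_no_crash():
    rng = np.random.default_rng(2)
    cohort, z, groups = null_cohort(rng, n_rrms=40, n_spms=0)
    rep = build_report(cohort, z, groups)
    assert set(rep["group_summary"]["phenotype"]) == {"RRMS"}
    assert rep["phenotype_tests"].empty  # nothing to compare against


def test_build_report_excludes_outliers():
    rng = np.random.default_rng(3)
    cohort, z, groups = null_cohort(rng, n_rrms=20, n_spms=10)
    groups.loc[0, "group"] = "bp_only_outlier"
    rep = build_report(cohort, z, groups)
    assert {e["id"] for e in rep["excluded"]} == {"p0"}


def test_build_report_id_mismatch_listed():
    rng = np.random.default_rng(4)
    cohort, z, groups = null_cohort(rng, n_rrms=10, n_spms=5)
    with pytest.raises(ValidationError, match="p0"):
        build_report(cohort, z.iloc[1:], groups)


def test_build_report_null_flag_rate_controlled():
    # zero-effect cohorts: each phenotype-comparison test flags at ~alpha
    rng = np.random.default_rng(99)
    flags, total = 0, 0
    for _ in range(60):
        cohort, z, groups = null_cohort(rng)
        rep = build_report(cohort, z, groups)
        tests = rep["phenotype_tests"]
        flags += int(tests["significant"].sum())
        total += len(tests)
    rate = flags / total
    assert rate < 0.12
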