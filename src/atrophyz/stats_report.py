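"""Group-comparison statistics and cohort summary tables.

The battery mirrors a standard clinical-volumetry report: median (q1; q3)
descriptives, Wilcoxon rank-sum tests between the two phenotypes, one-sample
t-tests of regional z-scores against zero, one-way ANOVA across regions with
Bonferroni-adjusted pairwise post-hocs, and Kruskal-Wallis tests across the
atrophy groups followed by Dunn's pooled-rank pairwise comparisons with
Šidák family-wise adjustment (p_adj = 1 - (1 - p)^m).

Quantiles use linear interpolation (the "type 7" convention). All tests are
two-sided; significance is flagged at a configurable alpha (default 0.05).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = [
    "TestResult", "median_iqr", "wilcoxon_rank_sum", "one_sample_t",
    "anova_bonferroni", "kruskal_wallis", "dunn_sidak_pairwise",
    "sidak_adjust", "bonferroni_adjust", "build_report",
]


@dataclass
class TestResult:
    """One hypothesis test, optionally with adjusted pairwise post-hocs."""

    name: str
    statistic: float
    pvalue: float
    groups: list | None = None
    pairwise: pd.DataFrame | None = None   # adjusted p, symmetric
    multiplicity: str | None = None
    m: int | None = None                   # family size of the adjustment
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"p-value {self.pvalue} outside [0, 1]")
        if self.pairwise is not None:
            a = self.pairwise.to_numpy(float)
            if not np.allclose(a, a.T, equal_nan=True):
                raise ValidationError("pairwise p matrix must be symmetric")

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.pvalue < alpha)

    def to_dict(self) -> dict:
        d = {"name": self.name, "statistic": self.statistic,
             "pvalue": self.pvalue, "groups": self.groups,
             "multiplicity": self.multiplicity, "m": self.m,
             "flags": list(self.flags)}
        if self.pairwise is not None:
            d["pairwise"] = {f"{i}|{j}": float(self.pairwise.loc[i, j])
                             for i in self.pairwise.index
                             for j in self.pairwise.columns if i < j}
        return d


def median_iqr(values) -> tuple:
    """(median, q1, q3) with linearly interpolated quartiles."""
    a = np.asarray(values, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValidationError("median_iqr needs at least one finite value")
    return (float(np.median(a)), float(np.quantile(a, 0.25)),
            float(np.quantile(a, 0.75)))


def _clean(sample, name="sample"):
    a = np.asarray(sample, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValidationError(f"{name} is empty")
    return a


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for small samples without ties, exhaustive
    permutation for small samples with ties, normal approximation with
    midrank tie correction otherwise. The statistic reported is the rank
    sum W of the first sample.
    """
    x, y = _clean(x, "x"), _clean(y, "y")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 <= 8 and n2 <= 8:
        method = sps.PermutationMethod(n_resamples=13000) if has_ties \
            else "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        # tie-corrected normal approximation; no continuity correction so the
        # two-group case agrees exactly with Kruskal-Wallis
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0
    return TestResult(name="wilcoxon_rank_sum", statistic=w,
                      pvalue=float(min(res.pvalue, 1.0)),
                      flags=["ties"] if has_ties else [])


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test against mean ``mu0``."""
    a = _clean(values)
    if a.size < 2:
        raise ValidationError("one_sample_t needs n >= 2")
    if np.ptp(a) == 0:
        raise ValidationError("one_sample_t needs nonzero variance")
    res = sps.ttest_1samp(a, popmean=mu0)
    return TestResult(name="one_sample_t", statistic=float(res.statistic),
                      pvalue=float(res.pvalue))


def bonferroni_adjust(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def sidak_adjust(p: float, m: int) -> float:
    """Family-wise adjustment p_adj = 1 - (1 - p)^m, capped at 1."""
    if p >= 1.0:
        return 1.0
    return float(min(1.0, -math.expm1(m * math.log1p(-max(p, 0.0)))))


def _pairwise_frame(labels, values: dict) -> pd.DataFrame:
    frame = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for (i, j), p in values.items():
        frame.loc[i, j] = frame.loc[j, i] = p
    return frame


def anova_bonferroni(groups, labels=None) -> TestResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise t post-hocs."""
    arrays = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("ANOVA needs >= 2 groups with n >= 2 each")
    labels = list(labels) if labels is not None else \
        [str(i) for i in range(len(arrays))]
    f, p = sps.f_oneway(*arrays)
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    adj = {}
    for i, j in pairs:
        t = sps.ttest_ind(arrays[i], arrays[j], equal_var=True)
        adj[(labels[i], labels[j])] = bonferroni_adjust(float(t.pvalue), m)
    return TestResult(name="anova", statistic=float(f), pvalue=float(p),
                      groups=labels, pairwise=_pairwise_frame(labels, adj),
                      multiplicity="bonferroni", m=m)


def kruskal_wallis(groups, labels=None) -> TestResult:
    """Kruskal-Wallis H with midrank tie correction, chi-square p (k-1 df).

    All observations identical is flagged and reported as H = 0, p = 1
    (the all-tie correction leaves H undefined).
    """
    arrays = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2 or sum(len(a) for a in arrays) < 3:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups, total n >= 3")
    labels = list(labels) if labels is not None else \
        [str(i) for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(name="kruskal_wallis", statistic=0.0, pvalue=1.0,
                          groups=labels, flags=["all_values_tied"])
    h, p = sps.kruskal(*arrays)
    return TestResult(name="kruskal_wallis", statistic=float(h),
                      pvalue=float(p), groups=labels)


def dunn_sidak_pairwise(groups, labels=None) -> TestResult:
    """Dunn's pooled-rank pairwise comparisons with Šidák adjustment.

    For groups i, j with mean pooled midranks R̄_i, R̄_j over N observations,

        z_ij = (R̄_i - R̄_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),

    with tie term T = Σ(t³ - t) / (12(N - 1)); two-sided normal p values are
    Šidák-adjusted over the m = k(k-1)/2 comparisons. The omnibus
    Kruskal-Wallis p is reported as the headline p of the result.
    """
    arrays = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    labels = list(labels) if labels is not None else \
        [str(i) for i in range(len(arrays))]
    omnibus = kruskal_wallis(arrays, labels=labels)
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(arrays))]
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    adj = {}
    for i, j in pairs:
        if variance <= 0:
            adj[(labels[i], labels[j])] = 1.0
            continue
        se = math.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        adj[(labels[i], labels[j])] = sidak_adjust(
            2.0 * sps.norm.sf(abs(z)), m)
    return TestResult(name="dunn_sidak", statistic=omnibus.statistic,
                      pvalue=omnibus.pvalue, groups=labels,
                      pairwise=_pairwise_frame(labels, adj),
                      multiplicity="sidak", m=m, flags=omnibus.flags)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

_CLINICAL_VARS = ["age", "disease_duration", "edss", "sdmt", "lesion_load"]
_GROUP_VARS = ["lesion_load", "disease_duration", "edss", "sdmt"]


def _descriptive_rows(df, variables, by, alpha):
    rows, tests = [], []
    for var in variables:
        if var not in df.columns:
            continue
        vals = df[var].dropna()
        if vals.empty:
            continue
        med, q1, q3 = median_iqr(vals)
        rows.append({"variable": var, "split": "all", "n": len(vals),
                     "median": med, "q1": q1, "q3": q3})
        levels = sorted(df[by].dropna().unique().tolist())
        per_level = []
        for level in levels:
            lv = df.loc[df[by] == level, var].dropna()
            if lv.empty:
                continue
            med, q1, q3 = median_iqr(lv)
            rows.append({"variable": var, "split": level, "n": len(lv),
                         "median": med, "q1": q1, "q3": q3})
            per_level.append(lv.to_numpy(float))
        if len(per_level) == 2 and all(len(v) for v in per_level):
            try:
                res = wilcoxon_rank_sum(*per_level)
            except ValidationError:
                continue
            tests.append({"variable": var, "test": res.name,
                          "statistic": res.statistic, "pvalue": res.pvalue,
                          "significant": res.significant(alpha)})
    return pd.DataFrame(rows), pd.DataFrame(tests)


def build_report(cohort: pd.DataFrame, z_profiles: pd.DataFrame,
                 groups: pd.DataFrame, regions=None,
                 alpha: float = 0.05) -> dict:
    """Assemble phenotype- and atrophy-group-level summaries and tests.

    Parameters
    ----------
    cohort : patient table (``id``, ``cohort`` phenotype label, clinical
        scores).
    z_profiles : per-subject regional z-scores (``id`` + region columns).
    groups : frame with ``id`` and the ``group`` label; ``bp_only_outlier``
        and unclassified subjects are excluded from the group statistics.
    regions : region columns to analyze (default: all present).

    Returns a dict with ``phenotype_summary`` / ``phenotype_tests`` (the
    phenotype-comparison table), ``region_tests`` (one-sample t per region z
    plus across-region ANOVA with Bonferroni post-hocs),
    ``group_summary`` / ``group_tests`` (per-phenotype Kruskal-Wallis across
    atrophy groups with Dunn-Šidák post-hocs, family size annotated), and
    ``excluded``.
    """
    for name, frame in (("z_profiles", z_profiles), ("groups", groups)):
        missing = set(cohort["id"]) ^ set(frame["id"])
        if missing:
            raise ValidationError(
                f"subject ids in cohort and {name} differ: {sorted(missing)[:10]}")
    regions = list(regions) if regions is not None else \
        [c for c in z_profiles.columns
         if c not in ("id", "scanner", "age_extrapolated")]
    z_cols = z_profiles[["id"] + regions].rename(
        columns={r: f"{r}_z" for r in regions})
    merged = cohort.merge(z_cols, on="id").merge(
        groups[["id", "group"]], on="id")

    variables = _CLINICAL_VARS + [f"{r}_z" for r in regions]
    phen_summary, phen_tests = _descriptive_rows(
        merged, variables, by="cohort", alpha=alpha)

    region_tests = []
    for region in regions:
        vals = merged[f"{region}_z"].dropna()
        if len(vals) >= 2 and np.ptp(vals) > 0:
            res = one_sample_t(vals, 0.0)
            region_tests.append({"region": region, "test": res.name,
                                 "statistic": res.statistic,
                                 "pvalue": res.pvalue,
                                 "significant": res.significant(alpha)})
    anova = None
    z_arrays = [merged[f"{r}_z"].dropna().to_numpy(float) for r in regions]
    if len(z_arrays) >= 2 and all(len(a) >= 2 for a in z_arrays):
        anova = anova_bonferroni(z_arrays, labels=regions)

    keep = merged["group"].isin(["group0", "group1", "group2"])
    excluded = merged.loc[~keep, ["id", "group"]].to_dict(orient="records")
    grouped = merged.loc[keep]
    group_rows, group_tests = [], []
    group_vars = [f"{r}_z" for r in regions
                  if r in ("thalamus", "bp")] + _GROUP_VARS
    for phen in sorted(grouped["cohort"].dropna().unique().tolist()):
        sub = grouped[grouped["cohort"] == phen]
        order = [g for g in ("group0", "group1", "group2")
                 if (sub["group"] == g).any()]
        for g in order:
            block = sub[sub["group"] == g]
            row = {"phenotype": phen, "group": g, "n": len(block)}
            for var in group_vars:
                vals = block[var].dropna() if var in block else pd.Series([])
                if not vals.empty:
                    med, q1, q3 = median_iqr(vals)
                    row[f"{var}_median"] = med
                    row[f"{var}_q1"] = q1
                    row[f"{var}_q3"] = q3
            group_rows.append(row)
        for var in _GROUP_VARS:
            samples = [sub.loc[sub["group"] == g, var].dropna().to_numpy(float)
                       for g in order]
            if len(samples) < 2 or any(len(s) == 0 for s in samples):
                continue
            try:
                kw = kruskal_wallis(samples, labels=order)
            except ValidationError:
                continue
            entry = {"phenotype": phen, "variable": var, "test": kw.name,
                     "statistic": kw.statistic, "pvalue": kw.pvalue,
                     "significant": kw.significant(alpha)}
            if kw.significant(alpha) and all(len(s) >= 2 for s in samples):
                dunn = dunn_sidak_pairwise(samples, labels=order)
                entry["posthoc"] = dunn.to_dict()
            group_tests.append(entry)

    return {
        "alpha": alpha,
        "phenotype_summary": phen_summary,
        "phenotype_tests": phen_tests,
        "region_tests": pd.DataFrame(region_tests),
        "region_anova": anova,
        "group_summary": pd.DataFrame(group_rows),
        "group_tests": group_tests,
        "excluded": excluded,
    }


def plot_z_distributions(z_profiles: pd.DataFrame, cohort: pd.DataFrame,
                         regions=None, path=None):
    """Box plots of regional z-scores split by phenotype (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = list(regions) if regions is not None else \
        [c for c in z_profiles.columns
         if c not in ("id", "scanner", "age_extrapolated")]
    merged = z_profiles.merge(cohort[["id", "cohort"]], on="id")
    phenotypes = sorted(merged["cohort"].dropna().unique().tolist())
    fig, ax = plt.subplots(figsize=(1.2 * len(regions) + 2, 4))
    width = 0.8 / max(len(phenotypes), 1)
    for k, phen in enumerate(phenotypes):
        data = [merged.loc[merged["cohort"] == phen, r].dropna()
                for r in regions]
        pos = [i + k * width for i in range(len(regions))]
        ax.boxplot(data, positions=pos, widths=width * 0.9)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axhline(-1.96, color="red", lw=0.8, ls="--")
    ax.set_xticks([i + width * (len(phenotypes) - 1) / 2
                   for i in range(len(regions))])
    ax.set_xticklabels(regions, rotation=30, ha="right")
    ax.set_ylabel("z-score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
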