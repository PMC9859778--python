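"""Cross-sectional subtype characterization statistics.

Implements the group-comparison battery used to profile the clusters:
Pearson chi-squared for categorical variables, one-way ANOVA for
continuous variables (from raw values or from printed mean/SD/n
summaries), per-ROI age-adjusted ANCOVA with Benjamini-Hochberg FDR
across the 96 ROIs, and the basal-ganglia/cortical volume ratio with
pairwise Welch comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import residualize
from .schema import ROISchema
from .simulate import CLINICAL_BINARIES, MMSE_COLUMNS


@dataclass
class GroupComparisonResult:
    """One variable's between-cluster comparison."""

    variable: str
    test: str                  # "oneway-anova" | "chi-squared" | "ancova"
    statistic: float
    df: tuple
    p_value: float
    group_summaries: pd.DataFrame
    post_hoc: pd.DataFrame | None = None
    note: str = ""

    def __repr__(self) -> str:
        return (f"<GroupComparisonResult {self.variable}: {self.test} "
                f"stat={self.statistic:.3f} p={self.p_value:.4g}>")


# ---------------------------------------------------------------------------
# chi-squared

def chi_squared_test(counts, variable: str = "") -> GroupComparisonResult:
    """Pearson chi-squared (no continuity correction) on an R x C table."""
    table = np.asarray(counts)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if not np.all(table == np.floor(table)) or np.any(table < 0):
        raise ValueError("counts must be non-negative integers")
    table = table.astype(int)
    if table.sum() == 0:
        raise ValueError("contingency table is empty")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero margin")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    rows = pd.DataFrame(table)
    rows["present_pct"] = 100.0 * table[:, 0] / table.sum(axis=1)
    return GroupComparisonResult(variable=variable, test="chi-squared",
                                 statistic=float(stat), df=(dof,),
                                 p_value=float(p), group_summaries=rows)


# ---------------------------------------------------------------------------
# one-way ANOVA

def _anova_from_summaries(groups) -> tuple[float, tuple, float]:
    """F from per-group (mean, sd, n); exact sums-of-squares reconstruction."""
    means = np.array([g[0] for g in groups], dtype=float)
    sds = np.array([g[1] for g in groups], dtype=float)
    ns = np.array([g[2] for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("summary-mode ANOVA needs n >= 2 per group")
    k = len(groups)
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds ** 2).sum()
    if ss_within == 0:
        raise ValueError("zero within-group variance in every group")
    df = (k - 1, n_total - k)
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(f, *df))
    return float(f), df, p


def oneway_anova(groups=None, *, summaries=None,
                 variable: str = "") -> GroupComparisonResult:
    """One-way ANOVA from raw per-group values or (mean, sd, n) summaries.

    ``groups`` is a list of 1-D value arrays; alternatively pass
    ``summaries`` as a list of (mean, sd, n) tuples (SD with ddof=1).
    The two modes agree exactly when the summaries are computed from
    the raw values.
    """
    if (groups is None) == (summaries is None):
        raise ValueError("pass exactly one of groups= or summaries=")
    if groups is not None:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if len(arrays) < 2:
            raise ValueError("need at least 2 groups")
        if any(len(a) < 1 for a in arrays):
            raise ValueError("every group needs at least one value")
        summaries = [(a.mean(), a.std(ddof=1) if len(a) > 1 else 0.0, len(a))
                     for a in arrays]
        if sum(len(a) for a in arrays) <= len(arrays):
            raise ValueError("no residual degrees of freedom")
    f, df, p = _anova_from_summaries(summaries)
    summ = pd.DataFrame(summaries, columns=["mean", "sd", "n"])
    return GroupComparisonResult(variable=variable, test="oneway-anova",
                                 statistic=f, df=df, p_value=p,
                                 group_summaries=summ)


def pairwise_posthoc(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Welch pairwise t-tests with Bonferroni correction over all pairs."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    names = labels if labels is not None else list(range(1, len(arrays) + 1))
    pairs = list(combinations(range(len(arrays)), 2))
    rows = []
    for i, j in pairs:
        t, p = sps.ttest_ind(arrays[i], arrays[j], equal_var=False)
        p_adj = min(1.0, p * len(pairs))
        rows.append({"group_a": names[i], "group_b": names[j],
                     "mean_diff": arrays[i].mean() - arrays[j].mean(),
                     "t": float(t), "p_raw": float(p), "p_bonferroni": p_adj,
                     "significant": p_adj < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FDR

def fdr_bh(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# per-ROI ANCOVA

@dataclass
class AncovaTable:
    """Per-ROI cluster-effect F tests with FDR correction."""

    table: pd.DataFrame      # roi, f, df1, df2, p_raw, p_fdr, significant, error
    covariates: tuple[str, ...]
    alpha: float = 0.05

    @property
    def significant_rois(self) -> list[str]:
        ok = self.table[self.table["significant"].fillna(False)]
        return ok["roi"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")


def ancova_per_roi(volumes: pd.DataFrame, labels, age,
                   alpha: float = 0.05) -> AncovaTable:
    """Per-ROI ANCOVA: volume ~ cluster (factor) + age, FDR across ROIs.

    ``volumes`` may be raw volumes or center/ICV residuals (the default
    pipeline passes residuals, so cluster effects are tested net of
    center, head size and age).  Returns an F test of the cluster
    factor per ROI; Benjamini-Hochberg correction is applied across all
    ROIs at ``alpha``.  Rank-deficient single-ROI fits produce an error
    entry rather than aborting the table.
    """
    labels = np.asarray(labels)
    age = np.asarray(age, dtype=float)
    n = len(labels)
    if volumes.shape[0] != n or age.shape[0] != n:
        raise ValueError("volumes, labels and age must have equal length")
    if np.isnan(age).any():
        raise ValueError("age must be complete")
    clusters = np.unique(labels)
    k = clusters.size
    if k < 2:
        raise ValueError("need at least 2 clusters")

    # shared designs: full (cluster dummies + age) vs reduced (age only)
    dummies = np.column_stack([(labels == c).astype(float) for c in clusters[1:]])
    ones = np.ones(n)
    X_full = np.column_stack([ones, dummies, age])
    X_red = np.column_stack([ones, age])
    df1 = k - 1
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")

    rows = []
    full_ok = np.linalg.matrix_rank(X_full) == X_full.shape[1]
    for roi in volumes.columns:
        y = volumes[roi].to_numpy(dtype=float)
        if np.isnan(y).any() or not full_ok:
            rows.append({"roi": roi, "f": np.nan, "df1": df1, "df2": df2,
                         "p_raw": np.nan,
                         "error": ("missing values" if full_ok
                                   else "rank-deficient design")})
            continue
        rss_full = _rss(X_full, y)
        rss_red = _rss(X_red, y)
        if rss_full <= 0:
            f = float("inf") if rss_red > rss_full else 0.0
            p = 0.0 if f > 0 else 1.0
        else:
            f = ((rss_red - rss_full) / df1) / (rss_full / df2)
            f = max(f, 0.0)
            p = float(sps.f.sf(f, df1, df2))
        rows.append({"roi": roi, "f": f, "df1": df1, "df2": df2,
                     "p_raw": p, "error": ""})
    table = pd.DataFrame(rows)
    ok = table["p_raw"].notna()
    p_adj = np.full(len(table), np.nan)
    sig = np.full(len(table), np.nan, dtype=object)
    if ok.any():
        adj, rej = fdr_bh(table.loc[ok, "p_raw"].to_numpy(), alpha=alpha)
        p_adj[ok.to_numpy()] = adj
        sig[ok.to_numpy()] = rej
    table["p_fdr"] = p_adj
    table["significant"] = sig
    return AncovaTable(table=table, covariates=("age",), alpha=alpha)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# basal-ganglia / cortical ratio

@dataclass
class RatioResult:
    """Per-subject BG/cortical volume ratio and cluster comparisons."""

    ratios: pd.Series
    cluster_stats: pd.DataFrame       # cluster, n, mean, sd
    pairwise: pd.DataFrame            # Welch CIs and p-values per cluster pair

    def to_csv(self, path) -> None:
        self.cluster_stats.to_csv(path, index=False, float_format="%.17g")


def bg_cortical_ratio(cohort: pd.DataFrame, schema: ROISchema,
                      labels=None) -> RatioResult:
    """Sum of the 6 basal-ganglia volumes over the sum of the 82 cortical.

    Computed on raw volumes (the ratio is scale invariant, so head-size
    adjustment is unnecessary).  With cluster labels, per-cluster
    means/SDs and pairwise Welch 95% CIs are reported.
    """
    bg = schema.basal_ganglia
    cortical = schema.cortical
    if len(bg) != 6 or len(cortical) != 82:
        raise ValueError("schema must flag exactly 6 basal-ganglia "
                         "and 82 cortical ROIs")
    cort_sum = cohort[cortical].to_numpy(dtype=float).sum(axis=1)
    if np.any(cort_sum <= 0):
        raise ValueError("non-positive cortical volume sum")
    ratios = pd.Series(cohort[bg].to_numpy(dtype=float).sum(axis=1) / cort_sum,
                       index=cohort.index, name="bg_cortical_ratio")
    if labels is None:
        labels = (cohort["true_cluster"].to_numpy()
                  if "true_cluster" in cohort.columns
                  else np.ones(len(cohort), dtype=int))
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    stats_rows = [{"cluster": int(c), "n": int((labels == c).sum()),
                   "mean": ratios[labels == c].mean(),
                   "sd": ratios[labels == c].std(ddof=1)} for c in clusters]
    pair_rows = []
    for a, b in combinations(clusters, 2):
        x, y = ratios[labels == a], ratios[labels == b]
        t, p = sps.ttest_ind(x, y, equal_var=False)
        se = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        dof = _welch_df(x, y)
        half = sps.t.ppf(0.975, dof) * se
        diff = x.mean() - y.mean()
        pair_rows.append({"cluster_a": int(a), "cluster_b": int(b),
                          "mean_diff": diff, "ci_low": diff - half,
                          "ci_high": diff + half, "t": float(t),
                          "p_value": float(p)})
    return RatioResult(ratios=ratios,
                       cluster_stats=pd.DataFrame(stats_rows),
                       pairwise=pd.DataFrame(pair_rows))


def _welch_df(x, y) -> float:
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))


# ---------------------------------------------------------------------------
# Table-1-style battery

CONTINUOUS_VARIABLES = ("age", "education", "mmse_00", "wmh")
CATEGORICAL_VARIABLES = ("sex",) + CLINICAL_BINARIES + ("center",)


def _ancova_f(y, labels, covariate_matrix) -> tuple[float, tuple, float]:
    """F test of the cluster factor adjusting for the given covariates."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    n = len(y)
    dummies = np.column_stack([(labels == c).astype(float) for c in clusters[1:]])
    ones = np.ones(n)
    X_full = np.column_stack([ones, dummies, covariate_matrix])
    X_red = np.column_stack([ones, covariate_matrix])
    df1 = clusters.size - 1
    df2 = n - X_full.shape[1]
    rss_full = _rss(X_full, y)
    rss_red = _rss(X_red, y)
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return float(f), (df1, df2), float(sps.f.sf(f, df1, df2))


def characterize_table(cohort: pd.DataFrame, labels,
                       continuous=CONTINUOUS_VARIABLES,
                       categorical=CATEGORICAL_VARIABLES,
                       ) -> list[GroupComparisonResult]:
    """Run the demographic/clinical comparison battery across clusters.

    Available-case analysis per variable: subjects missing a value are
    dropped for that variable only, and the per-cluster n with data is
    reported.  Continuous variables get one-way ANOVA plus Welch
    pairwise post-hoc tests (Bonferroni over the pairs); categorical
    variables get Pearson chi-squared.  Baseline MMSE additionally gets
    an ANCOVA adjusting for age and education, and WMH an ANCOVA
    adjusting for age, mirroring the age-confound checks used when
    profiling the subtypes.  Variables absent from the cohort are
    skipped with a warning.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    results: list[GroupComparisonResult] = []

    for var in continuous:
        if var not in cohort.columns:
            warnings.warn(f"variable {var!r} absent, skipped")
            continue
        values = cohort[var]
        ok = values.notna().to_numpy()
        groups = [values.to_numpy(dtype=float)[ok & (labels == c)]
                  for c in clusters]
        res = oneway_anova(groups=groups, variable=var)
        res.group_summaries["cluster"] = clusters
        res.post_hoc = pairwise_posthoc(groups, labels=list(map(int, clusters)))
        results.append(res)

    for var in categorical:
        if var not in cohort.columns:
            warnings.warn(f"variable {var!r} absent, skipped")
            continue
        values = cohort[var]
        ok = values.notna().to_numpy()
        sub = pd.crosstab(labels[ok], values[ok])
        try:
            res = chi_squared_test(sub.to_numpy(), variable=var)
        except ValueError as exc:
            warnings.warn(f"variable {var!r}: {exc}; skipped")
            continue
        res.group_summaries.index = sub.index
        res.group_summaries.columns = (
            list(sub.columns) + ["present_pct"]
            if "present_pct" not in sub.columns else list(sub.columns))
        res.note = f"levels: {list(sub.columns)}"
        results.append(res)

    # covariate-adjusted follow-ups
    if "mmse_00" in cohort.columns and {"age", "education"} <= set(cohort.columns):
        ok = cohort["mmse_00"].notna().to_numpy()
        f, df, p = _ancova_f(cohort.loc[ok, "mmse_00"].to_numpy(dtype=float),
                             labels[ok],
                             cohort.loc[ok, ["age", "education"]]
                             .to_numpy(dtype=float))
        results.append(GroupComparisonResult(
            variable="mmse_00", test="ancova", statistic=f, df=df, p_value=p,
            group_summaries=pd.DataFrame(),
            note="adjusted for age and education"))
    if "wmh" in cohort.columns and "age" in cohort.columns:
        ok = cohort["wmh"].notna().to_numpy()
        f, df, p = _ancova_f(cohort.loc[ok, "wmh"].to_numpy(dtype=float),
                             labels[ok],
                             cohort.loc[ok, ["age"]].to_numpy(dtype=float))
        results.append(GroupComparisonResult(
            variable="wmh", test="ancova", statistic=f, df=df, p_value=p,
            group_summaries=pd.DataFrame(), note="adjusted for age"))
    return results


def comparison_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Flatten a battery of comparisons into one summary DataFrame."""
    rows = []
    for r in results:
        rows.append({"variable": r.variable, "test": r.test,
                     "statistic": r.statistic,
                     "df": "/".join(str(int(d)) for d in r.df),
                     "p_value": r.p_value, "note": r.note})
    return pd.DataFrame(rows)
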