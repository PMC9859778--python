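import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gmsubtype import (SimulationSpec, ancova_per_roi, bg_cortical_ratio,
                       characterize_table, chi_squared_test, fdr_bh,
                       oneway_anova, simulate_cohort)
from reference_oracles import (ANOVA_SUMMARY_CASES, CHI2_CASES,
                               brute_force_bh)


@pytest.mark.parametrize("name", CHI2_CASES)
def test_chi_squared_reference_statistics(name):
    counts, expected = CHI2_CASES[name]
    res = chi_squared_test(counts, variable=name)
    assert res.statistic == pytest.approx(expected, abs=5e-4)
    assert res.df == (2,)


def test_chi_squared_four_center_table():
    res = chi_squared_test([[28, 14, 4, 3], [26, 12, 15, 23], [14, 3, 15, 8]])
    assert res.statistic == pytest.approx(27.800, abs=5e-3)
    assert res.df == (6,)


def test_chi_squared_independence_gives_zero():
    res = chi_squared_test([[10, 10], [10, 10]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_squared_validation():
    with pytest.raises(ValueError, match="integer"):
        chi_squared_test([[1.5, 2], [3, 4]])
    with pytest.raises(ValueError, match="margin"):
        chi_squared_test([[0, 5], [0, 7]])


# ---------------------------------------------------------------------------
# one-way ANOVA

@pytest.mark.parametrize("name", ANOVA_SUMMARY_CASES)
def test_summary_anova_reference_statistics(name):
    """F from printed per-group mean/SD/n; agreement is limited by the
    2-decimal rounding of the inputs (within 1.5%)."""
    summaries, expected = ANOVA_SUMMARY_CASES[name]
    res = oneway_anova(summaries=summaries, variable=name)
    assert res.statistic == pytest.approx(expected, rel=0.015)


def test_equal_means_give_zero_f():
    res = oneway_anova(summaries=[(5.0, 1.0, 10), (5.0, 2.0, 12),
                                  (5.0, 1.5, 8)])
    assert res.statistic == pytest.approx(0.0)


def test_summary_mode_equals_raw_mode_exactly():
    rng = np.random.default_rng(0)
    groups = [rng.normal(m, 1.0, n) for m, n in ((0, 12), (0.5, 20), (1.2, 9))]
    raw = oneway_anova(groups=groups)
    summ = oneway_anova(summaries=[(g.mean(), g.std(ddof=1), len(g))
                                   for g in groups])
    assert raw.statistic == summ.statistic
    assert raw.p_value == summ.p_value


def test_raw_anova_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(7)
    groups = [rng.normal(i, 2.0, n) for i, n in enumerate((15, 10, 20, 8))]
    res = oneway_anova(groups=groups)
    # independent two-pass oracle
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ssb / 3) / (ssw / (len(allv) - 4))
    assert abs(res.statistic - f) < 1e-10


def test_anova_zero_variance_error():
    with pytest.raises(ValueError, match="variance"):
        oneway_anova(summaries=[(1.0, 0.0, 5), (2.0, 0.0, 5)])


# ---------------------------------------------------------------------------
# FDR

def test_fdr_all_below_line_rejected():
    adj, reject = fdr_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05)
    assert reject.all()


def test_fdr_single_p_unchanged():
    adj, reject = fdr_bh([0.03])
    assert adj[0] == pytest.approx(0.03)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=1, max_size=10))
def test_fdr_matches_enumeration_oracle(pvals):
    adj, reject = fdr_bh(pvals, alpha=0.05)
    adj_o, reject_o = brute_force_bh(pvals, alpha=0.05)
    assert np.allclose(adj, adj_o)
    assert np.array_equal(reject, reject_o)


def test_fdr_rejects_bad_input():
    with pytest.raises(ValueError):
        fdr_bh([0.5, 1.2])


def test_fdr_null_calibration():
    """On uniform-null p-vectors of length 96 the realized false
    discovery proportion stays at or below alpha on average."""
    rng = np.random.default_rng(42)
    fdp = []
    for _ in range(1000):
        p = rng.random(96)
        _, reject = fdr_bh(p, alpha=0.05)
        fdp.append(reject.sum() > 0)
    # P(any rejection) under the global null is <= alpha for BH
    assert np.mean(fdp) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 1000)


# ---------------------------------------------------------------------------
# per-ROI ANCOVA

def _planted_ancova_data(rng, n=165, p=96, n_signal=20, effect=1.0):
    labels = rng.integers(1, 4, n)
    age = rng.normal(70, 8, n)
    X = rng.normal(0, 1, (n, p))
    X[labels == 1, :n_signal] -= effect
    cols = [f"roi{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), labels, age


def test_ancova_sensitivity_and_false_positives():
    """>= 90% of 20 planted ROIs flagged; false-positive rate among the
    null ROIs <= 0.05, averaged over 50 seeds."""
    rng = np.random.default_rng(100)
    sens, fpr = [], []
    for _ in range(50):
        vols, labels, age = _planted_ancova_data(rng)
        table = ancova_per_roi(vols, labels, age).table
        sig = table["significant"].to_numpy(bool)
        sens.append(sig[:20].mean())
        fpr.append(sig[20:].mean())
    assert np.mean(sens) >= 0.9
    assert np.mean(fpr) <= 0.05


def test_ancova_adjusts_out_age_signal():
    """Clusters differing only through an age-driven volume gradient are
    not flagged once age is in the model."""
    rng = np.random.default_rng(200)
    rates = []
    for _ in range(20):
        n = 165
        labels = np.repeat([1, 2, 3], (49, 76, 40))
        age = np.concatenate([rng.normal(74, 6, 49), rng.normal(69, 6, 76),
                              rng.normal(64, 6, 40)])
        X = rng.normal(0, 1, (n, 96)) - 0.1 * (age - 70)[:, None]
        vols = pd.DataFrame(X, columns=[f"roi{j}" for j in range(96)])
        table = ancova_per_roi(vols, labels, age).table
        rates.append(table["significant"].to_numpy(bool).mean())
    assert np.mean(rates) <= 0.05


def test_ancova_identical_volumes_no_rejections():
    labels = np.repeat([1, 2, 3], 10)
    age = np.linspace(60, 80, 30)
    vols = pd.DataFrame(np.ones((30, 4)), columns=list("abcd"))
    table = ancova_per_roi(vols, labels, age).table
    assert (table["f"] == 0).all()
    assert not table["significant"].to_numpy(bool).any()


def test_ancova_adjusted_p_monotone():
    rng = np.random.default_rng(5)
    vols, labels, age = _planted_ancova_data(rng, n=100, p=30, n_signal=5)
    table = ancova_per_roi(vols, labels, age).table
    assert (table["p_fdr"] >= table["p_raw"] - 1e-12).all()
    sig = table[table["significant"] == True]          # noqa: E712
    nonsig = table[table["significant"] == False]      # noqa: E712
    if len(sig) and len(nonsig):
        assert sig["p_raw"].max() <= nonsig["p_raw"].min()


# ---------------------------------------------------------------------------
# BG/cortical ratio

def test_ratio_closed_form(schema):
    n = 5
    df = pd.DataFrame(1.0, index=range(n), columns=schema.cortical)
    for roi in schema.basal_ganglia:
        df[roi] = 0.5
    for roi in schema.names:
        if roi not in df.columns:
            df[roi] = 2.0
    res = bg_cortical_ratio(df, schema, labels=np.ones(n, int))
    assert np.allclose(res.ratios, 3.0 / 82.0)


def test_ratio_scale_invariance(default_cohort, schema):
    r1 = bg_cortical_ratio(default_cohort, schema)
    doubled = default_cohort.copy()
    doubled[schema.names] = doubled[schema.names] * 2.0
    r2 = bg_cortical_ratio(doubled, schema)
    assert np.allclose(r1.ratios, r2.ratios)


def test_ratio_matches_row_sum_oracle(default_cohort, schema):
    res = bg_cortical_ratio(default_cohort, schema)
    for i in (0, 50, 120):
        row = default_cohort.iloc[i]
        expected = sum(row[r] for r in schema.basal_ganglia) / \
            sum(row[r] for r in schema.cortical)
        assert abs(res.ratios.iloc[i] - expected) < 1e-12
    assert ((res.ratios > 0) & (res.ratios < 1)).all()


def test_ratio_cluster_ordering_and_cis(default_cohort, schema):
    res = bg_cortical_ratio(default_cohort, schema,
                            labels=default_cohort["true_cluster"])
    means = res.cluster_stats.set_index("cluster")["mean"]
    assert means[1] > means[2] > means[3]
    pair13 = res.pairwise.query("cluster_a == 1 and cluster_b == 3").iloc[0]
    assert pair13["ci_low"] < pair13["mean_diff"] < pair13["ci_high"]
    assert pair13["p_value"] < 0.001


# ---------------------------------------------------------------------------
# comparison battery

def test_characterize_table_no_missing_n_equals_cluster_sizes(default_cohort):
    labels = default_cohort["true_cluster"].to_numpy()
    results = characterize_table(default_cohort, labels)
    byvar = {r.variable: r for r in results if r.test == "oneway-anova"}
    sizes = np.bincount(labels)[1:]
    assert byvar["age"].group_summaries["n"].tolist() == sizes.tolist()


def test_characterize_table_available_case(default_cohort):
    cohort = default_cohort.copy()
    cohort.loc[cohort.index[:5], "wmh"] = np.nan
    labels = cohort["true_cluster"].to_numpy()
    results = characterize_table(cohort, labels)
    wmh = [r for r in results if r.variable == "wmh"
           and r.test == "oneway-anova"][0]
    assert wmh.group_summaries["n"].sum() == len(cohort) - 5


def test_characterize_table_skips_absent_variable(default_cohort):
    cohort = default_cohort.drop(columns=["education"])
    with pytest.warns(UserWarning, match="education"):
        results = characterize_table(cohort, cohort["true_cluster"].to_numpy())
    assert "education" not in {r.variable for r in results}


def test_characterize_table_contains_adjusted_followups(default_cohort):
    labels = default_cohort["true_cluster"].to_numpy()
    results = characterize_table(default_cohort, labels)
    ancova_vars = {r.variable for r in results if r.test == "ancova"}
    assert {"mmse_00", "wmh"} <= ancova_vars
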