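"""ANOVA decompositions, chi-square with residual analysis and Cohen's w,
Holm adjustment, the median split, and Pearson correlation, checked against
from-scratch oracles, an independent library, and the printed demographic
tables."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vflda import (chisq_independence, median_split, mixed_anova,
                   oneway_anova, pearson_correlation)


# --- one-way ANOVA -------------------------------------------------------

def test_identical_groups_give_zero_F():
    res, _ = oneway_anova({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
    assert res.F == pytest.approx(0.0)
    assert res.partial_eta_sq == pytest.approx(0.0)


def test_oneway_matches_manual_sum_of_squares():
    samples = {"a": [2.0, 3.5, 4.0, 1.5], "b": [5.0, 6.5, 5.5], "c": [1.0, 0.5, 2.0]}
    res, _ = oneway_anova(samples)
    # from-scratch decomposition
    allv = np.concatenate([np.asarray(v) for v in samples.values()])
    grand = allv.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in samples.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in samples.values())
    F = (ssb / 2) / (ssw / (len(allv) - 3))
    from scipy.stats import f

    assert res.F == pytest.approx(F, abs=1e-10)
    assert res.p == pytest.approx(float(f.sf(F, 2, len(allv) - 3)), abs=1e-10)
    assert res.partial_eta_sq == pytest.approx(ssb / (ssb + ssw), abs=1e-10)
    assert res.df_effect == 2 and res.df_error == len(allv) - 3


def test_oneway_agrees_with_scipy():
    from scipy.stats import f_oneway

    rng = np.random.default_rng(1)
    samples = {g: rng.normal(loc=i, size=10) for i, g in enumerate("abc")}
    res, _ = oneway_anova(samples)
    ref = f_oneway(*samples.values())
    assert res.F == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-10)


def test_holm_adjusted_ps_dominate_raw_and_are_monotone():
    rng = np.random.default_rng(5)
    samples = {g: rng.normal(loc=0.4 * i, size=8) for i, g in enumerate("abcd")}
    _, table = oneway_anova(samples)
    t = table.sort_values("p_raw")
    assert (t["p_holm"].to_numpy() >= t["p_raw"].to_numpy() - 1e-15).all()
    assert (np.diff(t["p_holm"].to_numpy()) >= -1e-15).all()
    # Holm never exceeds plain Bonferroni
    m = len(table)
    assert (t["p_holm"] <= np.minimum(t["p_raw"] * m, 1.0) + 1e-15).all()


def test_oneway_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        oneway_anova({"a": [1.0], "b": [2.0, 3.0]})


# --- mixed (split-plot) ANOVA --------------------------------------------

def _long(y, groups):
    rows = []
    for i, (vals, g) in enumerate(zip(y, groups)):
        for p, v in enumerate(vals):
            rows.append({"subject": f"s{i}", "group": g, "phase": p + 1,
                         "value": float(v)})
    return pd.DataFrame(rows)


def test_phase_constant_data_has_zero_phase_and_interaction_F():
    y = [[3, 3, 3, 3], [5, 5, 5, 5], [4, 4, 4, 4], [6, 6, 6, 6]]
    res = mixed_anova(_long(y, ["a", "a", "b", "b"]))
    by = {r.effect: r for r in res}
    assert by["phase"].F == pytest.approx(0.0)
    assert by["group x phase"].F == pytest.approx(0.0)


def test_mixed_anova_matches_pingouin():
    """Independent cross-check of the split-plot decomposition."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    n = {"a": 7, "b": 6, "c": 5}
    rows = []
    for g, ng in n.items():
        base = {"a": 8.0, "b": 6.5, "c": 4.0}[g]
        for i in range(ng):
            subj_eff = rng.normal(0, 1)
            for p in range(4):
                rows.append({"subject": f"{g}{i}", "group": g, "phase": p + 1,
                             "value": base + subj_eff - 1.1 * p + rng.normal(0, 0.8)})
    data = pd.DataFrame(rows)
    ours = {r.effect: r for r in mixed_anova(data)}
    ref = pingouin.mixed_anova(data=data, dv="value", within="phase",
                               subject="subject", between="group")
    ref = ref.set_index("Source")
    for ours_key, ref_key in (("group", "group"), ("phase", "phase"),
                              ("group x phase", "Interaction")):
        assert ours[ours_key].F == pytest.approx(ref.loc[ref_key, "F"], rel=1e-8)
        assert ours[ours_key].p == pytest.approx(ref.loc[ref_key, "p_unc"], rel=1e-6)
        assert ours[ours_key].partial_eta_sq == pytest.approx(
            ref.loc[ref_key, "np2"], rel=1e-8)


def test_df_pattern_for_66_subjects_in_3_groups_4_phases():
    rng = np.random.default_rng(2)
    groups = ["young"] * 24 + ["older"] * 23 + ["ad"] * 19
    y = rng.poisson(5, size=(66, 4))
    res = mixed_anova(_long(y, groups))
    dfs = {r.effect: (r.df_effect, r.df_error) for r in res}
    assert dfs["group"] == (2, 63)
    assert dfs["phase"] == (3, 189)
    assert dfs["group x phase"] == (6, 189)


def test_mixed_anova_rejects_missing_phases():
    data = _long([[1, 2, 3, 4], [2, 3, 4, 5]], ["a", "b"]).iloc[:-1]
    with pytest.raises(ValueError, match="phase"):
        mixed_anova(data)


# --- chi-square -----------------------------------------------------------

def test_sex_by_group_table_reproduces_printed_statistic():
    """Female/male counts by the three study-like groups: chi2(2) = 1.1 at
    the printed precision."""
    res = chisq_independence([[13, 9, 9], [11, 14, 10]])
    assert res.df == 2
    assert res.chi2 == pytest.approx(1.1, abs=0.05)


def test_sex_by_subgroup_table_reproduces_printed_statistic():
    res = chisq_independence([[5, 4, 5, 4], [4, 10, 4, 6]])
    assert res.df == 3
    assert res.chi2 == pytest.approx(2.38, abs=0.01)
    assert res.w == pytest.approx(np.sqrt(res.chi2 / 42), abs=1e-12)


def test_proportional_table_gives_zero_chi2_and_w():
    res = chisq_independence([[10, 20, 30], [5, 10, 15]])
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.w == pytest.approx(0.0, abs=1e-12)
    assert res.significant_cells == []


def test_chi2_matches_direct_formula_on_all_small_2x2_tables():
    """Exhaustive oracle: every 2x2 table with entries in 1..6 agrees with
    sum (O-E)^2 / E to 1e-10."""
    for a, b, c, d in itertools.product(range(1, 7), repeat=4):
        obs = np.array([[a, b], [c, d]], dtype=float)
        res = chisq_independence(obs)
        N = obs.sum()
        row = obs.sum(axis=1)
        col = obs.sum(axis=0)
        expected = np.outer(row, col) / N
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.w == pytest.approx(np.sqrt(chi2 / N), abs=1e-10)


def test_scaling_all_cells_scales_chi2_and_keeps_residual_signs():
    obs = np.array([[8, 2], [3, 9]], dtype=float)
    base = chisq_independence(obs)
    scaled = chisq_independence(5 * obs)
    assert scaled.chi2 == pytest.approx(5 * base.chi2, abs=1e-9)
    assert np.array_equal(np.sign(scaled.adjusted_residuals),
                          np.sign(base.adjusted_residuals))


def test_residual_analysis_flags_deviant_cells():
    # strong diagonal excess: all four cells exceed |z| = 1.96
    res = chisq_independence([[20, 2], [3, 25]])
    assert set(res.significant_cells) == {(0, 0), (0, 1), (1, 0), (1, 1)}


def test_degenerate_table_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        chisq_independence([[0, 0], [1, 2]])


# --- median split ---------------------------------------------------------

def test_median_split_direct_rule():
    sg = median_split({"s1": 0, "s2": 0, "s3": 1, "s4": 2}, "older")
    assert sg.median_cutoff == 0.5
    assert sg.assignments == {"s1": "low_error", "s2": "low_error",
                              "s3": "high_error", "s4": "high_error"}


def test_all_zero_totals_puts_everyone_in_high_error_subgroup():
    sg = median_split({f"s{i}": 0 for i in range(5)}, "older")
    assert sg.median_cutoff == 0.0
    assert set(sg.assignments.values()) == {"high_error"}


def test_median_split_reproduces_study_like_cutoffs():
    """AD-like totals (9 low-error / 10 high-error subjects shaped like the
    printed subgroup means) give the printed cutoff of 1; for the odd-sized
    older-like group the printed 0.5 cutoff partitions integer scores
    identically to the computed median rule."""
    ad_totals = {f"ad{i}": v for i, v in enumerate(
        [0, 0, 0, 0, 0, 0, 1, 1, 1] +          # low-error, mean ~0.3
        [1, 1, 1, 1, 2, 2, 2, 2, 3, 3])}        # high-error, mean 1.8
    sg = median_split(ad_totals, "ad")
    assert sg.median_cutoff == 1.0
    assert sum(a == "high_error" for a in sg.assignments.values()) == 13

    older_totals = {f"c{i}": v for i, v in enumerate(
        [0] * 9 + [1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 3])}
    sg = median_split(older_totals, "older")
    by_half = {s: ("high_error" if v >= 0.5 else "low_error")
               for s, v in older_totals.items()}
    assert sg.assignments == by_half


# --- Pearson correlation ----------------------------------------------------

def test_pearson_correlation_known_cases():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson_correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
    assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)
    assert pearson_correlation(x, [5.0] * 4) is None
    with pytest.raises(ValueError):
        pearson_correlation([1, 2], [3, 4])


def test_pearson_matches_direct_covariance_formula():
    rng = np.random.default_rng(4)
    x = rng.normal(size=14)
    y = 0.5 * x + rng.normal(size=14)
    r = pearson_correlation(x, y)
    direct = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
    assert r == pytest.approx(direct, abs=1e-12)
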