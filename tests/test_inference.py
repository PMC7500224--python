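"""ANOVA, t-tests, correlations, and dependent-correlation comparison
against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psyflex import (ConfigurationError, bonferroni_alpha,
                     compare_dependent_overlapping, correlate,
                     normality_gate, paired_t_hedges, partial_correlation,
                     rm_anova, run_battery)


def _long(values):
    """subjects x conditions matrix -> long-format frame."""
    n, k = values.shape
    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "condition": np.tile([f"c{j}" for j in range(k)], n),
        "value": values.ravel(),
    })


def _oneway_ss_oracle(values):
    """Classical within-subject sums of squares, computed directly."""
    n, k = values.shape
    grand = values.mean()
    ss_cond = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    return F, df1, df2, ss_cond / (ss_cond + ss_err)


def test_oneway_rm_anova_matches_ss_oracle():
    rng = np.random.default_rng(3)
    values = rng.normal(0, 1, (5, 3)) + np.array([0.0, 0.6, 1.1])
    res = rm_anova(_long(values), dv="value", within="condition")[0]
    F, df1, df2, np2 = _oneway_ss_oracle(values)
    assert res.F == pytest.approx(F)
    assert (res.df_effect, res.df_error) == (df1, df2)
    assert res.partial_eta_sq == pytest.approx(np2)
    assert res.p == pytest.approx(stats.f.sf(F, df1, df2))


def test_sphericity_correction_changes_p_not_F():
    rng = np.random.default_rng(5)
    values = rng.normal(0, 1, (10, 3)) * np.array([1.0, 1.5, 3.0]) \
        + np.array([0.0, 0.4, 0.9])
    plain = rm_anova(_long(values), dv="value", within="condition")[0]
    gg = rm_anova(_long(values), dv="value", within="condition",
                  sphericity_correction=True)[0]
    assert gg.F == plain.F
    assert gg.p != plain.p   # heterogeneous variances break sphericity


def test_identical_conditions_give_zero_F():
    values = np.tile(np.arange(5.0)[:, None], (1, 3))  # subject effect only
    res = rm_anova(_long(values), dv="value", within="condition")[0]
    assert res.F == pytest.approx(0.0, abs=1e-10)
    assert res.partial_eta_sq == pytest.approx(0.0, abs=1e-10)


def test_two_by_two_anova_matches_oracle():
    rng = np.random.default_rng(8)
    n = 12
    cells = {}
    for a in (0, 1):
        for b in (0, 1):
            cells[(a, b)] = rng.normal(0.5 * a + 0.3 * b + 0.4 * a * b, 1, n)
    rows = []
    for (a, b), vals in cells.items():
        for s, v in enumerate(vals):
            rows.append({"subject": s, "A": f"a{a}", "B": f"b{b}", "value": v})
    df = pd.DataFrame(rows)
    results = {r.effect: r for r in rm_anova(df, dv="value", within=["A", "B"])}
    assert set(results) == {"A", "B", "A * B"}
    # hand oracle for the interaction: t-test on the double difference
    dd = (cells[(1, 1)] - cells[(1, 0)]) - (cells[(0, 1)] - cells[(0, 0)])
    t = dd.mean() / (dd.std(ddof=1) / np.sqrt(n))
    assert results["A * B"].F == pytest.approx(t ** 2, rel=1e-6)
    assert results["A * B"].df_effect == 1
    assert results["A * B"].df_error == n - 1
    np2 = t ** 2 / (t ** 2 + (n - 1))
    assert results["A * B"].partial_eta_sq == pytest.approx(np2, rel=1e-6)


def test_paired_t_matches_textbook_oracle():
    x = np.array([5.1, 4.8, 6.0, 5.5, 5.9, 4.7, 5.2, 6.1, 5.0, 5.6])
    y = np.array([4.9, 4.5, 5.2, 5.6, 5.1, 4.2, 5.0, 5.3, 4.6, 5.2])
    d = x - y
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(10))
    g_oracle = d.mean() / d.std(ddof=1) * (1 - 3 / (4 * 9 - 1))
    res = paired_t_hedges(x, y)
    assert res.t == pytest.approx(t_oracle)
    assert res.hedges_g == pytest.approx(g_oracle)
    assert res.df == 9
    assert np.sign(res.t) == np.sign(d.mean())


def test_identical_vectors_give_zero_t_and_g():
    x = np.arange(8.0)
    res = paired_t_hedges(x, x.copy())
    assert res.t == 0.0 and res.hedges_g == 0.0 and res.p == 1.0


def test_constant_nonzero_difference_flagged():
    x = np.arange(8.0) + 2.0
    res = paired_t_hedges(x, np.arange(8.0))
    assert np.isnan(res.t)
    assert res.warnings


def test_normality_gate_levels():
    """Normal samples pass at least 90/100 seeds; a lognormal sample fails."""
    passes = sum(
        normality_gate(np.random.default_rng(s).standard_normal(100)) == "normal"
        for s in range(100))
    assert passes >= 90
    skewed = np.exp(np.random.default_rng(1).standard_normal(100) * 1.5)
    assert normality_gate(skewed) == "non_normal"


def test_normality_gate_constant_errors():
    with pytest.raises(ConfigurationError):
        normality_gate(np.ones(30))


def test_correlate_directionality():
    x = np.linspace(0, 1, 30)
    res = correlate(x, x, direction="positive")
    assert res.r == pytest.approx(1.0)
    assert res.p_one_sided < 1e-20
    res = correlate(x, -x, direction="positive")
    assert res.p_one_sided > 0.999
    res = correlate(x, -x, direction="negative")
    assert res.p_one_sided < 1e-20


def test_spearman_with_ties_matches_rank_oracle():
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
    y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 9.0, 7.0, 8.0])
    res = correlate(x, y, method="spearman")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]   # tie-corrected brute force
    assert res.r == pytest.approx(oracle)


def test_one_sided_p_is_half_two_sided_in_direction():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(40)
    y = 0.4 * x + rng.standard_normal(40)
    one = correlate(x, y, sided="one", direction="positive")
    two = correlate(x, y, sided="two")
    assert one.p_one_sided == pytest.approx(two.p_one_sided / 2)


def test_fisher_ci_contains_r(small_indices):
    t = small_indices
    res = correlate(t["sc_rt_cog"], t["sc_rt_aff_gender"])
    assert res.ci95[0] < res.r < res.ci95[1]


@pytest.mark.parametrize("alpha, m, expected", [
    (0.05, 3, 0.05 / 3),   # printed .017
    (0.05, 2, 0.025),
    (0.05, 1, 0.05),
])
def test_bonferroni_alpha(alpha, m, expected):
    assert bonferroni_alpha(alpha, m) == pytest.approx(expected)


def test_dependent_comparison_trivial_cases():
    res = compare_dependent_overlapping(0.4, 0.4, 0.3, 50)
    assert res.t == 0.0 and res.p_two_sided == 1.0
    a = compare_dependent_overlapping(0.49, 0.35, 0.3, 93)
    b = compare_dependent_overlapping(0.35, 0.49, 0.3, 93)
    assert a.t == pytest.approx(-b.t)
    assert a.p_two_sided == pytest.approx(b.p_two_sided)
    assert a.df == 90


def test_dependent_comparison_matches_williams_formula():
    """Correlations measured from constructed data, statistic vs an
    independently coded Williams/Steiger oracle."""
    rng = np.random.default_rng(44)
    n = 93
    z = rng.standard_normal(n)
    x1 = z + 0.8 * rng.standard_normal(n)
    x2 = 0.9 * z + rng.standard_normal(n)
    x3 = 0.5 * z + rng.standard_normal(n)
    r12 = np.corrcoef(x1, x2)[0, 1]
    r13 = np.corrcoef(x1, x3)[0, 1]
    r23 = np.corrcoef(x2, x3)[0, 1]
    res = compare_dependent_overlapping(r12, r13, r23, n)
    detR = (1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23)
    rbar = (r12 + r13) / 2
    t_oracle = (r12 - r13) * np.sqrt(
        (n - 1) * (1 + r23)
        / (2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3))
    assert res.t == pytest.approx(t_oracle, rel=1e-10)
    assert res.p_two_sided == pytest.approx(2 * stats.t.sf(abs(t_oracle), 90))


def test_dependent_comparison_rejects_non_psd():
    with pytest.raises(ConfigurationError):
        compare_dependent_overlapping(0.9, -0.9, 0.9, 50)


def test_partial_correlation_oracles():
    rng = np.random.default_rng(6)
    n = 80
    c = rng.standard_normal(n)
    # covariate orthogonalized against span(1, x, y): partial == zero-order
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    B = np.column_stack([np.ones(n), x, y])
    c = c - B @ np.linalg.lstsq(B, c, rcond=None)[0]
    res = partial_correlation(x, y, c)
    zero_order = np.corrcoef(x, y)[0, 1]
    assert res.r == pytest.approx(zero_order, abs=1e-10)
    # y equal to the covariate: partial r ~ 0
    res = partial_correlation(x, y, y)
    assert res.r == pytest.approx(0.0, abs=1e-10)
    # x = y: partial r = 1
    res = partial_correlation(x, x, c)
    assert res.r == pytest.approx(1.0)


def test_partial_correlation_matches_pingouin():
    import pingouin as pg
    rng = np.random.default_rng(13)
    n = 60
    c = rng.standard_normal(n)
    x = 0.6 * c + rng.standard_normal(n)
    y = 0.4 * c + 0.3 * x + rng.standard_normal(n)
    res = partial_correlation(x, y, c, sided="two")
    df = pd.DataFrame({"x": x, "y": y, "c": c})
    oracle = pg.partial_corr(df, x="x", y="y", covar="c")
    p_col = "p_val" if "p_val" in oracle.columns else "p-val"
    assert res.r == pytest.approx(float(oracle["r"].iloc[0]), abs=1e-8)
    assert res.p_one_sided == pytest.approx(float(oracle[p_col].iloc[0]),
                                            abs=1e-8)


def test_battery_structure(small_indices):
    out = run_battery(small_indices)
    assert len(out) == 14
    assert set(out["family"]) == {"H1", "H1b", "H2", "H3a", "H3b", "H5"}
    h1 = out[out["family"] == "H1"]
    assert np.allclose(h1["alpha_adjusted"], 0.05 / 3)
    assert ((out["method"] == "pearson") | (out["method"] == "spearman")).all()
    assert (out["p_one_sided"].between(0, 1)).all()
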