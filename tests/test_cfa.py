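"""One-factor CFA and its assumption diagnostics."""

import numpy as np
import pandas as pd
import pytest

from psyflex import (ConfigurationError, assumption_checks,
                     bartlett_sphericity, fit_one_factor, kmo, mardia)

LAMBDA = np.array([0.8, 0.6, 0.4, 0.7, 0.5])
COLS = [f"ind{k}" for k in range(5)]


def _factor_sample(lam, n, rng):
    eta = rng.standard_normal(n)
    X = np.column_stack([l * eta + np.sqrt(1 - l * l) * rng.standard_normal(n)
                         for l in lam])
    return pd.DataFrame(X, columns=COLS[:len(lam)])


def test_population_covariance_recovery():
    """Exact one-factor covariance: loadings recovered to +/-.02, perfect fit."""
    Sigma = np.outer(LAMBDA, LAMBDA) + np.diag(1 - LAMBDA ** 2)
    S = pd.DataFrame(Sigma, index=COLS, columns=COLS)
    res = fit_one_factor(S, data_is_covariance=True, n_obs=100000)
    assert res.converged
    assert np.abs(res.loadings - LAMBDA).max() < 0.02
    assert res.rmsea < 0.01
    assert res.cfi == pytest.approx(1.0, abs=1e-6)
    assert res.chi_sq == pytest.approx(0.0, abs=1e-6)


def test_independent_indicators_give_zero_loadings():
    """Zero-loading truth. At the exact identity matrix the loadings are
    unidentified (any single loading with complementary uniqueness fits
    perfectly), so the meaningful checks are at finite n: each loading stays
    at the n**-0.25 scale (square root of correlation noise) and the implied
    correlations stay at correlation-noise scale."""
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.standard_normal((10000, 5)), columns=COLS)
    res = fit_one_factor(X)
    assert np.abs(res.loadings).max() < 3 * 10000 ** -0.25
    # implied correlations stay at correlation-noise scale
    implied = np.outer(res.loadings, res.loadings)
    assert np.abs(implied[~np.eye(5, dtype=bool)]).max() < 0.03


def test_model_degrees_of_freedom():
    Sigma = np.outer(LAMBDA, LAMBDA) + np.diag(1 - LAMBDA ** 2)
    S = pd.DataFrame(Sigma, index=COLS, columns=COLS)
    res = fit_one_factor(S, data_is_covariance=True, n_obs=500)
    assert res.df_model == 5   # 15 moments - 10 parameters


def test_perfect_fit_indices_when_chi_below_df():
    rng = np.random.default_rng(3)
    res = fit_one_factor(_factor_sample(LAMBDA, 4000, rng))
    if res.chi_sq <= res.df_model:
        assert res.cfi == pytest.approx(1.0, abs=1e-6)
        assert res.rmsea == 0.0
    # sampling may push chi above df; the invariant is conditional, so force
    # it with the exact population matrix as well
    Sigma = np.outer(LAMBDA, LAMBDA) + np.diag(1 - LAMBDA ** 2)
    S = pd.DataFrame(Sigma, index=COLS, columns=COLS)
    exact = fit_one_factor(S, data_is_covariance=True, n_obs=1000)
    assert exact.cfi == pytest.approx(1.0, abs=1e-6)
    assert exact.tli >= 1.0 - 1e-6
    assert exact.rmsea == 0.0


def test_sign_flip_invariance():
    rng = np.random.default_rng(11)
    data = _factor_sample(LAMBDA, 2000, rng)
    res = fit_one_factor(data)
    flipped = data.copy()
    flipped[COLS[1]] = -flipped[COLS[1]]
    res_f = fit_one_factor(flipped)
    expect = res.loadings.copy()
    expect[1] = -expect[1]
    assert np.abs(np.abs(res_f.loadings) - np.abs(expect)).max() < 1e-3
    assert res_f.chi_sq == pytest.approx(res.chi_sq, abs=1e-6)


def test_finite_sample_standard_errors_cover_truth():
    """z = beta/se; across replicates the truth falls inside +/-2 SE most of
    the time (coarse calibration check)."""
    rng = np.random.default_rng(21)
    hits = 0
    total = 0
    for _ in range(20):
        res = fit_one_factor(_factor_sample(LAMBDA, 400, rng))
        hits += int(np.sum(np.abs(res.loadings - LAMBDA) < 2 * res.se))
        total += 5
    assert hits / total > 0.85


def test_mlm_scaling_near_one_for_normal_data():
    rng = np.random.default_rng(2)
    res = fit_one_factor(_factor_sample(LAMBDA, 3000, rng), estimator="mlm")
    assert res.scaling_factor == pytest.approx(1.0, abs=0.15)
    assert res.chi_sq > 0 or res.df_model == 5


def _elliptical_sample(n, rng):
    """Exactly one-factor covariance, but a shared random scale per
    observation (elliptical scale mixture) so fourth moments are dependent
    and the normal-theory chi-square is genuinely inflated."""
    eta = rng.standard_normal(n)
    u = rng.standard_normal((n, 5))
    X = np.column_stack([l * eta + np.sqrt(1 - l * l) * u[:, i]
                         for i, l in enumerate(LAMBDA)])
    s = np.where(rng.random(n) < 0.1, 2.0, 1.0) / np.sqrt(0.9 + 0.1 * 4)
    return pd.DataFrame(X * s[:, None], columns=COLS)


def test_mlm_scaling_predicts_mean_statistic():
    """The Satorra-Bentler factor's defining property: under an exactly
    fitting model, E[T_ML] = c * df. An elliptical scale mixture gives
    c ~ 1.5, clearly separated from the naive df."""
    rng = np.random.default_rng(0)
    big = fit_one_factor(_elliptical_sample(60000, rng), estimator="mlm")
    c = big.scaling_factor
    assert c > 1.2
    chis = [fit_one_factor(_elliptical_sample(400,
                                              np.random.default_rng(10_000 + s)),
                           estimator="ml").chi_sq for s in range(120)]
    mean_chi = np.mean(chis)
    se = np.std(chis) / np.sqrt(len(chis))
    assert abs(mean_chi - c * 5) < max(3 * se, 0.12 * c * 5)
    assert abs(mean_chi - c * 5) < abs(mean_chi - 5)


def test_kmo_matches_equicorrelation_oracle():
    """Equicorrelated population matrix: every partial correlation is
    rho / (1 + (p-2) rho), giving a closed-form KMO."""
    p, rho = 5, 0.5
    R = np.full((p, p), rho)
    np.fill_diagonal(R, 1.0)
    overall, per = kmo(R)
    partial = rho / (1 + (p - 2) * rho)
    oracle = rho ** 2 / (rho ** 2 + partial ** 2)
    assert overall == pytest.approx(oracle, abs=1e-10)
    assert np.allclose(per, oracle)


def test_bartlett_identity_population():
    R = np.eye(5)
    chi, df, p = bartlett_sphericity(R, n=200)
    assert chi == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)
    assert df == 10


def test_kmo_undefined_for_identity():
    with pytest.raises(ConfigurationError):
        kmo(np.eye(4))


def test_mardia_level_under_normality():
    """Multivariate normal samples: both Mardia tests non-significant at
    alpha = .01 in >= 95% of seeded replicates."""
    ok = 0
    reps = 100
    for s in range(reps):
        rng = np.random.default_rng(1000 + s)
        X = rng.standard_normal((500, 5))
        sk, sk_p, ku, ku_p = mardia(X)
        ok += int(sk_p > 0.01 and ku_p > 0.01)
    assert ok >= 95


def test_mardia_detects_skew():
    rng = np.random.default_rng(4)
    X = np.exp(rng.standard_normal((1000, 4)))
    sk, sk_p, ku, ku_p = mardia(X)
    assert sk_p < 1e-6


def test_assumption_checks_report(small_indices):
    from psyflex.population import FACTOR_INDICATORS
    rep = assumption_checks(small_indices, indicators=list(FACTOR_INDICATORS))
    assert 0.0 <= rep.kmo_overall <= 1.0
    assert rep.bartlett_df == 10
    assert rep.bartlett_p <= 1.0


def test_singular_matrix_rejected():
    X = pd.DataFrame(np.random.default_rng(0).standard_normal((50, 3)),
                     columns=["a", "b", "c"])
    X["d"] = X["a"] + X["b"]          # exactly collinear
    with pytest.raises((ConfigurationError, np.linalg.LinAlgError)):
        rep = assumption_checks(X)
        # a numerically non-singular inverse must still flag nonsense
        if not (0 <= rep.kmo_overall <= 1):
            raise ConfigurationError("invalid KMO")


def test_heywood_case_flagged():
    """A near-singular two-factor structure forced into one factor can push
    a uniqueness to the bound; the result carries a warning, not a crash."""
    rng = np.random.default_rng(17)
    n = 500
    f = rng.standard_normal(n)
    X = pd.DataFrame({
        "a": f + 0.01 * rng.standard_normal(n),
        "b": f + 0.01 * rng.standard_normal(n),
        "c": 0.3 * f + rng.standard_normal(n),
        "d": 0.2 * f + rng.standard_normal(n),
        "e": 0.1 * f + rng.standard_normal(n),
    })
    res = fit_one_factor(X)
    assert res.converged or res.warnings
    assert np.all(res.uniquenesses >= 0)
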