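"""One-factor confirmatory factor analysis with assumption checks.

Model: for p z-standardized indicators, ``Sigma(theta) = lambda lambda' +
Psi`` with a single latent variable of unit variance (so the loadings are
standardized) and diagonal unique variances ``Psi``. Estimation minimizes
the normal-theory ML discrepancy

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p

over the sample correlation matrix S; the model chi-square is
``(n - 1) F_min`` with ``p(p+1)/2 - 2p`` degrees of freedom. Standard
errors come from the inverse information ``(n - 1)/2 * d2F/dtheta2``.
CFI/TLI are computed against the independence baseline and RMSEA with a
90% CI by inverting the non-central chi-square distribution.

``estimator="mlm"`` additionally applies a Satorra-Bentler mean scaling:
the chi-square is divided by ``c = tr(U Gamma) / df`` where ``Gamma`` is
the asymptotic (distribution-free, fourth-moment) covariance of the sample
covariances and ``U`` the normal-theory residual weight matrix; the
baseline statistic is scaled the same way before computing robust
CFI/TLI/RMSEA. Scaling conventions differ slightly across software; this
implementation follows the formula above.

Unique variances are bounded at zero; a solution on the bound is flagged
as a Heywood case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError


@dataclass
class CFAResult:
    indicators: list[str]
    loadings: np.ndarray           # standardized (beta)
    uniquenesses: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    chi_sq: float
    df_model: int
    p_model: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    n: int
    converged: bool
    estimator: str
    scaling_factor: float | None = None
    warnings: list[str] = field(default_factory=list)

    def loading_table(self) -> pd.DataFrame:
        """Indicator / Beta / SE / Z / p table."""
        return pd.DataFrame({
            "indicator": self.indicators, "beta": self.loadings,
            "se": self.se, "z": self.z, "p": self.p_values,
        }).set_index("indicator")


@dataclass
class AssumptionReport:
    kmo_overall: float
    kmo_per_indicator: pd.Series
    bartlett_chi_sq: float
    bartlett_df: int
    bartlett_p: float
    mardia_skewness_stat: float
    mardia_skewness_p: float
    mardia_kurtosis_stat: float
    mardia_kurtosis_p: float
    kmo_ci: tuple[float, float] | None = None


def _sigma(lam: np.ndarray, psi: np.ndarray) -> np.ndarray:
    return np.outer(lam, lam) + np.diag(psi)


def _ml_discrepancy(theta: np.ndarray, S: np.ndarray, p: int) -> float:
    lam, psi = theta[:p], theta[p:]
    sigma = _sigma(lam, psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10
    sign_s, logdet_s = np.linalg.slogdet(S)
    return float(logdet + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps * eps)
    return H


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix: vech(A) -> vec(A) for symmetric A."""
    rows = []
    idx = {}
    k = 0
    for j in range(p):
        for i in range(j, p):
            idx[(i, j)] = k
            k += 1
    D = np.zeros((p * p, k))
    for j in range(p):
        for i in range(p):
            D[j * p + i, idx[(max(i, j), min(i, j))]] = 1.0
    return D


def _vech(A: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    return np.concatenate([A[j:, j] for j in range(p)])


def _sb_scaling(X: np.ndarray, S: np.ndarray, lam: np.ndarray,
                psi: np.ndarray, df: int) -> float:
    """Satorra-Bentler mean-scaling factor tr(U Gamma) / df."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    # ADF Gamma: covariance of vech(x x') across observations
    vechs = np.array([_vech(np.outer(x, x)) for x in Xc])
    Gamma = np.cov(vechs, rowvar=False, ddof=1)
    sigma = _sigma(lam, psi)
    sigma_inv = np.linalg.inv(sigma)
    D = _duplication(p)
    Dplus = np.linalg.pinv(D)
    W = 0.5 * D.T @ np.kron(sigma_inv, sigma_inv) @ D
    # Jacobian of vech(Sigma) in (lambda, psi)
    k = p * (p + 1) // 2
    Delta = np.zeros((k, 2 * p))
    for j in range(p):
        dlam = np.zeros((p, p))
        dlam[j, :] = lam
        dlam[:, j] += lam
        Delta[:, j] = _vech(dlam)
        dpsi = np.zeros((p, p))
        dpsi[j, j] = 1.0
        Delta[:, p + j] = _vech(dpsi)
    WD = W @ Delta
    U = W - WD @ np.linalg.pinv(Delta.T @ WD) @ WD.T
    return float(np.trace(U @ Gamma) / df)


def _fit_indices(chi: float, df: int, chi_b: float, df_b: int,
                 n: int) -> tuple[float, float, float, tuple[float, float]]:
    d = max(chi - df, 0.0)
    d_b = max(chi_b - df_b, 0.0)
    cfi = 1.0 - (d / d_b if d_b > 0 else 0.0)
    cfi = min(max(cfi, 0.0), 1.0)
    if df > 0 and df_b > 0 and chi_b / df_b != 1.0:
        tli = ((chi_b / df_b) - (chi / df)) / ((chi_b / df_b) - 1.0)
    else:
        tli = 1.0
    if chi <= df:
        tli = min(tli, 1.0) if tli <= 1.0 else tli  # TLI may exceed 1
    rmsea = np.sqrt(d / (df * (n - 1))) if df > 0 else 0.0

    def _ci_bound(prob: float) -> float:
        # non-centrality nc with ncx2.cdf(chi; df, nc) == prob
        if stats.ncx2.cdf(chi, df, 0.0) < prob:
            return 0.0
        hi = max(chi * 2, df * 5, 10.0)
        while stats.ncx2.cdf(chi, df, hi) > prob and hi < 1e7:
            hi *= 2
        nc = optimize.brentq(lambda x: stats.ncx2.cdf(chi, df, x) - prob,
                             0.0, hi)
        return float(np.sqrt(nc / (df * (n - 1))))

    ci = (_ci_bound(0.95), _ci_bound(0.05)) if df > 0 else (0.0, 0.0)
    return float(cfi), float(tli), float(rmsea), ci


def fit_one_factor(index_table: pd.DataFrame,
                   indicators: list[str] | None = None,
                   estimator: str = "ml",
                   data_is_covariance: bool = False,
                   n_obs: int | None = None) -> CFAResult:
    """Fit the one-factor model to z-standardized indicators.

    ``index_table`` is a subjects x indicators frame (listwise deletion is
    applied), or a covariance/correlation matrix when
    ``data_is_covariance=True`` (then ``n_obs`` is required and the MLM
    estimator is unavailable).
    """
    if estimator not in ("ml", "mlm"):
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    if data_is_covariance:
        if n_obs is None:
            raise ConfigurationError("n_obs required with covariance input")
        if estimator == "mlm":
            raise ConfigurationError("mlm needs raw data (fourth moments)")
        cols = indicators or list(index_table.columns)
        S = np.asarray(index_table.loc[cols, cols], dtype=float)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)   # standardize
        n = int(n_obs)
        X = None
    else:
        cols = indicators or list(index_table.columns)
        data = index_table[cols].dropna()
        n = len(data)
        X = data.to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        S = np.corrcoef(X, rowvar=False)
    p = len(cols)
    if p < 3:
        raise ConfigurationError("one-factor model needs >= 3 indicators")
    if n <= p:
        raise ConfigurationError("need more observations than indicators")
    df = p * (p + 1) // 2 - 2 * p

    # start at the first principal component solution
    evals, evecs = np.linalg.eigh(S)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 0.1))
    if lam0.sum() < 0:
        lam0 = -lam0
    psi0 = np.clip(1.0 - lam0 ** 2, 0.05, None)
    theta0 = np.concatenate([lam0, psi0])
    bounds = [(-3.0, 3.0)] * p + [(1e-6, 10.0)] * p
    res = optimize.minimize(_ml_discrepancy, theta0, args=(S, p),
                            method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 2000, "ftol": 1e-12,
                                     "gtol": 1e-10})
    warnings: list[str] = []
    lam, psi = res.x[:p], res.x[p:]
    if lam.sum() < 0:
        lam = -lam  # sign indeterminacy: report positively oriented factor
    if np.any(psi <= 2e-6):
        warnings.append("Heywood case: unique variance bounded at zero")
    if np.any(np.abs(lam) > 1.0):
        warnings.append("standardized loading outside [-1, 1]")
    converged = bool(res.success)
    if not converged:
        warnings.append(f"optimizer did not converge: {res.message}")

    chi = max(float((n - 1) * res.fun), 0.0)
    p_model = float(stats.chi2.sf(chi, df)) if df > 0 else 1.0
    sign_s, logdet_s = np.linalg.slogdet(S)
    chi_b = float(-(n - 1) * logdet_s)    # independence baseline on R
    df_b = p * (p - 1) // 2

    H = _numerical_hessian(lambda th: _ml_discrepancy(th, S, p),
                           np.concatenate([lam, psi]))
    try:
        acov = 2.0 / (n - 1) * np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(acov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(2 * p, np.nan)
        warnings.append("information matrix singular; SEs unavailable")
    se = se_all[:p]

    scaling = None
    if estimator == "mlm":
        c = _sb_scaling(X, S, lam, psi, df)
        if c <= 0 or not np.isfinite(c):
            warnings.append("non-positive SB scaling factor; fell back to ML")
        else:
            scaling = c
            chi = chi / c
            p_model = float(stats.chi2.sf(chi, df)) if df > 0 else 1.0
            # scale the baseline with its own factor (diagonal model)
            cb = _sb_scaling_baseline(X, df_b)
            if cb > 0 and np.isfinite(cb):
                chi_b = chi_b / cb

    cfi, tli, rmsea, ci = _fit_indices(chi, df, chi_b, df_b, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lam / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CFAResult(indicators=list(cols), loadings=lam, uniquenesses=psi,
                     se=se, z=z, p_values=pvals, chi_sq=chi, df_model=df,
                     p_model=p_model, cfi=cfi, tli=tli, rmsea=rmsea,
                     rmsea_ci90=ci, n=n, converged=converged,
                     estimator=estimator, scaling_factor=scaling,
                     warnings=warnings)


def _sb_scaling_baseline(X: np.ndarray, df_b: int) -> float:
    """SB scaling factor for the independence (diagonal Sigma) baseline."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    vechs = np.array([_vech(np.outer(x, x)) for x in Xc])
    Gamma = np.cov(vechs, rowvar=False, ddof=1)
    sigma_inv = np.eye(p)   # baseline Sigma = I on standardized data
    D = _duplication(p)
    W = 0.5 * D.T @ np.kron(sigma_inv, sigma_inv) @ D
    k = p * (p + 1) // 2
    # baseline free parameters: the p diagonal entries
    Delta = np.zeros((k, p))
    for j in range(p):
        dpsi = np.zeros((p, p))
        dpsi[j, j] = 1.0
        Delta[:, j] = _vech(dpsi)
    WD = W @ Delta
    U = W - WD @ np.linalg.pinv(Delta.T @ WD) @ WD.T
    return float(np.trace(U @ Gamma) / df_b)


def kmo(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy (overall, per indicator).

    Uses the anti-image (partial) correlation matrix from the inverse of R.
    """
    R = np.asarray(R, dtype=float)
    off = ~np.eye(R.shape[0], dtype=bool)
    if np.allclose(R[off], 0.0):
        raise ConfigurationError("KMO undefined: all off-diagonal "
                                 "correlations are zero")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise ConfigurationError("singular correlation matrix") from e
    d = 1.0 / np.sqrt(np.diag(Rinv))
    partial = -Rinv * np.outer(d, d)
    r2 = (R ** 2)[off].reshape(R.shape[0], -1)
    p2 = (partial ** 2)[off].reshape(R.shape[0], -1)
    per = r2.sum(axis=1) / (r2.sum(axis=1) + p2.sum(axis=1))
    overall = r2.sum() / (r2.sum() + p2.sum())
    return float(overall), per


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that R is an identity matrix."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ConfigurationError("singular correlation matrix")
    chi = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi), df, float(stats.chi2.sf(chi, df))


def mardia(X: np.ndarray) -> tuple[float, float, float, float]:
    """Mardia's multivariate skewness and kurtosis tests.

    Returns (skewness chi-square statistic, its p, kurtosis z, its p).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    Sinv = np.linalg.inv(S)
    M = Xc @ Sinv @ Xc.T
    b1 = float((M ** 3).sum()) / (n * n)
    skew_stat = n * b1 / 6.0
    df_skew = p * (p + 1) * (p + 2) / 6.0
    skew_p = float(stats.chi2.sf(skew_stat, df_skew))
    b2 = float(np.mean(np.diag(M) ** 2))
    kurt_z = (b2 - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    kurt_p = float(2 * stats.norm.sf(abs(kurt_z)))
    return float(skew_stat), skew_p, float(kurt_z), kurt_p


def assumption_checks(index_table: pd.DataFrame,
                      indicators: list[str] | None = None,
                      kmo_bootstrap: int | None = None,
                      seed: int | None = None) -> AssumptionReport:
    """KMO, Bartlett sphericity, and Mardia multivariate normality.

    ``kmo_bootstrap`` requests an optional percentile bootstrap CI for the
    overall KMO (its construction is this package's own; published KMO
    intervals may use a different one).
    """
    cols = indicators or list(index_table.columns)
    data = index_table[cols].dropna()
    n = len(data)
    if n <= len(cols):
        raise ConfigurationError("need more observations than indicators")
    X = data.to_numpy(dtype=float)
    R = np.corrcoef(X, rowvar=False)
    overall, per = kmo(R)
    chi, df, p_bart = bartlett_sphericity(R, n)
    sk, sk_p, ku, ku_p = mardia(X)
    ci = None
    if kmo_bootstrap:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(kmo_bootstrap):
            idx = rng.integers(0, n, n)
            Rb = np.corrcoef(X[idx], rowvar=False)
            try:
                boots.append(kmo(Rb)[0])
            except ConfigurationError:
                continue
        if boots:
            ci = (float(np.percentile(boots, 2.5)),
                  float(np.percentile(boots, 97.5)))
    return AssumptionReport(
        kmo_overall=overall,
        kmo_per_indicator=pd.Series(per, index=cols),
        bartlett_chi_sq=chi, bartlett_df=df, bartlett_p=p_bart,
        mardia_skewness_stat=sk, mardia_skewness_p=sk_p,
        mardia_kurtosis_stat=ku, mardia_kurtosis_p=ku_p,
        kmo_ci=ci)
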