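"""Group-level statistics for the flexibility battery.

Repeated-measures ANOVA (one-way and 2x2 within-subject, partial eta
squared), paired t-tests with Hedges' g, Shapiro-Wilk normality gating of
Pearson vs Spearman, one-sided correlations with Fisher-z CIs and
Bonferroni-adjusted alpha thresholds, the Hotelling-Williams comparison of
dependent overlapping correlations, and first-order partial correlations.

Bonferroni control is applied as adjusted alpha thresholds per hypothesis
family (alpha / family size), matching how directional a-priori tests are
usually reported, rather than by inflating p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import ConfigurationError


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_effect: float
    df_error: float
    p: float
    partial_eta_sq: float


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    hedges_g: float
    warnings: tuple[str, ...] = ()


@dataclass
class CorrelationResult:
    method: str
    r: float
    p_one_sided: float
    ci95: tuple[float, float]
    n: int
    alpha_adjusted: float
    direction: str = "positive"

    @property
    def significant(self) -> bool:
        return self.p_one_sided < self.alpha_adjusted


@dataclass
class DependentCorComparison:
    t: float
    df: int
    p_two_sided: float


def rm_anova(data: pd.DataFrame, dv: str, within: str | list[str],
             subject: str = "subject",
             sphericity_correction: bool = False) -> list[AnovaResult]:
    """Within-subject ANOVA (one-way k-level, or 2x2 with interaction).

    ``data`` is long-format with complete cases. Partial eta squared is
    recovered from F and the degrees of freedom
    (``F * df1 / (F * df1 + df2)``, algebraically SS_effect /
    (SS_effect + SS_error)). ``sphericity_correction`` reports
    Greenhouse-Geisser-corrected p-values (dfs are reported uncorrected).
    """
    if data[subject].nunique() < 2:
        raise ConfigurationError("repeated-measures ANOVA needs >= 2 subjects")
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      correction=sphericity_correction, detailed=True)
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    if sphericity_correction:
        for cand in ("p_GG_corr", "p-GG-corr"):
            if cand in aov.columns:
                p_col = cand
                break
    results = []
    for _, row in aov.iterrows():
        if str(row["Source"]).lower() == "error":
            continue
        # a fully degenerate decomposition (zero effect and error SS) has no
        # F column; the effect is exactly null
        F = float(row["F"]) if "F" in aov.columns else 0.0
        if "ddof1" in aov.columns:
            df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        else:   # detailed one-way layout: effect DF + a trailing Error row
            df1 = float(row["DF"])
            df2 = float(aov.loc[aov["Source"].str.lower() == "error",
                                "DF"].iloc[0])
        np2 = F * df1 / (F * df1 + df2)
        p = float(row[p_col]) if p_col in aov.columns else 1.0
        results.append(AnovaResult(effect=str(row["Source"]), F=F,
                                   df_effect=df1, df_error=df2, p=p,
                                   partial_eta_sq=np2))
    return results


def paired_t_hedges(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Paired t-test with a bias-corrected standardized mean difference.

    Hedges' g is the mean of the pair differences over their SD, scaled by
    the small-sample correction ``1 - 3 / (4 df - 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConfigurationError("paired vectors must have equal length")
    if len(x) < 2:
        raise ConfigurationError("need at least 2 pairs")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    warnings: tuple[str, ...] = ()
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, hedges_g=0.0)
        warnings = ("zero-variance differences: t and g undefined",)
        return TTestResult(t=np.nan, df=n - 1, p=np.nan, hedges_g=np.nan,
                           warnings=warnings)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    correction = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = (d.mean() / sd) * correction
    return TTestResult(t=float(t), df=n - 1, p=float(p), hedges_g=float(g))


def normality_gate(x: np.ndarray, alpha: float = 0.05) -> str:
    """Shapiro-Wilk decision: 'normal' or 'non_normal' at ``alpha``."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ConfigurationError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ConfigurationError("Shapiro-Wilk undefined for a constant vector")
    _, p = stats.shapiro(x)
    return "normal" if p >= alpha else "non_normal"


def _fisher_ci(r: float, n: int, var_factor: float = 1.0) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = np.sqrt(var_factor / (n - 3))
    return (float(np.tanh(z - 1.959964 * se)),
            float(np.tanh(z + 1.959964 * se)))


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson",
              sided: str = "one", direction: str = "positive",
              alpha_adjusted: float = 0.05) -> CorrelationResult:
    """Pearson or Spearman correlation with directional p and Fisher-z CI.

    One-sided p is taken in the hypothesized ``direction``; the Spearman CI
    uses the Fieller-corrected variance ``1.06 / (n - 3)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ConfigurationError("correlation needs n >= 3 complete pairs")
    if method == "pearson":
        r, p_two = stats.pearsonr(x, y)
        var_factor = 1.0
    elif method == "spearman":
        r, p_two = stats.spearmanr(x, y)
        var_factor = 1.06
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    r = float(r)
    if sided == "two":
        p = float(p_two)
    else:
        in_direction = (r >= 0) if direction == "positive" else (r <= 0)
        p = float(p_two / 2 if in_direction else 1 - p_two / 2)
    return CorrelationResult(method=method, r=r, p_one_sided=p,
                             ci95=_fisher_ci(r, n, var_factor), n=n,
                             alpha_adjusted=alpha_adjusted,
                             direction=direction)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Adjusted per-test threshold alpha / m."""
    if m < 1:
        raise ConfigurationError("family size m must be >= 1")
    return alpha / m


def compare_dependent_overlapping(r12: float, r13: float, r23: float,
                                  n: int) -> DependentCorComparison:
    """Hotelling-Williams t for two dependent correlations sharing variable 1.

    Tests r12 = r13 given the correlation r23 between the non-shared
    variables; df = n - 3, two-sided p.
    """
    if n <= 3:
        raise ConfigurationError("need n > 3")
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    detR = np.linalg.det(R)
    if np.min(np.linalg.eigvalsh(R)) < -1e-10:
        raise ConfigurationError("correlation matrix is not positive "
                                 "semi-definite")
    if r12 == r13:
        return DependentCorComparison(t=0.0, df=n - 3, p_two_sided=1.0)
    rbar = (r12 + r13) / 2.0
    num = (r12 - r13) * np.sqrt((n - 1) * (1 + r23))
    den = np.sqrt(2 * detR * (n - 1) / (n - 3)
                  + rbar ** 2 * (1 - r23) ** 3)
    t = num / den
    p = 2 * stats.t.sf(abs(t), n - 3)
    return DependentCorComparison(t=float(t), df=n - 3, p_two_sided=float(p))


def partial_correlation(x: np.ndarray, y: np.ndarray, covariate: np.ndarray,
                        method: str = "pearson", sided: str = "one",
                        direction: str = "positive",
                        alpha_adjusted: float = 0.05) -> CorrelationResult:
    """First-order partial correlation, residual-based.

    ``x`` and ``y`` are residualized on the covariate (on ranks for
    Spearman) and correlated with the same sidedness machinery as
    :func:`correlate`; p uses df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(c))
    x, y, c = x[keep], y[keep], c[keep]
    n = len(x)
    if n <= 3:
        raise ConfigurationError("partial correlation needs n > 3")
    if method == "spearman":
        x, y, c = (stats.rankdata(v) for v in (x, y, c))
        var_factor = 1.06
    else:
        var_factor = 1.0
    X = np.column_stack([np.ones(n), c])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    # a residual vector that is numerically zero (variable explained by the
    # covariate) leaves no partial association to estimate
    scale_x = ((x - x.mean()) ** 2).sum()
    scale_y = ((y - y.mean()) ** 2).sum()
    x_gone = (rx ** 2).sum() <= 1e-12 * max(scale_x, 1e-300)
    y_gone = (ry ** 2).sum() <= 1e-12 * max(scale_y, 1e-300)
    if x_gone or y_gone:
        r = 0.0
    else:
        r = float((rx * ry).sum()
                  / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
    df = n - 3
    if abs(r) >= 1.0:
        t_stat = np.inf * np.sign(r)
    else:
        t_stat = r * np.sqrt(df / (1 - r * r))
    p_two = 2 * stats.t.sf(abs(t_stat), df)
    if sided == "two":
        p = float(p_two)
    else:
        in_direction = (r >= 0) if direction == "positive" else (r <= 0)
        p = float(p_two / 2 if in_direction else 1 - p_two / 2)
    return CorrelationResult(method=method, r=r, p_one_sided=p,
                             ci95=_fisher_ci(r, n, var_factor), n=n,
                             alpha_adjusted=alpha_adjusted,
                             direction=direction)


# ---------------------------------------------------------------------------
# The study's hypothesis battery

#: (family, x, y, direction); families share a Bonferroni-adjusted alpha.
DEFAULT_HYPOTHESES: list[tuple[str, str, str, str]] = [
    ("H1", "sc_rt_cog", "sc_rt_aff_emotion", "positive"),
    ("H1", "sc_rt_cog", "sc_rt_aff_gender", "positive"),
    ("H1", "switch_rate", "sc_rt_cog", "negative"),
    ("H1b", "sc_er_cog", "sc_er_aff_emotion", "positive"),
    ("H1b", "sc_er_cog", "sc_er_aff_gender", "positive"),
    ("H2", "reversal_errors", "sc_rt_cog", "positive"),
    ("H2", "reversal_errors", "sc_er_cog", "positive"),
    ("H2", "reversal_errors", "switch_rate", "negative"),
    ("H3a", "reversal_errors", "sc_rt_aff_emotion", "positive"),
    ("H3a", "reversal_errors", "sc_rt_aff_gender", "positive"),
    ("H3b", "reversal_errors", "sc_er_aff_emotion", "positive"),
    ("H3b", "reversal_errors", "sc_er_aff_gender", "positive"),
    ("H5", "sc_rt_cog", "sc_er_aff_emotion", "positive"),
    ("H5", "sc_rt_cog", "sc_er_aff_gender", "positive"),
]


def run_battery(index_table: pd.DataFrame,
                hypotheses: list[tuple[str, str, str, str]] | None = None,
                alpha: float = 0.05,
                covariate: np.ndarray | None = None) -> pd.DataFrame:
    """One-sided, normality-gated, Bonferroni-controlled correlation tests.

    For each (family, x, y, direction): the pair's method is Spearman if
    either variable fails Shapiro-Wilk on the pairwise-complete sample,
    Pearson otherwise; the adjusted alpha is ``alpha / family size``. With a
    ``covariate``, partial correlations are used instead.
    """
    hypotheses = hypotheses or DEFAULT_HYPOTHESES
    family_sizes: dict[str, int] = {}
    for fam, *_ in hypotheses:
        family_sizes[fam] = family_sizes.get(fam, 0) + 1
    rows = []
    for fam, xname, yname, direction in hypotheses:
        x = index_table[xname].to_numpy(dtype=float)
        y = index_table[yname].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        if covariate is not None:
            cov = np.asarray(covariate, dtype=float)
            keep &= ~np.isnan(cov)
        xs, ys = x[keep], y[keep]
        method = ("pearson"
                  if normality_gate(xs) == "normal"
                  and normality_gate(ys) == "normal" else "spearman")
        a_adj = bonferroni_alpha(alpha, family_sizes[fam])
        if covariate is None:
            res = correlate(xs, ys, method=method, sided="one",
                            direction=direction, alpha_adjusted=a_adj)
        else:
            res = partial_correlation(xs, ys, cov[keep], method=method,
                                      sided="one", direction=direction,
                                      alpha_adjusted=a_adj)
        rows.append({"family": fam, "x": xname, "y": yname,
                     "direction": direction, "method": res.method,
                     "n": res.n, "r": res.r, "p_one_sided": res.p_one_sided,
                     "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                     "alpha_adjusted": a_adj,
                     "significant": res.significant})
    return pd.DataFrame(rows)
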