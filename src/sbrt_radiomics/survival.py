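"""Survival machinery: Kaplan-Meier / log-rank on median-dichotomized
variables, restricted mean survival time at a 36-month horizon,
componentwise likelihood boosting for Cox variable screening, backward
selection, (optionally time-stratified) Cox fits with IQR-scaled hazard
ratios, Harrell optimism-bootstrap corrected concordance, and Schoenfeld
proportional-hazards diagnostics.

Kaplan-Meier estimation, Cox partial-likelihood fitting (Efron ties, left
truncation) and the rank-transform PH test are delegated to ``lifelines``;
the screening, selection, RMST, episode-splitting and bootstrap layers are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from lifelines.utils import concordance_index
from scipy import stats

RMST_TAU_MONTHS = 36.0


def dichotomize_at_median(x: np.ndarray | pd.Series) -> np.ndarray:
    """Below/above-median groups (1 = below or equal, 2 = above).

    Ties with the median go to the lower group, so the split is
    deterministic for day-resolution and score data.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    return np.where(x <= med, 1, 2)


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray
    label: object = None


def _km_curve(times, events, label=None) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    t = tab.index.to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where((n - d) > 0, d / (n * (n - d)), 0.0)
    var = surv**2 * np.cumsum(inc)
    return KMCurve(times=t, survival=surv, at_risk=n, greenwood_var=var, label=label)


def km_logrank(times, events, groups) -> tuple[dict, float, float]:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns (curves keyed by group label, chi-square statistic, p-value).
    With a single group the curve is returned and the test raises.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    labels = np.unique(groups)
    curves = {g: _km_curve(times[groups == g], events[groups == g], g) for g in labels}
    if len(labels) < 2:
        raise ValueError("log-rank test requires two groups")
    g1, g2 = labels[:2]
    res = logrank_test(
        times[groups == g1], times[groups == g2],
        events[groups == g1], events[groups == g2],
    )
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class RMSTResult:
    """Restricted mean survival time per group with a difference test."""

    tau: float
    rmst: dict  # group -> (estimate, se, ci_low, ci_high)
    difference: float | None = None
    difference_ci: tuple | None = None
    p_value: float | None = None


def _rmst_one(times, events, tau: float) -> tuple[float, float]:
    """RMST = area under the KM step function on [0, tau]; variance by the
    standard Greenwood-based large-sample formula."""
    curve = _km_curve(times, events)
    t = np.concatenate([[0.0], curve.times])
    s = np.concatenate([[1.0], curve.survival])
    keep = t < tau
    t_k = np.concatenate([t[keep], [tau]])
    s_k = s[keep]
    area = float(np.sum(s_k * np.diff(t_k)))

    # variance: sum over event times < tau of A_i^2 * d_i / (n_i (n_i - d_i))
    var = 0.0
    tab = KaplanMeierFitter().fit(times, events).event_table
    et = tab.index.to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    for ti, ni, di in zip(et, n, d):
        if di == 0 or ti >= tau or (ni - di) <= 0:
            continue
        # area under the step function from ti to tau
        lens = np.clip(t_k[1:] - np.maximum(t_k[:-1], ti), 0.0, None)
        a_i = float(np.sum(s_k * lens))
        var += a_i**2 * di / (ni * (ni - di))
    return area, float(np.sqrt(var))


def rmst(times, events, groups=None, tau: float = RMST_TAU_MONTHS) -> RMSTResult:
    """RMST at horizon tau (same time unit as ``times``); with two groups,
    a normal test on the RMST difference.

    If the observed follow-up in a group ends before tau, tau is truncated
    to the latest follow-up with a warning.
    """
    import warnings

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0 and times.max() < tau:
        raise ValueError("no events and no follow-up past tau")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    max_follow = min(times[groups == g].max() for g in labels)
    if max_follow < tau:
        warnings.warn(
            f"follow-up ends at {max_follow:.1f} < tau={tau:.1f}; truncating tau"
        )
        tau = float(max_follow)

    z = stats.norm.ppf(0.975)
    per_group = {}
    for g in labels:
        est, se = _rmst_one(times[groups == g], events[groups == g], tau)
        per_group[g] = (est, se, est - z * se, est + z * se)
    result = RMSTResult(tau=tau, rmst=per_group)
    if len(labels) == 2:
        (e1, s1, *_), (e2, s2, *_) = (per_group[labels[0]], per_group[labels[1]])
        diff = e1 - e2
        se = np.sqrt(s1**2 + s2**2)
        result.difference = float(diff)
        result.difference_ci = (float(diff - z * se), float(diff + z * se))
        zstat = diff / se if se > 0 else 0.0
        result.p_value = float(2 * stats.norm.sf(abs(zstat)))
    return result


# ---------------------------------------------------------------------------
# Cox partial likelihood utilities (Breslow form, used by the boosting screen)
# ---------------------------------------------------------------------------

def cox_partial_loglik(lp: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    order = np.argsort(times)
    lp, events = lp[order], events[order]
    # risk set of subject i = all with time >= t_i  (descending cumulative sum)
    rev = np.exp(lp)[::-1].cumsum()[::-1]
    # handle ties: subjects with equal times share the same risk set
    t_sorted = times[order]
    first_idx = np.searchsorted(t_sorted, t_sorted, side="left")
    denom = rev[first_idx]
    return float(np.sum(events * (lp - np.log(denom))))


def _cox_gradient(lp, times, events):
    """Negative gradient of the negative partial log-likelihood w.r.t. lp
    (martingale-residual form)."""
    n = len(lp)
    order = np.argsort(times)
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    elp = np.exp(lp[order])
    rev = elp[::-1].cumsum()[::-1]
    t_sorted = times[order]
    first_idx = np.searchsorted(t_sorted, t_sorted, side="left")
    denom = rev[first_idx]
    ev = events[order]
    # cumulative hazard increment experienced by each subject
    h = ev / denom
    cumh = np.cumsum(h)
    grad_sorted = ev - elp * cumh
    return grad_sorted[inv]


@dataclass
class BoostingResult:
    selected: list
    coefficients: pd.Series
    coefficient_paths: pd.DataFrame
    importance: pd.Series  # % share of in-bag risk (partial-likelihood) reduction
    n_iterations: int


def boost_cox(
    table: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    n_iterations: int = 100,
    step: float = 0.1,
) -> BoostingResult:
    """Componentwise likelihood boosting on the Cox partial likelihood.

    At each iteration every candidate covariate is fitted by least squares
    to the current negative gradient of the loss; only the best (largest
    partial-likelihood gain) is updated by step length ``step``.  Variable
    importance is each covariate's share of the cumulative risk reduction,
    in percent.  Covariates are standardized internally.
    """
    times = table[duration_col].to_numpy(dtype=float)
    events = table[event_col].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("no events")
    X = table[covariates].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in covariates if table[c].isna().any()]
        raise ValueError(f"covariates contain missing values: {bad}")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    p = len(covariates)
    beta = np.zeros(p)
    lp = np.zeros(len(times))
    paths = np.zeros((n_iterations + 1, p))
    gains = np.zeros(p)
    ll = cox_partial_loglik(lp, times, events)
    for it in range(n_iterations):
        g = _cox_gradient(lp, times, events)
        # univariate LS coefficient of each standardized covariate on g
        b = Xs.T @ g / len(g)
        # candidate gains in partial log-likelihood
        best_j, best_ll, best_b = -1, -np.inf, 0.0
        for j in np.argsort(-np.abs(b))[: max(3, p // 4)]:
            cand = cox_partial_loglik(lp + step * b[j] * Xs[:, j], times, events)
            if cand > best_ll:
                best_j, best_ll, best_b = j, cand, b[j]
        beta[best_j] += step * best_b
        lp = Xs @ beta
        new_ll = cox_partial_loglik(lp, times, events)
        gains[best_j] += max(new_ll - ll, 0.0)
        ll = new_ll
        paths[it + 1] = beta

    total = gains.sum()
    importance = pd.Series(
        100.0 * gains / total if total > 0 else np.zeros(p), index=covariates
    ).sort_values(ascending=False)
    selected = [c for c, b in zip(covariates, beta) if b != 0.0]
    return BoostingResult(
        selected=selected,
        coefficients=pd.Series(beta / sd, index=covariates),
        coefficient_paths=pd.DataFrame(paths, columns=covariates),
        importance=importance,
        n_iterations=n_iterations,
    )


# ---------------------------------------------------------------------------
# Cox model fitting
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    predictors: list
    coefficients: pd.Series
    covariance: pd.DataFrame
    hazard_ratios: pd.DataFrame  # per-IQR HR with 95% CI and p per predictor
    partial_log_likelihood: float
    time_strata: list = field(default_factory=list)
    model: CoxPHFitter = field(default=None, repr=False)
    data: pd.DataFrame = field(default=None, repr=False)
    duration_col: str = "duration"
    event_col: str = "event"
    entry_col: str | None = None

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Baseline-period linear predictor for concordance ranking (the
        pre-365-day effect is used for time-stratified predictors)."""
        lp = np.zeros(len(table))
        for name, b in self.coefficients.items():
            if name.endswith(":late"):
                continue  # post-365-day increment not part of baseline risk
            col = name[: -len(":early")] if name.endswith(":early") else name
            lp += b * table[col].to_numpy(dtype=float)
        return lp


def _episode_split(
    table: pd.DataFrame,
    duration_col: str,
    event_col: str,
    time_strata: list[str],
    split_day: float = 365.0,
) -> pd.DataFrame:
    """Split each subject at ``split_day`` and interact the named predictors
    with the period indicator (":early" before, ":late" after)."""
    rows = []
    for _, r in table.iterrows():
        t = r[duration_col]
        if t <= split_day:
            episodes = [(0.0, t, r[event_col], 0)]
        else:
            episodes = [(0.0, split_day, 0, 0), (split_day, t, r[event_col], 1)]
        for start, stop, ev, late in episodes:
            row = r.to_dict()
            row["_entry"], row[duration_col], row[event_col] = start, stop, ev
            for c in time_strata:
                row[f"{c}:early"] = r[c] * (1 - late)
                row[f"{c}:late"] = r[c] * late
            rows.append(row)
    return pd.DataFrame(rows)


def cox_fit(
    table: pd.DataFrame,
    duration_col: str,
    event_col: str,
    predictors: list[str],
    time_strata: list[str] | None = None,
    split_day: float = 365.0,
    penalizer: float = 0.0,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with IQR-scaled hazard
    ratios; predictors named in ``time_strata`` get separate effects before
    and after ``split_day`` via episode splitting (counting-process rows
    with left truncation).
    """
    import warnings

    time_strata = list(time_strata or [])
    if table[event_col].sum() < len(predictors):
        warnings.warn("fewer events than predictors; estimates may be unstable")

    work = table.copy()
    entry_col = None
    fit_cols = list(predictors)
    if time_strata:
        work = _episode_split(work, duration_col, event_col, time_strata, split_day)
        entry_col = "_entry"
        fit_cols = [c for c in predictors if c not in time_strata]
        for c in time_strata:
            fit_cols += [f"{c}:early", f"{c}:late"]

    cph = CoxPHFitter(penalizer=penalizer)
    fit_df = work[[duration_col, event_col] + fit_cols
                  + ([entry_col] if entry_col else [])].reset_index(drop=True)
    try:
        cph.fit(
            fit_df,
            duration_col=duration_col,
            event_col=event_col,
            entry_col=entry_col,
        )
    except Exception as exc:  # non-convergence / separation
        raise RuntimeError(f"Cox fit failed: {exc}") from exc

    beta = cph.params_
    cov = cph.variance_matrix_
    z = stats.norm.ppf(0.975)
    rows = []
    for name in fit_cols:
        base = name.split(":")[0]
        x = table[base].to_numpy(dtype=float)
        uniq = np.unique(x)
        q75, q25 = np.percentile(x, [75, 25])
        scale = 1.0 if len(uniq) <= 2 else float(q75 - q25)
        b, se = beta[name], np.sqrt(cov.loc[name, name])
        rows.append({
            "predictor": name,
            "scale": scale,
            "hr": float(np.exp(b * scale)),
            "ci_low": float(np.exp((b - z * se) * scale)),
            "ci_high": float(np.exp((b + z * se) * scale)),
            "p": float(2 * stats.norm.sf(abs(b / se))) if se > 0 else float("nan"),
        })
    return CoxFit(
        predictors=fit_cols,
        coefficients=beta,
        covariance=cov,
        hazard_ratios=pd.DataFrame(rows).set_index("predictor"),
        partial_log_likelihood=float(cph.log_likelihood_),
        time_strata=time_strata,
        model=cph,
        data=fit_df,
        duration_col=duration_col,
        event_col=event_col,
        entry_col=entry_col,
    )


def backward_select(
    table: pd.DataFrame,
    duration_col: str,
    event_col: str,
    candidates: list[str],
    p_enter: float = 0.10,
    p_remove: float = 0.15,
    correlation_threshold: float = 0.8,
    importance: pd.Series | None = None,
    max_iter: int = 50,
) -> list[str]:
    """Backward selection on Wald p-values with re-entry, preceded by a
    Spearman correlation prefilter: within any candidate pair with
    |rho| > threshold the lower-importance variable is dropped."""
    cands = list(candidates)
    # correlation prefilter
    if len(cands) > 1:
        rho = table[cands].corr(method="spearman").abs()
        drop = set()
        for i, a in enumerate(cands):
            for b_ in cands[i + 1:]:
                if a in drop or b_ in drop:
                    continue
                if rho.loc[a, b_] > correlation_threshold:
                    if importance is not None:
                        worse = a if importance.get(a, 0) < importance.get(b_, 0) else b_
                    else:
                        worse = b_
                    drop.add(worse)
        cands = [c for c in cands if c not in drop]

    current = list(cands)
    excluded: list[str] = []
    for _ in range(max_iter):
        changed = False
        if current:
            fit = cox_fit(table, duration_col, event_col, current)
            pvals = fit.hazard_ratios["p"]
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                current.remove(worst)
                excluded.append(worst)
                changed = True
        for c in list(excluded):
            trial = cox_fit(table, duration_col, event_col, current + [c])
            if trial.hazard_ratios.loc[c, "p"] < p_enter:
                current.append(c)
                excluded.remove(c)
                changed = True
        if not changed:
            return current
    raise RuntimeError("backward selection did not stabilize")


def _fast_cox_newton(
    X: np.ndarray, times: np.ndarray, events: np.ndarray,
    penalizer: float = 0.0, max_iter: int = 30, tol: float = 1e-7,
) -> np.ndarray:
    """Compact Newton solver for the Cox partial likelihood (Breslow risk
    sets; identical to Efron when event times are tie-free, as they are for
    the continuous-time bootstrap refits this backs).

    Returns the coefficient vector; raises on non-convergence.
    """
    n, p = X.shape
    order = np.argsort(times)
    Xo, ev = X[order], events[order].astype(float)
    t_sorted = times[order]
    first_idx = np.searchsorted(t_sorted, t_sorted, side="left")
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(Xo @ beta, -200, 200)
        w = np.exp(eta)
        # reverse cumulative sums over the risk sets
        s0 = w[::-1].cumsum()[::-1][first_idx]
        s1 = (w[:, None] * Xo)[::-1].cumsum(axis=0)[::-1][first_idx]
        xbar = s1 / s0[:, None]
        grad = ((Xo - xbar) * ev[:, None]).sum(axis=0) - penalizer * beta
        # information matrix
        info = np.zeros((p, p))
        s2 = np.einsum("ij,ik,i->ijk", Xo, Xo, w)[::-1].cumsum(axis=0)[::-1][first_idx]
        cov = s2 / s0[:, None, None] - np.einsum("ij,ik->ijk", xbar, xbar)
        info = (cov * ev[:, None, None]).sum(axis=0) + penalizer * np.eye(p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix") from exc
        beta = beta + step
        if np.abs(step).max() < tol:
            return beta
    raise RuntimeError("Cox Newton did not converge")


@dataclass
class CIndexReport:
    apparent: float
    optimism: float
    corrected: float
    n_bootstrap: int
    ci: tuple


def _cindex(table, duration_col, event_col, lp) -> float:
    return concordance_index(table[duration_col], -lp, table[event_col])


def corrected_cindex(
    table: pd.DataFrame,
    duration_col: str,
    event_col: str,
    predictors: list[str],
    B: int = 2000,
    seed: int = 0,
    time_strata: list[str] | None = None,
    split_day: float = 365.0,
    penalizer: float = 0.0,
) -> CIndexReport:
    """Harrell optimism-bootstrap corrected concordance index.

    For each of B bootstrap resamples the model is refitted and optimism is
    C(boot model on boot data) - C(boot model on original data); corrected
    C = apparent - mean optimism.  The CI is the percentile interval of the
    bootstrap-model concordances on the original data, shifted by the mean
    optimism (a pragmatic percentile choice, documented in the methods note).
    """
    if B < 10:
        raise ValueError("need at least 10 bootstrap iterations")
    rng = np.random.default_rng(seed)
    full = cox_fit(table, duration_col, event_col, predictors, time_strata=time_strata,
                   split_day=split_day, penalizer=penalizer)
    apparent = _cindex(table, duration_col, event_col, full.linear_predictor(table))
    optimisms, test_cs = [], []
    n = len(table)
    fast = not time_strata  # tie-free refits take the compact Newton path
    X_all = table[predictors].to_numpy(dtype=float) if fast else None
    t_all = table[duration_col].to_numpy(dtype=float)
    e_all = table[event_col].to_numpy(dtype=int)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = table.iloc[idx].reset_index(drop=True)
        if boot[event_col].sum() < 2:
            continue
        try:
            if fast:
                try:
                    beta = _fast_cox_newton(X_all[idx], t_all[idx], e_all[idx],
                                            penalizer=penalizer)
                except RuntimeError:
                    beta = _fast_cox_newton(X_all[idx], t_all[idx], e_all[idx],
                                            penalizer=max(penalizer, 0.1) * n)
                lp_boot = X_all[idx] @ beta
                lp_orig = X_all @ beta
            else:
                try:
                    fit_b = cox_fit(boot, duration_col, event_col, predictors,
                                    time_strata=time_strata, split_day=split_day,
                                    penalizer=penalizer)
                except RuntimeError:
                    fit_b = cox_fit(boot, duration_col, event_col, predictors,
                                    time_strata=time_strata, split_day=split_day,
                                    penalizer=0.1)
                lp_boot = fit_b.linear_predictor(boot)
                lp_orig = fit_b.linear_predictor(table)
        except RuntimeError:
            continue
        c_boot = _cindex(boot, duration_col, event_col, lp_boot)
        c_orig = _cindex(table, duration_col, event_col, lp_orig)
        optimisms.append(c_boot - c_orig)
        test_cs.append(c_orig)
    opt = float(np.mean(optimisms))
    lo, hi = np.percentile(test_cs, [2.5, 97.5])
    return CIndexReport(
        apparent=float(apparent),
        optimism=opt,
        corrected=float(apparent - opt),
        n_bootstrap=len(optimisms),
        ci=(float(lo), float(hi)),
    )


def schoenfeld_check(fit: CoxFit) -> pd.DataFrame:
    """Scaled Schoenfeld residual PH test per predictor (rank transform).

    Returns a frame with one row per predictor: test statistic, p-value and
    the residual series (length = number of events)."""
    if fit.data[fit.event_col].sum() < 2:
        raise ValueError("need at least 2 events")
    if fit.entry_col is not None:
        raise ValueError(
            "Schoenfeld residuals are not defined for episode-split "
            "(time-stratified) fits; check the unstratified model instead"
        )
    res = proportional_hazard_test(fit.model, fit.data, time_transform="rank")
    resid = fit.model.compute_residuals(fit.data, kind="scaled_schoenfeld")
    out = res.summary.copy()
    out["residuals"] = [resid[c].to_numpy() for c in out.index]
    return out
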