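"""Benchmark computations exercising the package end to end.

Each function runs a self-contained experiment (oracle construction,
simulation, or in-package analysis) and returns plain numbers.  They back
both the acceptance-style tests and ``scripts/acceptance.py``; every
returned value is computed from scratch at call time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import truncnorm

from . import association, ctta, density, fpca, pipeline, survival, synthetic
from .density import DENSITY_FLOOR, SmoothDensity
from .geometry import HU_SUPPORT


def _analytic_density(pdf_values: np.ndarray, grid: np.ndarray) -> SmoothDensity:
    f = np.asarray(pdf_values, dtype=float)
    f = f / np.trapezoid(f, grid)
    f = np.maximum(f, DENSITY_FLOOR * 1.02)
    return SmoothDensity(grid=grid, density=f / np.trapezoid(f, grid))


def _truncnorm_density(mu: float, sd: float, grid: np.ndarray) -> SmoothDensity:
    lo, hi = HU_SUPPORT
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return _analytic_density(truncnorm.pdf(grid, a, b, loc=mu, scale=sd), grid)


def ctta_feature_count(seed: int = 0) -> int:
    """Number of filtration-histogram features emitted for one lesion."""
    spec = synthetic.LesionSpec(target_diameter=18.0, peak_mass_fraction=0.4)
    vol, mask = synthetic.generate_lesion(spec, seed=seed)
    return len(ctta.ctta_features(vol, mask))


def lqd_round_trip(seed: int = 0, n_densities: int = 20) -> dict:
    """Sup-norm error of from_lqd(to_lqd(f)) over smooth test densities,
    plus the uniform-density LQD constant."""
    grid = np.linspace(HU_SUPPORT[0], HU_SUPPORT[1], 1501)
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_densities):
        parts = [
            truncnorm.pdf(
                grid,
                (HU_SUPPORT[0] - mu) / sd, (HU_SUPPORT[1] - mu) / sd,
                loc=mu, scale=sd,
            )
            for mu, sd in zip(
                rng.uniform(-800, 300, 2), rng.uniform(60, 250, 2)
            )
        ]
        w = rng.uniform(0.2, 0.8)
        f = _analytic_density(w * parts[0] + (1 - w) * parts[1], grid)
        back = density.from_lqd(density.to_lqd(f, M=1501))
        errors.append(float(np.abs(back.density - f.density).max()))
    uniform = _analytic_density(np.ones_like(grid), grid)
    psi_u = density.to_lqd(uniform, M=101)
    return {
        "max_sup_error": float(max(errors)),
        "uniform_lqd_deviation": float(np.abs(psi_u.lqd - np.log(1500.0)).max()),
    }


def fpca_scale_family(seed: int = 0, n_curves: int = 100) -> dict:
    """FVE of the first component on a one-parameter scale family, the
    Parseval gap, and whether two density shapes separate by F1 sign."""
    grid = np.linspace(HU_SUPPORT[0], HU_SUPPORT[1], 1501)
    sds = np.linspace(30.0, 150.0, n_curves)
    curves = [density.to_lqd(_truncnorm_density(-300.0, sd, grid), M=101) for sd in sds]
    model, _ = fpca.fit_fpca(curves)
    mat = np.vstack([c.lqd for c in curves])
    centred = mat - mat.mean(axis=0)
    total = float((centred**2 * model.weights).sum() / (n_curves - 1))
    parseval_gap = abs(float(model.eigenvalues.sum()) - total)

    rng = np.random.default_rng(seed)
    mix_curves, labels = [], []
    for _ in range(50):
        f = _truncnorm_density(-500.0 + rng.normal(0, 10), 80.0, grid)
        mix_curves.append(density.to_lqd(f, M=101))
        labels.append(0)
    for _ in range(50):
        lo = _truncnorm_density(-700.0, 60.0, grid)
        hi = _truncnorm_density(100.0 + rng.normal(0, 10), 40.0, grid)
        mix_curves.append(
            density.to_lqd(_analytic_density(0.5 * lo.density + 0.5 * hi.density, grid), M=101)
        )
        labels.append(1)
    _, scores = fpca.fit_fpca(mix_curves)
    labels = np.asarray(labels)
    g0, g1 = scores[labels == 0, 0], scores[labels == 1, 0]
    separated = bool(g0.max() < g1.min() or g1.max() < g0.min())
    return {
        "first_fve": float(model.fve[0]),
        "parseval_gap": parseval_gap,
        "two_shape_separated": separated,
    }


def rmst_exponential(seed: int = 0, n: int = 2000) -> float:
    """RMST at 36 months for exponential survival at rate 0.1/month
    (closed form: (1 - e^-3.6)/0.1 = 9.73 months)."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(10.0, n)
    r = survival.rmst(t, np.ones(n, int), tau=36.0)
    return float(r.rmst[0][0])


def cox_recovery(seed: int = 0, n: int = 1000) -> float:
    """Hazard ratio recovered for a binary covariate with true HR 2."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * x)))
    c = rng.exponential(150.0, n)
    df = pd.DataFrame({"x": x, "T": np.minimum(t, c), "E": (t <= c).astype(int)})
    return float(survival.cox_fit(df, "T", "E", ["x"]).hazard_ratios.loc["x", "hr"])


def cox_noise_coverage(seed: int = 0, n_rep: int = 200, n: int = 500) -> float:
    """Fraction of replicates whose 95% CI for a pure-noise HR contains 1."""
    covered = 0
    for rep in range(n_rep):
        rng = np.random.default_rng(seed * 100_000 + rep)
        x = rng.normal(size=n)
        t = rng.exponential(100.0, n)
        c = rng.exponential(150.0, n)
        df = pd.DataFrame({"x": x, "T": np.minimum(t, c), "E": (t <= c).astype(int)})
        hr = survival.cox_fit(df, "T", "E", ["x"]).hazard_ratios.loc["x"]
        covered += hr["ci_low"] <= 1.0 <= hr["ci_high"]
    return covered / n_rep


def null_cindex_calibration(
    seed: int = 0, n_rep: int = 50, n: int = 50, p: int = 10, B: int = 200
) -> dict:
    """Mean apparent and optimism-corrected concordance for pure-noise Cox
    models (Harrell bootstrap)."""
    corrected, apparent = [], []
    for rep in range(n_rep):
        rng = np.random.default_rng(seed * 100_000 + rep)
        X = rng.normal(size=(n, p))
        t = rng.exponential(1.0, n)
        c = rng.exponential(3.0, n)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
        df["T"], df["E"] = np.minimum(t, c), (t <= c).astype(int)
        rep_res = survival.corrected_cindex(
            df, "T", "E", [f"x{i}" for i in range(p)], B=B, seed=rep
        )
        corrected.append(rep_res.corrected)
        apparent.append(rep_res.apparent)
    return {
        "mean_corrected": float(np.mean(corrected)),
        "mean_apparent": float(np.mean(apparent)),
    }


def boosting_selection_rate(
    seed: int = 0, n_rep: int = 50, n: int = 300, n_noise: int = 18
) -> float:
    """Rate at which two informative covariates (|log HR| = 0.7) top the
    importance ranking against pure-noise competitors."""
    hits = 0
    covariates = [f"x{i}" for i in range(2 + n_noise)]
    for rep in range(n_rep):
        rng = np.random.default_rng(seed * 100_000 + rep)
        X = rng.normal(size=(n, 2 + n_noise))
        lp = 0.7 * X[:, 0] - 0.7 * X[:, 1]
        t = rng.exponential(np.exp(-lp))
        c = rng.exponential(2.0, n)
        df = pd.DataFrame(X, columns=covariates)
        df["T"], df["E"] = np.minimum(t, c), (t <= c).astype(int)
        res = survival.boost_cox(df, "T", "E", covariates, n_iterations=100)
        hits += set(res.importance.index[:2]) == {"x0", "x1"}
    return hits / n_rep


def segmented_benchmarks(
    seed: int = 0, n_coverage: int = 200, n_type1: int = 500
) -> dict:
    """Noiseless breakpoint recovery, CI coverage under noise, and type-I
    error of the pseudo-score test under a linear null."""
    x = np.linspace(0.4, 3.5, 60)
    y = 2.0 + 1.5 * x - 1.2 * np.clip(x - 1.5, 0, None)
    noiseless = association.segmented_fit(x, y).breakpoint

    covered = 0
    for rep in range(n_coverage):
        rng = np.random.default_rng(seed * 100_000 + rep)
        xx = rng.uniform(0.4, 3.5, 150)
        yy = 2 + 1.5 * xx - 1.2 * np.clip(xx - 1.5, 0, None) + rng.normal(0, 0.25, 150)
        fit = association.segmented_fit(xx, yy)
        covered += fit.breakpoint_ci[0] <= 1.5 <= fit.breakpoint_ci[1]

    rejections = 0
    for rep in range(n_type1):
        rng = np.random.default_rng(seed * 100_000 + 50_000 + rep)
        xx = rng.uniform(0.4, 3.5, 100)
        yy = 1 + 0.8 * xx + rng.normal(0, 0.5, 100)
        rejections += association.pseudo_score_test(xx, yy)[1] < 0.05
    return {
        "noiseless_breakpoint": float(noiseless),
        "ci_coverage": covered / n_coverage,
        "type1_error": rejections / n_type1,
    }


def f1_subsample_stability(seed: int = 0, n_lesions: int = 50) -> dict:
    """Bland-Altman agreement of F1 scores between full and 1/10-subsampled
    lesion histograms on a synthetic cohort spanning 0.4-3.5 cm."""
    rng = np.random.default_rng(seed)
    lesions = []
    for i in range(n_lesions):
        d = float(np.exp(rng.uniform(np.log(4.0), np.log(35.0))))
        spec = synthetic.LesionSpec(
            target_diameter=d,
            peak_mass_fraction=float(rng.uniform(0.0, 0.7)),
            background_mean=float(rng.uniform(-650.0, -350.0)),
            shape_irregularity=float(rng.uniform(0.05, 0.3)),
        )
        lesions.append(
            (f"L{i:03d}", *synthetic.generate_lesion(spec, seed=seed * 1000 + i))
        )
    feats = pipeline.extract_cohort_features(
        lesions, subsample_fraction=0.1, subsample_seed=seed
    )
    ba = association.bland_altman(feats["F1"], feats["F1_sub"])
    return {
        "loa_width": float(ba.loa_width),
        "loa_pct_of_iqr": float(ba.width_pct_of_iqr),
    }


def lung_origin_contingency_p() -> float:
    """Pearson chi-square p for the lung-origin x OS-group 2x2 counts
    (8, 66; 12, 25), without continuity correction."""
    table = np.array([[8, 66], [12, 25]])
    return float(stats.chi2_contingency(table, correction=False)[1])
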