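"""Histogram -> smooth density -> log-quantile-density (LQD) chain.

A CT density histogram on the fixed support [-1000, 500] HU is converted to
a smooth probability density by a penalized log-density spline (Ramsay-style
frequency-distribution smoothing): the log density is expanded in a cubic
B-spline basis and fitted to the bin counts by penalized Poisson maximum
likelihood with a second-difference penalty.  The smooth density is then
mapped to the unconstrained LQD space

    psi(p) = log q(p) = log dQ/dp = -log f(Q(p)),   p in [0, 1],

where FPCA of an ensemble of curves is well defined.  The inverse transform
rebuilds a density from any psi by exponentiating, integrating to a quantile
function anchored at the support minimum, rescaling so the total width
matches the support, and differentiating back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .geometry import DensityHistogram, HU_SUPPORT

SUPPORT_WIDTH = HU_SUPPORT[1] - HU_SUPPORT[0]
DENSITY_FLOOR = 1e-5  # per HU, applied before the log transform
N_BASIS = 35
_GRID = np.linspace(HU_SUPPORT[0], HU_SUPPORT[1], 1501)


@dataclass(frozen=True)
class SmoothDensity:
    """A smooth probability density on the HU support, trapezoid-normalized."""

    grid: np.ndarray
    density: np.ndarray
    smoothing: float | None = None  # penalty weight used by the fit, if any

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        f = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "density", f)
        if np.any(f < 0):
            raise ValueError("density must be non-negative")

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class LQDCurve:
    """Log quantile-density values on a uniform probability-level grid."""

    levels: np.ndarray
    lqd: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.levels, dtype=float)
        v = np.asarray(self.lqd, dtype=float)
        object.__setattr__(self, "levels", p)
        object.__setattr__(self, "lqd", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("LQD curve must be finite")


def _bspline_design(x: np.ndarray, n_basis: int = N_BASIS) -> np.ndarray:
    lo, hi = HU_SUPPORT
    degree = 3
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def _second_diff_penalty(n_basis: int) -> np.ndarray:
    d2 = np.diff(np.eye(n_basis), n=2, axis=0)
    return d2.T @ d2


def _penalized_poisson_fit(
    basis: np.ndarray, counts: np.ndarray, lam: float, penalty: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Newton fit of counts ~ Poisson(exp(B theta)) + (lam/2) theta'P theta.

    Returns (theta, deviance, effective df).
    """
    n_basis = basis.shape[1]
    # ridge least-squares init on log counts
    y0 = np.log(counts + 0.5) - np.log(counts.sum() + 0.5 * len(counts)) + np.log(len(counts))
    theta = np.linalg.solve(basis.T @ basis + 1e-4 * np.eye(n_basis), basis.T @ y0)

    def negll(th):
        eta = np.clip(basis @ th, -60.0, 60.0)  # guard exp overflow
        return float(np.exp(eta).sum() - counts @ eta + 0.5 * lam * th @ penalty @ th)

    cur = negll(theta)
    for _ in range(60):
        eta = np.clip(basis @ theta, -60.0, 60.0)
        mu = np.exp(eta)
        grad = basis.T @ (mu - counts) + lam * penalty @ theta
        hess = (basis * mu[:, None]).T @ basis + lam * penalty
        step = np.linalg.solve(hess, grad)
        # step halving
        t = 1.0
        for _ in range(30):
            new = theta - t * step
            val = negll(new)
            if val <= cur + 1e-12:
                break
            t /= 2
        if abs(cur - val) < 1e-9 * (1 + abs(cur)):
            theta, cur = new, val
            break
        theta, cur = new, val
    mu = np.exp(basis @ theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
    deviance = 2 * float(dev_terms.sum() - (counts - mu).sum())
    hess = (basis * mu[:, None]).T @ basis
    edf = float(np.trace(np.linalg.solve(hess + lam * penalty, hess)))
    return theta, deviance, edf


DEFAULT_TARGET_EDF = 15.0


def smooth_density(
    hist: DensityHistogram,
    smoothing: float | None = None,
    n_basis: int = N_BASIS,
    floor: float = DENSITY_FLOOR,
    target_edf: float = DEFAULT_TARGET_EDF,
) -> SmoothDensity:
    """Fit a smooth density to a CT density histogram.

    Parameters
    ----------
    hist : DensityHistogram
        1-HU-bin counts on the [-1000, 500] HU support.
    smoothing : float, optional
        Explicit penalty weight for the second-difference penalty on the
        log-density spline coefficients.  By default the weight is chosen
        (by bisection) so the fit has ``target_edf`` effective degrees of
        freedom.  Fixing the effective dimension rather than optimising a
        count-driven criterion makes the estimator equivariant to the
        histogram's total count, so a histogram and a subsample of it are
        smoothed equivalently — histogram totals from interpolated
        segmentation exports overstate the information content, which
        would otherwise drive an AIC/GCV choice to chase sampling noise.
    target_edf : float
        Effective degrees of freedom of the default fit (2 = log-linear,
        ``n_basis`` = unpenalized).
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("histogram has no counts")
    x = hist.bin_centers
    basis = _bspline_design(x, n_basis)
    penalty = _second_diff_penalty(n_basis)

    if smoothing is None:
        lo, hi = 1e-2, 1e12
        theta, lam_used = None, None
        for _ in range(30):
            lam = float(np.sqrt(lo * hi))
            theta, _, edf = _penalized_poisson_fit(basis, counts, lam, penalty)
            lam_used = lam
            if edf > target_edf:
                lo = lam
            else:
                hi = lam
            if abs(edf - target_edf) < 0.05:
                break
    else:
        lam_used = float(smoothing)
        theta, _, _ = _penalized_poisson_fit(basis, counts, lam_used, penalty)

    grid_basis = _bspline_design(_GRID, n_basis)
    f = np.exp(grid_basis @ theta)
    f /= np.trapezoid(f, _GRID)
    f = np.maximum(f, floor * 1.02)
    f /= np.trapezoid(f, _GRID)
    return SmoothDensity(grid=_GRID.copy(), density=f, smoothing=lam_used)


def to_lqd(f: SmoothDensity, M: int = 101) -> LQDCurve:
    """Log quantile-density transform of a smooth density.

    Computes the quantile function Q(p) by numerical inversion of the CDF
    and returns psi(p) = log dQ/dp = -log f(Q(p)) on M uniform levels.
    """
    dens = np.asarray(f.density, dtype=float)
    if dens.min() < DENSITY_FLOOR * 0.5:
        raise ValueError("density below floor: quantile inversion is degenerate")
    x = f.grid
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(x))])
    cdf /= cdf[-1]
    # enforce strict monotonicity for inversion (density is floored, so
    # increments are positive up to round-off)
    cdf = np.maximum.accumulate(cdf)
    levels = np.linspace(0.0, 1.0, M)
    Q = np.interp(levels, cdf, x)
    f_at_Q = np.interp(Q, x, dens)
    return LQDCurve(levels=levels, lqd=-np.log(f_at_Q))


def from_lqd(psi: LQDCurve, grid: np.ndarray | None = None, floor: float = DENSITY_FLOOR) -> SmoothDensity:
    """Invert the LQD transform back to a density on the HU support."""
    p = psi.levels
    q = np.exp(psi.lqd)
    integral = np.concatenate([[0.0], np.cumsum((q[1:] + q[:-1]) / 2 * np.diff(p))])
    scale = SUPPORT_WIDTH / integral[-1]
    Q = HU_SUPPORT[0] + scale * integral
    f_at_Q = 1.0 / (scale * q)
    x = _GRID if grid is None else np.asarray(grid, dtype=float)
    f = np.interp(x, Q, f_at_Q)
    f /= np.trapezoid(f, x)
    f = np.maximum(f, floor * 1.02)
    f /= np.trapezoid(f, x)
    return SmoothDensity(grid=x.copy(), density=f)
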