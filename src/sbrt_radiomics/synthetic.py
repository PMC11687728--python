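"""Synthetic lesions, cohorts and survival outcomes with known ground truth.

The generator emulates the study conditions of a pulmonary-metastasis SBRT
cohort: lesions 0.4-3.5 cm across embedded in aerated lung (~ -800 HU),
in-lesion HU densities on [-1000, 500] with a controllable high-density
(0-150 HU) mass fraction, 3 mm peri-tumoural context, patient-level
clinical covariates, and RFS/AR/OS outcomes drawn from a proportional-
hazards model tied to the realized lesion parameters.

Lesion shape is a spherical-harmonic perturbation of a sphere; survival
uses an exponential baseline with inverse-transform sampling so every
calibration quantity has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y
from scipy.stats import truncnorm

from .volume import DAYS_PER_MONTH, HU_MAX, HU_MIN, LesionMask, VoxelVolume

LUNG_MEAN_HU = -800.0
LUNG_SD_HU = 60.0


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and density-profile parameters of one synthetic lesion."""

    target_diameter: float  # mm
    density_profile: str = "high_peak"  # uniform_low | high_peak | bimodal
    peak_location: float = 75.0  # HU, centre of the high-density mode
    peak_mass_fraction: float = 0.3  # fraction of voxels in the 0-150 HU mode
    background_mean: float = -500.0  # HU
    background_sd: float = 250.0  # HU
    shape_irregularity: float = 0.15  # >= 0, dimensionless
    texture_correlation_mm: float = 1.5  # spatial correlation length of the HU field
    voxel_spacing: tuple[float, float, float] = (2.5, 0.7, 0.7)  # (dz, dy, dx) mm

    def __post_init__(self) -> None:
        if self.target_diameter <= 0:
            raise ValueError("target_diameter must be positive")
        if not (0 <= self.peak_mass_fraction <= 1):
            raise ValueError("peak mass fraction must be in [0, 1]")
        if self.shape_irregularity < 0:
            raise ValueError("shape_irregularity must be >= 0")
        if self.density_profile not in ("uniform_low", "high_peak", "bimodal"):
            raise ValueError(f"unknown density profile {self.density_profile!r}")


def _sh_coefficients(rng: np.random.Generator) -> list[tuple[int, int, float, float]]:
    coeffs = []
    for ell in (2, 3):
        for m in range(0, ell + 1):
            a = rng.normal(0, 1.0 / (2 * ell + 1))
            b = rng.normal(0, 1.0 / (2 * ell + 1)) if m > 0 else 0.0
            coeffs.append((ell, m, a, b))
    return coeffs


def _sh_eval(coeffs, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    g = np.zeros_like(theta)
    for ell, m, a, b in coeffs:
        y = sph_harm_y(ell, m, theta, phi)
        g += a * np.real(y)
        if m > 0:
            g += b * np.imag(y)
    return g


def _radius_factor(coeffs, irregularity: float, norm: float,
                   theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Direction-dependent radius multiplier 1 + irregularity * g / |g|_max."""
    if irregularity == 0:
        return np.ones_like(theta)
    return 1.0 + irregularity * _sh_eval(coeffs, theta, phi) / norm


def _fibonacci_directions(n: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-uniform unit directions (theta, phi) on the sphere."""
    i = np.arange(n)
    z = 1 - 2 * (i + 0.5) / n
    theta = np.arccos(z)
    phi = (np.pi * (1 + np.sqrt(5)) * i) % (2 * np.pi)
    return theta, phi


def _draw_hu(spec: LesionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """In-lesion HU values following the requested density profile."""
    def trunc(mean, sd, lo, hi, size):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    if spec.density_profile == "uniform_low":
        hu = trunc(spec.background_mean, spec.background_sd, -1000, 500, n)
    else:
        n_peak = rng.binomial(n, spec.peak_mass_fraction)
        lo, hi = (0.0, 150.0)
        peak = trunc(spec.peak_location, 30.0, lo, hi, n_peak)
        if spec.density_profile == "bimodal":
            bg = trunc(-700.0, 80.0, -1000, 500, n - n_peak)
        else:  # high_peak
            bg = trunc(spec.background_mean, spec.background_sd, -1000, 500, n - n_peak)
        hu = np.concatenate([peak, bg])
        rng.shuffle(hu)
    return np.clip(hu, HU_MIN, HU_MAX)


def generate_lesion(spec: LesionSpec, seed: int) -> tuple[VoxelVolume, LesionMask]:
    """Generate one lesion embedded in aerated lung background.

    The mask is a single connected (star-shaped) component; in-mask HU
    values follow the spec's density profile; surrounding voxels emulate
    lung parenchyma (mean ~ -800 HU).
    """
    rng = np.random.default_rng(seed)
    sp = np.asarray(spec.voxel_spacing, dtype=float)
    if spec.target_diameter < min(sp):
        raise ValueError("lesion below resolution")

    coeffs = _sh_coefficients(rng)
    th_s, ph_s = _fibonacci_directions()
    g_s = _sh_eval(coeffs, th_s, ph_s)
    norm = max(float(np.abs(g_s).max()), 1e-12)
    fac_s = _radius_factor(coeffs, spec.shape_irregularity, norm, th_s, ph_s)
    # antipodal partner of direction (theta, phi) is (pi - theta, phi + pi);
    # scale the base radius so the maximal paired extent hits the target
    fac_anti = _radius_factor(
        coeffs, spec.shape_irregularity, norm, np.pi - th_s, (ph_s + np.pi) % (2 * np.pi)
    )
    radius = spec.target_diameter / float((fac_s + fac_anti).max())

    pad = radius * (1 + spec.shape_irregularity) + 4.0  # mm margin
    shape = np.maximum(np.ceil(2 * pad / sp).astype(int) + 1, 5)
    centre = (shape - 1) / 2.0 * sp
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * sp[0] - centre[0],
        np.arange(shape[1]) * sp[1] - centre[1],
        np.arange(shape[2]) * sp[2] - centre[2],
        indexing="ij",
    )
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, zz / np.maximum(r, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(yy, xx) % (2 * np.pi)
    factor = _radius_factor(coeffs, spec.shape_irregularity, norm, theta, phi)
    mask_arr = r <= radius * factor
    if not mask_arr.any():
        raise ValueError("lesion below resolution")

    values = rng.normal(LUNG_MEAN_HU, LUNG_SD_HU, size=tuple(shape))
    hu = np.sort(_draw_hu(spec, int(mask_arr.sum()), rng))
    if spec.texture_correlation_mm > 0:
        # spatially correlated in-lesion field with the exact requested
        # marginal: rank-map a smoothed Gaussian field onto the sorted draws
        from scipy.ndimage import gaussian_filter

        field = rng.standard_normal(tuple(shape))
        field = gaussian_filter(field, sigma=spec.texture_correlation_mm / sp)
        ranks = np.argsort(np.argsort(field[mask_arr]))
        values[mask_arr] = hu[ranks]
    else:
        rng.shuffle(hu)
        values[mask_arr] = hu
    values = np.clip(values, HU_MIN, HU_MAX)
    spacing = tuple(float(s) for s in sp)
    return (
        VoxelVolume(values=values, spacing=spacing),
        LesionMask(membership=mask_arr, spacing=spacing),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, covariate distributions and survival-generating model.

    ``effect_sizes`` maps cohort-table column names to log hazard ratios
    per unit of that column; the linear predictor drives an exponential
    proportional-hazards recurrence process (and an independent death
    process at ``death_hazard_fraction`` of the baseline hazard).
    """

    n_patients: int = 100
    effect_sizes: dict = field(default_factory=lambda: {
        "peak_fraction": 1.2,       # high-density mass fraction of largest lesion
        "size_cm": 0.25,            # per cm of lesion diameter
        "lung_origin": 0.6,         # lung primary vs other, ~HR 1.8
        "indication_group2": 0.58,  # oligoprogression/dominant vs single/oligomet
        "age_years": -0.015,        # older age protective for recurrence
    })
    baseline_hazard: float = 1.1e-3  # per day
    horizon_days: float = 1600.0
    censoring_rate: float = 3.0e-4  # per day, independent exponential
    death_hazard_fraction: float = 0.12
    post_recurrence_mean_days: float = 1200.0
    age_mean: float = 67.0
    age_sd: float = 10.0
    female_prevalence: float = 0.51
    contrast_prevalence: float = 0.91
    lung_origin_prevalence: float = 0.18
    indication_group2_prevalence: float = 0.35
    multi_lesion_probs: tuple = (0.82, 0.15, 0.02, 0.01)  # P(1..4 lesions)
    diameter_range_mm: tuple = (4.0, 35.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.horizon_days <= 0:
            raise ValueError("censoring horizon must be positive")
        for p in (self.female_prevalence, self.contrast_prevalence,
                  self.lung_origin_prevalence, self.indication_group2_prevalence):
            if not (0 <= p <= 1):
                raise ValueError("prevalences must lie in [0, 1]")


def _patient_lesion_specs(spec: CohortSpec, rng: np.random.Generator) -> list[LesionSpec]:
    n_lesions = 1 + rng.choice(len(spec.multi_lesion_probs), p=spec.multi_lesion_probs)
    lo, hi = spec.diameter_range_mm
    out = []
    for _ in range(n_lesions):
        d = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        out.append(
            LesionSpec(
                target_diameter=d,
                density_profile="high_peak",
                peak_mass_fraction=float(rng.uniform(0.0, 0.7)),
                background_mean=float(rng.uniform(-650, -350)),
                shape_irregularity=float(rng.uniform(0.05, 0.3)),
            )
        )
    return out


def generate_cohort(
    spec: CohortSpec, with_volumes: bool = False
) -> tuple[pd.DataFrame, list[tuple[VoxelVolume, LesionMask]] | None]:
    """Generate a patient-level cohort table and (optionally) the lesion
    volume/mask pair of each patient's largest lesion.

    Survival: recurrence time ~ Exp(h0 * exp(lp)); independent death time
    ~ Exp(f * h0 * exp(lp_death)); RFS = min of the two, AR = recurrence,
    OS = death time (= recurrence + positive post-recurrence time when
    recurrence comes first, so OS >= RFS).  All endpoints are censored at
    min(administrative horizon, independent exponential censoring).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    volumes: list[tuple[VoxelVolume, LesionMask]] = []
    for i in range(spec.n_patients):
        lesions = _patient_lesion_specs(spec, rng)
        largest = max(lesions, key=lambda s: s.target_diameter)
        row = {
            "patient_id": f"P{i:04d}",
            "age_years": float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 34, 90)),
            "sex_female": int(rng.random() < spec.female_prevalence),
            "contrast": int(rng.random() < spec.contrast_prevalence),
            "lung_origin": int(rng.random() < spec.lung_origin_prevalence),
            "indication_group2": int(rng.random() < spec.indication_group2_prevalence),
            "n_lesions": len(lesions),
            "multiple_lesions": int(len(lesions) > 1),
            "size_cm": largest.target_diameter / 10.0,
            "peak_fraction": largest.peak_mass_fraction,
            "background_mean_hu": largest.background_mean,
        }
        row["indication_group"] = 1 + row["indication_group2"]
        rows.append(row)
        if with_volumes:
            volumes.append(generate_lesion(largest, seed=rng.integers(2**31)))
    table = pd.DataFrame(rows)

    lp = np.zeros(len(table))
    for name, beta in spec.effect_sizes.items():
        if name not in table.columns:
            raise KeyError(f"effect on unknown column {name!r}")
        lp += beta * table[name].to_numpy(dtype=float)
    lp -= lp.mean()  # centre so baseline_hazard is the cohort-typical hazard

    h_rec = spec.baseline_hazard * np.exp(lp)
    h_death = spec.death_hazard_fraction * spec.baseline_hazard * np.exp(lp)
    t_rec = rng.exponential(1.0 / h_rec)
    t_death0 = rng.exponential(1.0 / h_death)
    post = rng.exponential(spec.post_recurrence_mean_days, size=len(table))
    t_death = np.where(t_rec < t_death0, t_rec + post, t_death0)
    t_rfs = np.minimum(t_rec, t_death)

    cens = np.minimum(
        spec.horizon_days,
        rng.exponential(1.0 / spec.censoring_rate, size=len(table))
        if spec.censoring_rate > 0
        else np.inf,
    )
    for name, t in (("rfs", t_rfs), ("ar", t_rec), ("os", t_death)):
        table[f"{name}_days"] = np.minimum(t, cens)
        table[f"{name}_event"] = (t <= cens).astype(int)
        table[f"{name}_months"] = table[f"{name}_days"] / DAYS_PER_MONTH
    table["true_linear_predictor"] = lp
    return table, (volumes if with_volumes else None)
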