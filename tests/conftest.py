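import numpy as np
import pytest
from scipy.stats import truncnorm

from sbrt_radiomics import density, synthetic
from sbrt_radiomics.density import DENSITY_FLOOR, SmoothDensity
from sbrt_radiomics.geometry import HU_SUPPORT


def analytic_density(pdf_values: np.ndarray, grid: np.ndarray) -> SmoothDensity:
    """Wrap an analytic pdf as a floored, renormalized SmoothDensity."""
    f = np.asarray(pdf_values, dtype=float)
    f = f / np.trapezoid(f, grid)
    f = np.maximum(f, DENSITY_FLOOR * 1.02)
    f = f / np.trapezoid(f, grid)
    return SmoothDensity(grid=grid, density=f)


def truncnorm_density(mu: float, sd: float, grid: np.ndarray) -> SmoothDensity:
    lo, hi = HU_SUPPORT
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return analytic_density(truncnorm.pdf(grid, a, b, loc=mu, scale=sd), grid)


@pytest.fixture(scope="session")
def hu_grid():
    return np.linspace(HU_SUPPORT[0], HU_SUPPORT[1], 1501)


@pytest.fixture(scope="session")
def default_lesion():
    """A 20 mm high-density-peak lesion on a 1 mm isotropic grid."""
    spec = synthetic.LesionSpec(
        target_diameter=20.0, voxel_spacing=(1.0, 1.0, 1.0), peak_mass_fraction=0.4
    )
    return synthetic.generate_lesion(spec, seed=7)


@pytest.fixture(scope="session")
def scale_family(hu_grid):
    """One-parameter scale family of truncated normal densities and their
    LQD curves (a single dominant mode of variation by construction)."""
    sds = np.linspace(30.0, 150.0, 100)
    curves = [
        density.to_lqd(truncnorm_density(-300.0, sd, hu_grid), M=101) for sd in sds
    ]
    return sds, curves
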