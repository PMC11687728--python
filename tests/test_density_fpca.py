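import numpy as np
import pytest
from scipy.stats import truncnorm

from sbrt_radiomics import density, fpca, geometry
from sbrt_radiomics.density import LQDCurve, SmoothDensity
from tests.conftest import analytic_density, truncnorm_density

EDGES = np.linspace(-1000.0, 500.0, 1501)


def _hist(counts):
    return geometry.DensityHistogram(bin_edges=EDGES, counts=np.asarray(counts))


class TestSmoothDensity:
    def test_flat_histogram_recovers_uniform(self):
        f = density.smooth_density(_hist(np.full(1500, 10)))
        np.testing.assert_allclose(f.density, 1.0 / 1500, rtol=0.05)

    def test_truncated_normal_sup_norm(self, hu_grid):
        rng = np.random.default_rng(0)
        mu, sd = -300.0, 50.0
        a, b = (-1000 - mu) / sd, (500 - mu) / sd
        draws = truncnorm.rvs(a, b, loc=mu, scale=sd, size=100_000, random_state=rng)
        counts, _ = np.histogram(draws, bins=EDGES)
        f = density.smooth_density(_hist(counts))
        pdf = truncnorm.pdf(hu_grid, a, b, loc=mu, scale=sd)
        assert np.abs(f.density - pdf).max() < 0.10 * pdf.max()

    @pytest.mark.parametrize("seed", [1, 2])
    def test_normalized_and_floored(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, 1500)
        f = density.smooth_density(_hist(counts))
        assert abs(f.integral - 1.0) < 1e-6
        assert f.density.min() >= density.DENSITY_FLOOR

    def test_all_zero_counts_raises(self):
        with pytest.raises(ValueError, match="no counts"):
            density.smooth_density(_hist(np.zeros(1500)))

    def test_explicit_smoothing_overrides_default(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, 1500)
        rough = density.smooth_density(_hist(counts), smoothing=1.0)
        smooth = density.smooth_density(_hist(counts), smoothing=1e8)
        # heavier penalty gives a flatter (lower total-variation) fit
        tv = lambda f: np.abs(np.diff(f.density)).sum()
        assert tv(smooth) < tv(rough)
        assert rough.smoothing == 1.0


class TestLQDTransform:
    def test_uniform_maps_to_constant_log_1500(self, hu_grid):
        f = analytic_density(np.ones_like(hu_grid), hu_grid)
        psi = density.to_lqd(f, M=101)
        np.testing.assert_allclose(psi.lqd, np.log(1500.0), atol=1e-6)

    def test_round_trip_identity(self, hu_grid):
        f = truncnorm_density(-300.0, 120.0, hu_grid)
        back = density.from_lqd(density.to_lqd(f, M=1501))
        assert np.abs(back.density - f.density).max() < 1e-3

    def test_triangular_closed_form(self, hu_grid):
        """f(x) ~ 2x on the rescaled support (Beta(2,1) shape) has
        psi(p) = log(750) - 0.5 log(p)."""
        f = analytic_density(np.maximum(hu_grid + 1000.0, 0.0), hu_grid)
        psi = density.to_lqd(f, M=1001)
        p = psi.levels
        interior = p >= 0.02  # the floored lower tail deviates near p = 0
        expected = np.log(750.0) - 0.5 * np.log(p[interior])
        np.testing.assert_allclose(psi.lqd[interior], expected, atol=0.02)

    def test_degenerate_density_raises(self, hu_grid):
        f = SmoothDensity(grid=hu_grid, density=np.full_like(hu_grid, 1e-9))
        with pytest.raises(ValueError, match="floor"):
            density.to_lqd(f)


class TestFPCA:
    def test_identical_curves_have_zero_spectrum(self, hu_grid):
        f = truncnorm_density(-300.0, 80.0, hu_grid)
        curves = [density.to_lqd(f, M=101) for _ in range(10)]
        model, scores = fpca.fit_fpca(curves)
        assert model.eigenvalues.max() < 1e-20
        np.testing.assert_allclose(scores, 0.0, atol=1e-9)

    def test_scale_family_has_one_dominant_mode(self, scale_family):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        assert model.fve[0] >= 0.95

    def test_parseval_identity(self, scale_family):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        mat = np.vstack([c.lqd for c in curves])
        centred = mat - mat.mean(axis=0)
        total = float((centred**2 * model.weights).sum() / (len(curves) - 1))
        assert abs(model.eigenvalues.sum() - total) < 1e-6

    def test_eigenfunctions_orthonormal(self, scale_family):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        k = min(5, model.eigenfunctions.shape[1])
        phi = model.eigenfunctions[:, :k]
        gram = (phi * model.weights[:, None]).T @ phi
        np.testing.assert_allclose(gram, np.eye(k), atol=1e-8)

    def test_training_scores_centred(self, scale_family):
        _, curves = scale_family
        _, scores = fpca.fit_fpca(curves)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-8)

    def test_two_shapes_perfectly_separated_by_f1(self, hu_grid):
        rng = np.random.default_rng(0)
        curves, labels = [], []
        for _ in range(30):
            f = truncnorm_density(-500.0 + rng.normal(0, 10), 80.0, hu_grid)
            curves.append(density.to_lqd(f, M=101))
            labels.append(0)
        for _ in range(30):
            lo = truncnorm_density(-700.0, 60.0, hu_grid)
            hi = truncnorm_density(100.0 + rng.normal(0, 10), 40.0, hu_grid)
            f = analytic_density(0.5 * lo.density + 0.5 * hi.density, hu_grid)
            curves.append(density.to_lqd(f, M=101))
            labels.append(1)
        _, scores = fpca.fit_fpca(curves)
        labels = np.asarray(labels)
        g0, g1 = scores[labels == 0, 0], scores[labels == 1, 0]
        assert g0.max() < g1.min() or g1.max() < g0.min()

    def test_fewer_than_three_curves_raises(self, hu_grid):
        f = truncnorm_density(-300.0, 80.0, hu_grid)
        with pytest.raises(ValueError):
            fpca.fit_fpca([density.to_lqd(f, M=101)] * 2)

    def test_reconstruction_error_monotone_in_components(self, hu_grid):
        rng = np.random.default_rng(5)
        curves = [
            density.to_lqd(truncnorm_density(rng.uniform(-500, -100),
                                             rng.uniform(40, 150), hu_grid), M=101)
            for _ in range(30)
        ]
        model, _ = fpca.fit_fpca(curves)
        target = curves[0].lqd - model.mean_lqd
        errs = []
        recon = np.zeros_like(target)
        for j in range(min(6, model.eigenfunctions.shape[1])):
            phi = model.eigenfunctions[:, j]
            recon = recon + float((target * model.weights) @ phi) * phi
            errs.append(float(((target - recon) ** 2 * model.weights).sum()))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))


class TestScoring:
    def test_mean_curve_scores_zero(self, scale_family):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        np.testing.assert_allclose(fpca.score(model, model.mean_curve), 0.0, atol=1e-10)

    def test_training_curve_scores_match(self, scale_family):
        _, curves = scale_family
        model, scores = fpca.fit_fpca(curves)
        np.testing.assert_allclose(fpca.score(model, curves[7]), scores[7], atol=1e-10)

    def test_unit_eigen_direction_scores_sqrt_lambda(self, scale_family):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        lam1 = model.eigenvalues[0]
        curve = LQDCurve(
            levels=model.levels,
            lqd=model.mean_lqd + np.sqrt(lam1) * model.eigenfunctions[:, 0],
        )
        got = fpca.score(model, curve)
        np.testing.assert_allclose(got[0], np.sqrt(lam1), atol=1e-8)
        np.testing.assert_allclose(got[1:], 0.0, atol=1e-8)

    def test_grid_mismatch_raises(self, scale_family):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        other = LQDCurve(levels=np.linspace(0, 1, 51), lqd=np.zeros(51))
        with pytest.raises(ValueError, match="grid"):
            fpca.score(model, other)


class TestModesOfVariation:
    def test_mode_zero_is_mean_backtransform(self, scale_family):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        f = fpca.mode_of_variation(model, 1, 0.0)
        assert abs(f.integral - 1.0) < 1e-6

    @pytest.mark.parametrize("k", [-2.0, 2.0])
    def test_modes_are_valid_densities(self, scale_family, k):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        f = fpca.mode_of_variation(model, 1, k)
        assert (f.density >= 0).all()
        assert abs(f.integral - 1.0) < 1e-6

    def test_scale_family_modes_ordered_by_spread(self, scale_family):
        """For a scale family, walking mode 1 orders the back-transformed
        densities by interquartile width."""
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)

        def iqr(f):
            cdf = np.cumsum(f.density)
            cdf = cdf / cdf[-1]
            return np.interp(0.75, cdf, f.grid) - np.interp(0.25, cdf, f.grid)

        widths = [iqr(fpca.mode_of_variation(model, 1, k)) for k in (-2.0, 0.0, 2.0)]
        assert widths == sorted(widths) or widths == sorted(widths, reverse=True)

    def test_unretained_component_raises(self, scale_family):
        _, curves = scale_family
        model, _ = fpca.fit_fpca(curves)
        with pytest.raises(ValueError):
            fpca.mode_of_variation(model, model.n_components_retained + 1, 1.0)


def test_orient_tumour_f1_sign_convention(hu_grid):
    """High-density-peak curves must receive LOW F1 after orientation."""
    rng = np.random.default_rng(2)
    curves, frac = [], []
    for _ in range(40):
        w = rng.uniform(0.0, 0.7)
        lo = truncnorm_density(-500.0, 150.0, hu_grid)
        hi = truncnorm_density(75.0, 30.0, hu_grid)
        f = analytic_density((1 - w) * lo.density + w * hi.density, hu_grid)
        curves.append(density.to_lqd(f, M=101))
        frac.append(w)
    model, scores = fpca.fit_fpca(curves)
    model, scores = fpca.orient_tumour_f1(model, scores, np.asarray(frac))
    from scipy.stats import spearmanr

    rho = spearmanr(scores[:, 0], frac).statistic
    assert rho < -0.5
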