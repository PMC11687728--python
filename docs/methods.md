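# Methods

`sbrt_radiomics` implements two CT radiomic feature-extraction methods and
the survival-modelling workflow used to relate those features to
recurrence-free survival (RFS), control of any recurrence (AR) and overall
survival (OS) in patients whose pulmonary metastases were treated with
stereotactic body radiotherapy (SBRT). Because no patient data are
distributed, a synthetic-data module generates lesions, cohorts and
outcomes with known ground truth; every downstream stage is exercised and
calibrated against that ground truth or against closed-form oracles.

## Synthetic lesions and cohorts

A lesion is a star-shaped solid: a sphere whose direction-dependent radius
is modulated by a random degree-2/3 spherical-harmonic field, scaled so the
maximal paired directional extent equals the requested diameter (generated
maximal diameters land within ~3% of target). Lesions span 0.4–3.5 cm
(log-uniform), embedded in aerated-lung background (HU ~ N(−800, 60)) on an
acquisition-like grid of 0.7 × 0.7 mm pixels and 2.5 mm slices.

In-lesion HU values follow one of three marginal profiles on
[−1000, 500] HU — `uniform_low` (broad truncated normal), `high_peak` (a
0–150 HU soft-tissue mode holding a controllable mass fraction, plus a
broad low-density background) and `bimodal` — and are arranged in space as
a correlated random field: a white-noise field is Gaussian-smoothed
(correlation length 1.5 mm by default) and rank-mapped onto the sorted
marginal draws. The copula construction keeps the marginal exact (the
0–150 HU mass fraction is realized to within binomial error) while giving
the lesion the spatial coherence of real tumour density maps; voxel-wise
white noise would make interpolated histograms and texture responses
unrealistically unstable.

Cohorts add clinical covariates (age ~ N(67, 10) clipped to 34–90, sex,
contrast use at 91%, lung primary origin at 18%, clinical-indication
group 2 at 35%, and a 1–4 lesion count with P = .82/.15/.02/.01; the
largest lesion is the feature source). Survival uses an exponential
baseline (1.1 × 10⁻³/day) with inverse-transform sampling: the recurrence
hazard multiplies exp(linear predictor) built from the named effect
columns (defaults: high-density fraction +1.2, size +0.25/cm, lung origin
+0.6, indication group 2 +0.58, age −0.015/yr); an independent death
process runs at 12% of the recurrence hazard; death after recurrence adds
an independent exponential post-recurrence time (mean 1200 days), so
OS ≥ RFS always. Censoring is the minimum of a 1600-day administrative
horizon and an independent exponential (3 × 10⁻⁴/day). These settings give
~70% RFS events, ~38% OS events and a median follow-up near 1000 days —
the regime of a ~900-day-median-follow-up SBRT cohort. All month/day
conversions use 30.4375 days/month.

What the generator does **not** emulate: scanner noise spectra, beam
hardening, partial-volume-accurate boundaries, respiratory artefacts, or
correlated censoring. Tests passing on these cohorts demonstrate the
correctness and calibration of the machinery, not clinical performance on
real CT.

## Geometry, histograms and the peri-tumoural shell

Geometric summaries operate on voxel centres: maximal 3D diameter (largest
pairwise physical distance, convex-hull-accelerated), mean of per-slice
maximal in-plane diameters, "size" = maximal axial in-plane diameter in
cm, volume = voxel count × voxel volume, and first-order HU moments. The
peri-tumoural shell is the set of voxels whose anisotropic Euclidean
distance to the lesion surface lies in (0, 3] mm (distance transform with
physical sampling); it is deliberately not clipped to lung parenchyma and
is silently truncated at image boundaries.

CT density histograms use 1500 one-HU bins on [−1000, 500]; out-of-support
voxels are clipped to the nearest bound so counts are conserved. Histograms
are exported from a fine isotropic resampling of the lesion grid — linear
HU interpolation and nearest-neighbour masks on a grid of 256 cells along
the longest extent (~0.05–0.17 mm spacing depending on lesion size). This
emulates the sub-voxel interpolated export of a multiplanar semi-automatic
segmentation tool, which is the form in which such histograms reach the
density analysis; it also gives every lesion a histogram total (10⁴–10⁶)
large enough that the 1/10 voxel-removal experiment probes the method
rather than raw multinomial noise. Geometry and 2D texture analysis stay
at acquisition resolution.

## Density smoothing and the log-quantile-density transform

Each histogram is converted to a smooth density by a penalized log-density
spline: log f expanded in 35 cubic B-splines on the support, fitted to bin
counts by penalized Poisson maximum likelihood (Newton with step-halving)
with a second-difference penalty. The penalty weight is chosen by
bisection so the fit has a fixed effective dimension (15 degrees of
freedom by default; an explicit weight can be supplied). We chose fixed-df
over AIC/GCV deliberately: interpolated histogram totals overstate the
independent information content, so a count-driven criterion chases
sampling noise, and — worse for paired analyses — assigns systematically
different roughness to a histogram and its subsample. Fixed-df is
equivariant to the total count, so both members of a pair are smoothed
identically. The fitted density is renormalized and floored at
δ = 10⁻⁵/HU (then renormalized again) so the log-quantile-density
transform is defined everywhere.

The LQD transform maps a density to ψ(p) = log dQ/dp = −log f(Q(p)) on a
uniform probability grid (M = 101 levels for analysis; the round-trip
numerics are validated at M = 1501, where 20 smooth two-component mixtures
reconstruct with sup-norm error < 10⁻³ against densities whose peaks are
~5 × 10⁻³/HU). The inverse transform exponentiates, integrates to a
quantile function anchored at −1000 HU, rescales so the total width equals
the 1500 HU support, and differentiates back.

## Functional PCA of density ensembles

The LQD curves of a cohort are centred and eigen-decomposed under the
trapezoid inner product (SVD of the weight-scaled data matrix; sample
covariance with n−1). Scores are projections onto the leading
eigenfunctions; training scores are exactly centred and satisfy Parseval's
identity to 10⁻⁶. Components are retained up to three, dropping a
component once its fraction of variance explained falls below 10%.
Eigenfunction signs are first fixed by a reproducibility convention
(positive integral over the upper half of the level grid); the first
tumour component is then oriented so lesions with a large 0–150 HU mass
fraction receive *low* F1 — making F1 an inverse marker of the
high-density peak, with high F1 indicating a flat, low-density profile.
On synthetic cohorts F1 correlates with the latent high-density fraction
at |Spearman ρ| ≈ 0.8.

## Filtration-histogram texture (CTTA)

The 2D texture method analyses the axial slice with the largest in-mask
pixel count (ties to the inferior slice), restricted to in-mask pixels
with unfiltered HU ≥ −50. The slice is convolved with a
Laplacian-of-Gaussian band-pass kernel at spatial scale filters
SSF ∈ {0, 2, 3, 4, 5, 6} mm (SSF 0 = identity); σ = SSF/2 mm converted to
pixels by the in-plane spacing, truncated at 4σ and re-centred to exact
zero sum, with edge-replication padding. Six first-order statistics are
computed over the analysis pixels of each filtered slice: mean, sample SD,
Shannon entropy in bits over a 64-bin fixed-width histogram between the
min and max, mean of positive pixels (flagged missing when no pixel is
positive), skewness, and excess kurtosis (flagged missing for constant
inputs) — 36 features named `ssf{s}-{metric}`. The σ mapping, kernel
normalization and entropy binning of the commercial implementation are
unpublished; these choices are documented tunables, so absolute feature
magnitudes are comparable only within this package. Band-pass behaviour is
verified directly: the SSF maximizing the central response to a Gaussian
blob grows with the blob width. On constant-texture synthetic lesions,
ssf4-entropy rises with lesion size and plateaus; segmented regression
places the breakpoint near 1.4 cm (p ≈ 10⁻¹⁰), reproducing the small-ROI
entropy bias phenomenon.

## Survival machinery

*Kaplan–Meier / log-rank.* Product-limit curves (lifelines) with Greenwood
variance; two-group log-rank; continuous variables dichotomized at the
median with ties to the lower group.

*RMST.* Restricted mean survival time at τ = 36 months = area under the KM
step function on [0, τ], computed exactly from the event table; variance
by the standard Greenwood-based large-sample formula
Var = Σ A_i² d_i / (n_i (n_i − d_i)) with A_i the area from t_i to τ;
group differences tested by a normal test. The point value is
cross-checked against lifelines' `restricted_mean_survival_time` and a
brute-force rectangle sum. When follow-up ends before τ, τ is truncated
with a warning.

*Boosting screen.* Componentwise likelihood boosting on the Cox partial
likelihood: at each of 100 iterations the negative gradient (martingale
form) is fitted by least squares against every standardized candidate, and
only the best covariate (largest partial-likelihood gain) is updated with
step length ν = 0.1. Variable importance is each covariate's share of the
cumulative in-bag risk reduction, in percent (shares sum to 100). The
published description of the variant is ambiguous between likelihood-based
and gradient-based componentwise schemes; the gradient-based scheme is
implemented and behaves as a screen should: two informative covariates
(|log HR| = 0.7) among 18 noise covariates top the ranking in ~100% of
replicates at n = 300.

*Backward selection.* Before selection, within any candidate pair with
|Spearman ρ| > 0.8 the lower-importance member is dropped (this is what
removes, e.g., a peri-F1 that shadows F1). Then Wald-p-based backward
steps (remove if p > 0.15) with re-entry (enter if p < 0.1), bounded
iterations.

*Cox fits.* Partial-likelihood maximization via lifelines (Efron ties).
Hazard ratios for continuous predictors are reported per interquartile
range: HR = exp(β·IQR), CIs scaled the same way; binary predictors per
unit. A time-varying age effect is accommodated by episode-splitting every
subject at one year (counting-process rows with left truncation) and
estimating separate `:early`/`:late` effects; splitting without
interactions leaves the estimate unchanged to 10⁻⁸, which is tested. A
compact Newton solver (Breslow risk sets — identical to Efron on tie-free
data) backs the bootstrap loops; it agrees with lifelines to 10⁻⁵.

*Optimism-corrected C-index.* Harrell's bootstrap: refit on each resample,
optimism = C(boot model on boot data) − C(boot model on original data),
corrected = apparent − mean optimism; B = 200 by default in analyses (the
reference procedure uses 2000; both are seed-controlled knobs). The CI is
the percentile interval of the bootstrap-model concordances on the
original data shifted by the mean optimism — a pragmatic choice, since the
reference publications do not state how their C-index CIs were formed.
A caveat established here with an independent R implementation
(survival::coxph): under heavy overfitting (e.g., 10 noise predictors at
n = 50, or even n = 200) the canonical Harrell loop retains residual
optimism of +0.02–0.035, because bootstrap models are evaluated on an
original sample that overlaps their training resample. Corrected values
near 0.5 under the null should therefore be read as "approximately
corrected", and the package intentionally reports both apparent and
corrected values side by side.

*Proportional hazards.* Scaled Schoenfeld residuals with a rank-transform
association test (lifelines), one residual series per predictor with one
value per event. The test is calibrated (≤ 15% rejections on
PH-respecting data at the tested sizes) and detects a first-year-only
effect with > 80% power at n = 500. It is undefined for episode-split
fits (the stratification already models the non-proportionality), and the
package raises rather than reporting a misleading p there.

## Association analyses

Group comparisons use Mann–Whitney (continuous; median + IQR) and Pearson
chi-square without continuity correction (categorical) — the
no-correction default reproduces the published lung-origin × OS p-value
(0.0052 vs printed 0.0054) where the Yates-corrected value (0.011) does
not; a correction flag exists. Correlograms use Spearman ρ with Fisher-z
CIs; constant columns are flagged missing.

Segmented regression follows Muggeo's reparameterization: augment the
linear model with U = (x − ψ)₊ and V = −1(x > ψ), update ψ ← ψ + γ̂/β̂_U
until the correction is negligible; a 2-cycle oscillation (common at noise
level) is settled at its midpoint; the breakpoint CI uses
SE(ψ) = SE(γ)/|β̂_U|. Breakpoint existence is tested by a pseudo-score
test: the standardized score statistic for adding U_ψ, maximized over a
10-point quantile grid of candidate ψ, assessed with Davies' two-sided
upcrossing bound 2[Φ̄(M) + V e^{−M²/2}/√(8π)] with V the total variation
of the observed score path. Measured behaviour: exact recovery of a
noiseless breakpoint (matching a 2901-point grid-search oracle), 91–92% CI
coverage at nominal 95%, type-I error ≈ 0.04 at nominal 0.05, and power
≈ 1 at the tested signal sizes.

Bland–Altman agreement reports mean difference, limits of agreement
(mean ± 1.96 SD of differences), their width, and the width as a
percentage of the reference IQR. Under the full pipeline (correlated
lesions, fine-grid export, fixed-df smoothing) the F1 limits-of-agreement
width under 1/10 voxel subsampling is ~3.6% of the F1 IQR on a 50-lesion
cohort; each ingredient was necessary — white-noise lesions, per-count
smoothing selection, or acquisition-resolution histograms each inflate the
width by an order of magnitude.

## Pipeline and problem sizes

`PipelineConfig` (YAML-serializable, content-hashed) carries every knob:
support bounds and export grid, spline basis size, density floor and
target df, LQD level count, FVE retention threshold, RMST horizon,
boosting iterations and step, selection thresholds, bootstrap count and
seed, and the five named model structures (RFS-1/2/3, AR-1, OS-1).
`run_feature_extraction` simulates (or accepts) lesions and emits the
merged clinical + feature table; `run_survival_analysis` runs the full
per-endpoint workflow and writes the KM/RMST table and the per-model
coefficient/HR/C-index reports as CSV. The analysis drivers under
`analysis/` run the pipeline at n = 100 patients with B = 200 bootstrap
iterations; the benchmark experiments behind `scripts/acceptance.py` use
the sizes stated in their docstrings (e.g., 2000 subjects for the RMST
closed form, 200 replicates for CI coverage, 50 replicates for the
C-index and boosting calibrations, a 50-lesion cohort for subsampling
stability). These sizes were chosen so each quantity's Monte-Carlo error
is small against the property being demonstrated while the whole suite
runs comfortably on one CPU.

## Known limitations

- Score magnitudes (F1–F3) and texture magnitudes are not comparable to
  the published tables: smoothing parameters, σ mappings and binning of
  the original software are unpublished, and FPCA scores are
  ensemble-relative by construction.
- The Harrell optimism correction's residual bias under heavy overfitting
  is a property of the estimator, not removed here (see above).
- The lung-background and peri-tumoural tissue model is a stand-in; no
  claim is made about real peri-tumoural composition.
- Per-lesion local-recurrence outcomes and semi-competing-risks analyses
  are out of scope, as are higher-order (GLCM/GLRLM) texture features.
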