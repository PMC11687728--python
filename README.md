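# sbrt-radiomics

CT radiomics and survival modelling for pulmonary metastases treated with
stereotactic body radiotherapy (SBRT). The package implements, end to end
and on fully synthetic data, the analysis workflow of a pre-treatment CT
prognostication study: two radiomic feature-extraction methods, the
patient-level survival machinery that relates those features to
recurrence-free survival (RFS), control of any recurrence (AR) and overall
survival (OS), and the supporting association analyses.

It is written for methodologists and imaging scientists who want a tested,
self-contained reference implementation of this workflow — every stage is
exercised against closed-form oracles or simulations with known ground
truth, because the original patient data are not public.

## What is implemented

**Density-histogram FPCA (data-driven features).** Each lesion's (and its
3 mm peri-tumoural shell's) CT density histogram on [−1000, 500] HU is
smoothed with a penalized log-density spline, mapped through the
log-quantile-density (LQD) transform ψ(p) = log dQ/dp = −log f(Q(p)), and
an ensemble of such curves is decomposed by functional PCA under the
trapezoid inner product. The projection scores F1–F3 (tumour) and
Peri-F1–F3 (shell) are the radiomic features; F1 is oriented so lesions
with a strong high-density (0–150 HU) peak score low.

**Filtration-histogram texture (CTTA).** The axial slice with the largest
tumour cross-section, restricted to pixels ≥ −50 HU, is band-pass filtered
with Laplacian-of-Gaussian kernels at spatial scale filters
SSF ∈ {0, 2, 3, 4, 5, 6} mm, and six first-order statistics (mean, SD,
entropy in bits, mean of positive pixels, skewness, excess kurtosis) are
computed per scale — 36 features per lesion.

**Survival analysis.** Kaplan–Meier curves and log-rank tests on
median-dichotomized variables; restricted mean survival time (RMST) at 36
months with Greenwood-based difference tests; a componentwise-boosting
screen on the Cox partial likelihood (100 iterations, step 0.1, importance
as % in-bag risk reduction); Spearman correlation prefilter and backward
selection; Cox models with interquartile-range-scaled hazard ratios
HR = exp(β·IQR) and a one-year episode split for time-varying age effects;
Harrell optimism-bootstrap corrected concordance indexes; Schoenfeld
proportional-hazards diagnostics.

**Association analyses.** Mann–Whitney/chi-square group comparisons,
Spearman correlograms, Muggeo segmented regression with a Davies-adjusted
pseudo-score breakpoint test, and Bland–Altman agreement analysis.

**Synthetic data.** Spherical-harmonic-perturbed lesions with correlated
HU fields and controllable density profiles, embedded in aerated lung;
cohorts with clinical covariates and RFS/AR/OS outcomes from an
exponential proportional-hazards generator with closed-form calibration.

See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
100-patient cohort (seed 1) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_density_modes_and_stability.py
python analysis/04_texture_size_association.py
python analysis/05_survival_models.py
```

Selected output (abridged):

```
cohort: 100 patients -> results/cohort.csv
  RFS events: 72 (72%), OS events: 38 (38%)
  tumour FPCA: 3 components explain 93% of LQD variance (73%, 17%, 4%)
  F1 vs latent high-density fraction: Spearman rho = -0.88
F1 stability under 1/10 voxel subsampling (50 lesions, 0.4-3.5 cm):
  LoA width = 0.0164 = 3.5% of the F1 IQR
key rank correlations:
  ssf4-entropy vs F1: rho = -0.59
  ssf4-entropy vs size_cm: rho = +0.81
segmented regression of ssf4-entropy on size: breakpoint at 0.85 cm
  (95% CI 0.72-0.98), pseudo-score p = 1.7e-06
  slope below: 4.53 bits/cm, above: 0.30 bits/cm (rise then plateau)
Cox models -> results/cox_model_table.csv
  RFS-3: corrected C = 0.56 (apparent 0.59)
    F1: HR/IQR 0.65 [0.45-0.95], p = 0.0255
  RFS-2: corrected C = 0.56 (apparent 0.59)
    ssf4-entropy: HR/IQR 1.31 [1.02-1.70], p = 0.0374
```

Reading this: the first three FPCA components capture 93% of the density
variation; F1 inversely tracks the latent high-density mass fraction the
generator planted (ρ = −0.88), and a lesion at the 75th F1 percentile has
~0.65 times the recurrence hazard of one at the 25th. Filtered entropy
rises steeply with lesion size until ~0.85 cm and then plateaus — the
small-ROI entropy bias — and higher entropy carries a 1.31-fold recurrence
hazard per IQR. F1 is essentially unchanged when 90% of a lesion's voxels
are discarded (limits-of-agreement width 3.5% of the cohort IQR).

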