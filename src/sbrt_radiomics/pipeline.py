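"""End-to-end orchestration: simulate -> extract -> FPCA -> CTTA ->
survival -> report, with YAML configuration and CSV outputs.

Every number in the reports is produced by a stage function from this
package; the drivers under ``analysis/`` are thin wrappers around the two
entry points here.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ctta, density, fpca, geometry, survival
from .synthetic import CohortSpec, generate_cohort
from .volume import DAYS_PER_MONTH, LesionMask, VoxelVolume, load_mask, load_volume, save_nifti

log = logging.getLogger("sbrt_radiomics")

FPCA_SCORE_COLS = ["F1", "F2", "F3", "periF1", "periF2", "periF3"]


@dataclass
class PipelineConfig:
    """Structured configuration for the full analysis."""

    schema_version: int = 1
    output_dir: str = "results"
    seed: int = 0
    n_patients: int = 100
    # FPCA settings
    lqd_levels: int = 101
    n_basis: int = 35
    density_floor: float = 1e-5
    density_target_edf: float = 15.0
    fve_threshold: float = 0.10
    # density histograms are exported from a fine isotropic resampling of
    # each lesion's grid (longest extent / export_grid_size), emulating the
    # interpolated export of a semi-automatic segmentation tool
    export_grid_size: int = 256
    # survival settings
    rmst_tau_months: float = 36.0
    bootstrap_B: int = 200
    boosting_iterations: int = 100
    boosting_step: float = 0.1
    p_enter: float = 0.10
    p_remove: float = 0.15
    correlation_threshold: float = 0.8
    # named model structures: endpoint + predictor lists
    model_specs: dict = field(default_factory=lambda: {
        "RFS-1": {"endpoint": "rfs", "predictors": ["F1", "F2", "periF3", "age_years"],
                   "time_strata": ["age_years"]},
        "RFS-2": {"endpoint": "rfs", "predictors": ["ssf4-entropy", "F2", "age_years"],
                   "time_strata": ["age_years"]},
        "RFS-3": {"endpoint": "rfs",
                   "predictors": ["F1", "age_years", "indication_group2", "lung_origin"]},
        "AR-1": {"endpoint": "ar",
                  "predictors": ["F1", "age_years", "indication_group2", "lung_origin"]},
        "OS-1": {"endpoint": "os",
                  "predictors": ["size_cm", "ssf4-skewness", "ssf0-kurtosis", "lung_origin"]},
    })

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def write_lesion_files(
    lesions: list[tuple[str, VoxelVolume, LesionMask]], out_dir: str | Path
) -> None:
    """Write one ``<id>_volume.nii.gz`` / ``<id>_mask.nii.gz`` pair per lesion."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, vol, mask in lesions:
        save_nifti(out / f"{pid}_volume.nii.gz", vol)
        save_nifti(out / f"{pid}_mask.nii.gz", mask)


def read_lesion_files(
    in_dir: str | Path, patient_ids: list[str]
) -> list[tuple[str, VoxelVolume, LesionMask]]:
    """Load volume/mask NIfTI pairs; a missing file raises naming the path."""
    src = Path(in_dir)
    lesions = []
    for pid in patient_ids:
        vol_path = src / f"{pid}_volume.nii.gz"
        mask_path = src / f"{pid}_mask.nii.gz"
        for p in (vol_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(f"missing lesion file: {p}")
        lesions.append((pid, load_volume(vol_path), load_mask(mask_path)))
    return lesions


def high_density_fraction(hist: geometry.DensityHistogram, lo=0.0, hi=150.0) -> float:
    """Fraction of voxels with HU in [lo, hi] — used to orient the F1 sign."""
    c = hist.bin_centers
    sel = (c >= lo) & (c <= hi)
    return float(hist.counts[sel].sum() / max(hist.n_voxels, 1))


def extract_cohort_features(
    lesions: list[tuple[str, VoxelVolume, LesionMask]],
    config: PipelineConfig | None = None,
    subsample_fraction: float | None = None,
    subsample_seed: int = 0,
) -> pd.DataFrame:
    """Per-lesion geometry, FPCA scores (tumour + peri) and CTTA features.

    FPCA is fitted on this cohort's LQD curves (separately for tumour and
    peri-tumoural histograms); the first tumour component is oriented so
    high-density-peak lesions get low F1.  If ``subsample_fraction`` is
    given, histograms are recomputed from randomly subsampled masks and
    scored with the SAME FPCA model (columns ``F1_sub`` ...).
    """
    cfg = config or PipelineConfig()

    def _smooth_curve(hist):
        f = density.smooth_density(hist, n_basis=cfg.n_basis, floor=cfg.density_floor,
                                   target_edf=cfg.density_target_edf)
        return density.to_lqd(f, M=cfg.lqd_levels)

    rows, tum_curves, peri_curves, hd_fracs = [], [], [], []
    sub_hists = []  # subsampled-mask histograms (fine grids are not retained)
    for i, (pid, vol, mask) in enumerate(lesions):
        geo = geometry.geometry_summary(vol, mask)
        # density histograms come from the fine isotropic export grid;
        # geometry and 2D texture stay at acquisition resolution
        extent = max(s * n for s, n in zip(vol.spacing, vol.values.shape))
        res_mm = extent / cfg.export_grid_size
        shell = geometry.peri_shell(mask, vol.spacing)
        rvol, rmask = geometry.resample_isotropic(vol, mask, res_mm)
        rshell = geometry.resample_mask(shell, res_mm)
        hist_t = geometry.extract_histogram(rvol, rmask, "tumour")
        hist_p = geometry.extract_histogram(rvol, rshell, "peri")
        hd_fracs.append(high_density_fraction(hist_t))
        tum_curves.append(_smooth_curve(hist_t))
        peri_curves.append(_smooth_curve(hist_p))
        if subsample_fraction is not None:
            sub = geometry.subsample_voxels(rmask, subsample_fraction,
                                            seed=subsample_seed + i)
            sub_hists.append(geometry.extract_histogram(rvol, sub, "tumour"))
        del rvol, rmask, rshell
        row = {"patient_id": pid, **{k: getattr(geo, k) for k in (
            "size", "max_diameter", "mean_diameter", "volume",
            "mean_hu", "sd_hu", "min_hu", "max_hu")}}
        row["volume_ml"] = geo.volume_ml
        try:
            row.update(ctta.ctta_features(vol, mask))
        except ValueError:
            # no analysis pixel >= -50 HU on the largest slice: texture
            # features are flagged missing for this lesion
            row.update({f"ssf{s}-{m}": float("nan")
                        for s in ctta.SSF_VALUES for m in ctta.METRICS})
        rows.append(row)
    feats = pd.DataFrame(rows)
    feats.rename(columns={"size": "size_cm"}, inplace=True)

    tum_model, tum_scores = fpca.fit_fpca(tum_curves, fve_threshold=cfg.fve_threshold)
    tum_model, tum_scores = fpca.orient_tumour_f1(tum_model, tum_scores, np.asarray(hd_fracs))
    peri_model, peri_scores = fpca.fit_fpca(peri_curves, fve_threshold=cfg.fve_threshold)
    for j in range(3):
        feats[f"F{j + 1}"] = tum_scores[:, j] if tum_scores.shape[1] > j else 0.0
        feats[f"periF{j + 1}"] = peri_scores[:, j] if peri_scores.shape[1] > j else 0.0
    feats.attrs["tumour_fpca"] = tum_model
    feats.attrs["peri_fpca"] = peri_model

    if subsample_fraction is not None:
        sub_scores = np.vstack(
            [fpca.score(tum_model, _smooth_curve(h)) for h in sub_hists]
        )
        for j in range(sub_scores.shape[1]):
            feats[f"F{j + 1}_sub"] = sub_scores[:, j]
    return feats


def run_feature_extraction(
    config: PipelineConfig,
    cohort_spec: CohortSpec | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate a cohort (lesion volumes + clinical table), extract all
    features for each patient's largest lesion, and write the merged
    feature table CSV."""
    t0 = time.time()
    spec = cohort_spec or CohortSpec(n_patients=config.n_patients, seed=config.seed)
    table, volumes = generate_cohort(spec, with_volumes=True)
    lesions = [(pid, v, m) for pid, (v, m) in zip(table["patient_id"], volumes)]
    feats = extract_cohort_features(lesions, config)
    # the generator's latent lesion size is kept for ground-truth checks;
    # analyses use the measured size from the segmentation
    table = table.rename(columns={"size_cm": "size_cm_true"})
    merged = table.merge(feats, on="patient_id")
    merged.attrs.update(feats.attrs)  # keep the fitted FPCA models
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    merged.to_csv(out / "cohort_features.csv", index=False)
    log.info("feature extraction: %d patients in %.1fs", len(merged), time.time() - t0)
    return merged


ENDPOINT_COLS = {"rfs": ("rfs_months", "rfs_event"),
                 "ar": ("ar_months", "ar_event"),
                 "os": ("os_months", "os_event")}


def run_survival_analysis(
    config: PipelineConfig,
    table: pd.DataFrame,
    out_dir: str | Path | None = None,
    endpoints: tuple = ("rfs", "ar", "os"),
) -> dict:
    """Per endpoint: KM/log-rank + RMST on median-dichotomized features,
    boosting screen, correlation prefilter + backward selection, final Cox
    fits with IQR HRs, optimism-corrected C-index and Schoenfeld checks.

    Writes Table-3-style (KM/RMST) and Table-4-style (model) CSV reports
    and returns the results keyed by endpoint/model name.
    """
    import warnings

    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"km_rmst": {}, "models": {}, "boosting": {}}

    candidate_features = [c for c in (
        ["age_years", "size_cm", "volume_ml", "mean_hu", "sd_hu"]
        + FPCA_SCORE_COLS
        + [c for c in table.columns if c.startswith("ssf")]
        + ["lung_origin", "indication_group2", "sex_female", "contrast"]
    ) if c in table.columns]
    # drop candidates with flagged-missing values (e.g. MPP when a lesion has
    # no positive filtered pixels) — screening needs complete columns
    candidate_features = [c for c in candidate_features if table[c].notna().all()]

    km_rows = []
    for ep in endpoints:
        dur, ev = ENDPOINT_COLS[ep]
        if table[ev].sum() == 0:
            warnings.warn(f"endpoint {ep}: zero events, skipped")
            continue
        for var in candidate_features:
            x = table[var]
            grp = (survival.dichotomize_at_median(x)
                   if x.nunique() > 2 else x.to_numpy())
            if len(np.unique(grp)) < 2:
                continue
            curves, chi2, p = survival.km_logrank(table[dur], table[ev], grp)
            row = {"endpoint": ep, "variable": var, "logrank_chi2": chi2, "logrank_p": p}
            if p < 0.05:
                r = survival.rmst(table[dur].to_numpy(), table[ev].to_numpy(),
                                  grp, tau=config.rmst_tau_months)
                for gi, lab in enumerate(sorted(r.rmst)):
                    est, se, lo_, hi_ = r.rmst[lab]
                    row[f"rmst_group{gi + 1}"] = est
                    row[f"rmst_group{gi + 1}_ci"] = f"[{lo_:.1f} {hi_:.1f}]"
                row["rmst_diff_p"] = r.p_value
            km_rows.append(row)

        screen = survival.boost_cox(
            table, dur, ev, candidate_features,
            n_iterations=config.boosting_iterations, step=config.boosting_step)
        results["boosting"][ep] = screen
        selected = survival.backward_select(
            table, dur, ev, screen.selected,
            p_enter=config.p_enter, p_remove=config.p_remove,
            correlation_threshold=config.correlation_threshold,
            importance=screen.importance)
        results[f"selected_{ep}"] = selected

    km_table = pd.DataFrame(km_rows)
    km_table.to_csv(out / "km_rmst_table.csv", index=False)
    results["km_rmst"] = km_table

    model_rows = []
    for name, mspec in config.model_specs.items():
        ep = mspec["endpoint"]
        if ep not in endpoints:
            continue
        dur, ev = ENDPOINT_COLS[ep]
        preds = [p_ for p_ in mspec["predictors"] if p_ in table.columns]
        strata = [s for s in mspec.get("time_strata", []) if s in preds]
        split_months = 365.0 / DAYS_PER_MONTH  # one year, in months
        model_tab = table.dropna(subset=preds).reset_index(drop=True)
        try:
            fit = survival.cox_fit(model_tab, dur, ev, preds, time_strata=strata,
                                   split_day=split_months)
        except RuntimeError as exc:
            warnings.warn(f"model {name} failed: {exc}")
            continue
        cindex = survival.corrected_cindex(
            model_tab, dur, ev, preds, B=config.bootstrap_B,
            seed=config.seed, time_strata=strata, split_day=split_months)
        # PH diagnostics: defined only for unstratified fits (the stratified
        # models already encode the time-varying age effect)
        ph = survival.schoenfeld_check(fit) if not strata else None
        results["models"][name] = {"fit": fit, "cindex": cindex, "schoenfeld": ph}
        for pred, r in fit.hazard_ratios.iterrows():
            model_rows.append({
                "model": name, "endpoint": ep, "predictor": pred,
                "hr_iqr": r["hr"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                "p": r["p"],
                "c_index_corrected": cindex.corrected,
                "c_index_apparent": cindex.apparent,
                "c_index_ci": f"[{cindex.ci[0]:.2f} {cindex.ci[1]:.2f}]",
            })
    model_table = pd.DataFrame(model_rows)
    model_table.to_csv(out / "cox_model_table.csv", index=False)
    results["model_table"] = model_table

    with open(out / "run_provenance.json", "w") as fh:
        json.dump({"config_hash": config.config_hash, "seed": config.seed,
                   "n_patients": int(len(table))}, fh, indent=2)
    return results
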