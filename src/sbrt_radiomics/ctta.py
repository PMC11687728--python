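"""2D filtration-histogram CT texture analysis (CTTA).

A band-pass Laplacian-of-Gaussian (LoG) filter is applied to the axial
slice with the largest tumour cross-section at six spatial scale filters
(SSF 0 = unfiltered, then 2-6 mm), and six first-order statistics are
computed over the in-mask analysis pixels: mean, SD, entropy (bits), mean
of positive pixels (MPP), skewness and excess kurtosis -> 36 features.

Analysis pixels are the in-mask pixels with UNFILTERED HU >= -50 (the soft
tissue inclusion rule); the rule defines the pixel set for every SSF.
Filtration is applied to the full slice with edge replication so that
statistics near the ROI boundary see real filter responses rather than
zero padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .volume import LesionMask, VoxelVolume

SSF_VALUES = (0, 2, 3, 4, 5, 6)  # mm
METRICS = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")
HU_INCLUSION = -50.0
ENTROPY_BINS = 64


@dataclass(frozen=True)
class RoiSlice:
    """The analysis slice: full pixel grid, ROI membership, spacing."""

    pixels: np.ndarray  # (ny, nx) HU
    in_roi: np.ndarray  # analysis pixels (mask & HU >= -50)
    pixel_spacing: tuple[float, float]
    slice_index: int


def largest_axial_roi(volume: VoxelVolume, mask: LesionMask) -> RoiSlice:
    """Select the axial slice maximizing the in-mask pixel count (ties to
    the inferior slice) and apply the >= -50 HU inclusion rule."""
    mask.check_aligned(volume)
    per_slice = mask.membership.sum(axis=(1, 2))
    if per_slice.sum() == 0:
        raise ValueError("empty segmentation")
    z = int(np.argmax(per_slice))  # argmax takes the first (inferior) tie
    pixels = volume.values[z]
    roi = mask.membership[z] & (pixels >= HU_INCLUSION)
    if not roi.any():
        raise ValueError("empty analysis ROI: no in-mask pixel >= -50 HU")
    return RoiSlice(
        pixels=pixels,
        in_roi=roi,
        pixel_spacing=(volume.spacing[1], volume.spacing[2]),
        slice_index=z,
    )


def log_kernel(ssf: float, pixel_spacing: tuple[float, float]) -> np.ndarray:
    """Discretized zero-sum LoG kernel with Gaussian sigma = SSF/2 mm.

    The kernel is truncated at 4 sigma per axis and re-centred to exact
    zero sum so constant regions map to exactly zero.
    """
    sigma_mm = ssf / 2.0
    sy = sigma_mm / pixel_spacing[0]
    sx = sigma_mm / pixel_spacing[1]
    ry = max(1, int(np.ceil(4 * sy)))
    rx = max(1, int(np.ceil(4 * sx)))
    y, x = np.mgrid[-ry : ry + 1, -rx : rx + 1]
    ym = y * pixel_spacing[0]
    xm = x * pixel_spacing[1]
    r2 = xm**2 + ym**2
    s2 = sigma_mm**2
    kern = (r2 - 2 * s2) / (s2**2) * np.exp(-r2 / (2 * s2))
    kern -= kern.mean()  # exact zero sum
    return kern


def log_filter(
    image: np.ndarray, ssf: float, pixel_spacing: tuple[float, float]
) -> np.ndarray:
    """LoG band-pass filtration at one spatial scale; SSF 0 = identity."""
    if ssf not in SSF_VALUES:
        raise ValueError(f"unsupported SSF {ssf}; choose from {SSF_VALUES}")
    img = np.asarray(image, dtype=float)
    if ssf == 0:
        return img.copy()
    kern = log_kernel(ssf, pixel_spacing)
    return ndimage.convolve(img, kern, mode="nearest")


def first_order_stats(values: np.ndarray) -> dict[str, float]:
    """Six first-order statistics of the filtered analysis-pixel values.

    Entropy is Shannon entropy in bits over a 64-bin fixed-width histogram
    between min and max; MPP is the mean of strictly positive values (NaN
    when none); skewness/kurtosis are NaN for constant inputs.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no analysis pixels")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    pos = v[v > 0]
    mpp = float(pos.mean()) if pos.size else float("nan")
    if sd == 0:
        return {"mean": mean, "sd": 0.0, "entropy": 0.0,
                "mpp": mpp, "skewness": float("nan"), "kurtosis": float("nan")}
    counts, _ = np.histogram(v, bins=ENTROPY_BINS, range=(v.min(), v.max()))
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "mean": mean,
        "sd": sd,
        "entropy": entropy,
        "mpp": mpp,
        "skewness": float(stats.skew(v, bias=True)),
        "kurtosis": float(stats.kurtosis(v, fisher=True, bias=True)),
    }


def ctta_features(volume: VoxelVolume, mask: LesionMask) -> dict[str, float]:
    """The 36 filtration-histogram features, keyed ``ssf{s}-{metric}``."""
    roi = largest_axial_roi(volume, mask)
    out: dict[str, float] = {}
    for ssf in SSF_VALUES:
        filt = log_filter(roi.pixels, ssf, roi.pixel_spacing)
        st = first_order_stats(filt[roi.in_roi])
        for m in METRICS:
            out[f"ssf{ssf}-{m}"] = st[m]
    return out
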