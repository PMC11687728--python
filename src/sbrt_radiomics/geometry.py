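"""Geometric summaries, CT density histograms, peri-tumoural shells and
voxel subsampling for segmented lesions.

The CT density histogram is the raw material of the density-FPCA feature
chain: 1-HU bins on the fixed support [-1000, 500] HU, with out-of-support
voxels clipped to the nearest bound so voxel counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .volume import LesionMask, VoxelVolume

HU_SUPPORT = (-1000.0, 500.0)
N_BINS = 1500  # 1-HU bins on [-1000, 500]


@dataclass(frozen=True)
class GeometrySummary:
    """Linear measurements, volume and first-order HU statistics of a lesion.

    ``size`` is the maximal axial in-plane diameter in cm; ``max_diameter``
    the largest pairwise 3D distance between in-mask voxel centres (mm);
    ``mean_diameter`` the mean over axial slices of the per-slice maximal
    in-plane diameter (mm).
    """

    size: float
    max_diameter: float
    mean_diameter: float
    volume: float  # mm^3
    mean_hu: float
    sd_hu: float
    min_hu: float
    max_hu: float

    @property
    def volume_ml(self) -> float:
        return self.volume / 1000.0


@dataclass(frozen=True)
class DensityHistogram:
    """Counts of in-mask voxels in 1-HU bins spanning [-1000, 500] HU."""

    bin_edges: np.ndarray
    counts: np.ndarray
    region_label: str = "tumour"

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(counts) != len(edges) - 1:
            raise ValueError("counts/edges length mismatch")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_voxels(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"hu_bin_center": self.bin_centers, "count": self.counts}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, region_label: str = "tumour") -> "DensityHistogram":
        df = pd.read_csv(path)
        centers = df["hu_bin_center"].to_numpy(dtype=float)
        width = centers[1] - centers[0]
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        return cls(bin_edges=edges, counts=df["count"].to_numpy(), region_label=region_label)


def _voxel_coords_mm(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx * np.asarray(spacing, dtype=float)


def _max_pairwise_diameter(coords: np.ndarray) -> float:
    """Largest pairwise distance; convex-hull reduction for big masks."""
    if len(coords) == 1:
        return 0.0
    pts = coords
    if len(pts) > 400:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    return float(pdist(pts).max())


def geometry_summary(volume: VoxelVolume, mask: LesionMask) -> GeometrySummary:
    """Compute linear measurements, volume and HU moments of a lesion."""
    mask.check_aligned(volume)
    m = mask.membership
    if not m.any():
        raise ValueError("empty segmentation")
    spacing = volume.spacing
    coords = _voxel_coords_mm(m, spacing)
    max_d = _max_pairwise_diameter(coords)

    # per-axial-slice maximal in-plane diameter, slices weighted equally
    slice_diams = []
    in_plane = (spacing[1], spacing[2])
    for z in np.unique(np.argwhere(m)[:, 0]):
        sl = np.argwhere(m[z]) * np.asarray(in_plane)
        slice_diams.append(_max_pairwise_diameter(sl))
    mean_d = float(np.mean(slice_diams))
    size_cm = max(slice_diams) / 10.0

    hu = volume.values[m]
    return GeometrySummary(
        size=size_cm,
        max_diameter=max_d,
        mean_diameter=mean_d,
        volume=mask.n_voxels * volume.voxel_volume_mm3,
        mean_hu=float(hu.mean()),
        sd_hu=float(hu.std(ddof=0)),
        min_hu=float(hu.min()),
        max_hu=float(hu.max()),
    )


def extract_histogram(
    volume: VoxelVolume, mask: LesionMask, region_label: str = "tumour"
) -> DensityHistogram:
    """Bin in-mask HU values into 1-HU bins on [-1000, 500].

    Out-of-support values are clipped to the nearest bound (not discarded),
    so the histogram conserves the in-mask voxel count.
    """
    mask.check_aligned(volume)
    if not mask.membership.any():
        raise ValueError("empty segmentation")
    lo, hi = HU_SUPPORT
    hu = np.clip(volume.values[mask.membership], lo, hi)
    edges = np.linspace(lo, hi, N_BINS + 1)
    counts, _ = np.histogram(hu, bins=edges)
    # np.histogram puts hi into the last bin already; clipping handled above
    return DensityHistogram(bin_edges=edges, counts=counts, region_label=region_label)


def resample_isotropic(
    volume: VoxelVolume, mask: LesionMask, spacing_mm: float = 0.3
) -> tuple[VoxelVolume, LesionMask]:
    """Resample a volume/mask pair to a fine isotropic grid (linear HU
    interpolation, nearest-neighbour mask).

    This emulates the sub-voxel interpolation a multiplanar semi-automatic
    segmentation tool performs before exporting 3D density histograms: the
    counts grow by the subdivision factor while neighbouring sub-voxel
    values become smooth interpolates of the acquired data.
    """
    factors = tuple(s / spacing_mm for s in volume.spacing)
    vals = ndimage.zoom(volume.values, factors, order=1, mode="nearest")
    memb = ndimage.zoom(mask.membership.astype(np.uint8), factors, order=0,
                        mode="nearest").astype(bool)
    sp = (spacing_mm,) * 3
    return VoxelVolume(values=vals, spacing=sp), LesionMask(membership=memb, spacing=sp)


def resample_mask(mask: LesionMask, spacing_mm: float) -> LesionMask:
    """Nearest-neighbour resample of a mask onto the same isotropic grid
    :func:`resample_isotropic` produces for a congruent volume."""
    factors = tuple(s / spacing_mm for s in mask.spacing)
    memb = ndimage.zoom(mask.membership.astype(np.uint8), factors, order=0,
                        mode="nearest").astype(bool)
    return LesionMask(membership=memb, spacing=(spacing_mm,) * 3)


def peri_shell(
    mask: LesionMask,
    spacing: tuple[float, float, float] | None = None,
    thickness: float = 3.0,
) -> LesionMask:
    """Peri-tumoural shell: voxels at Euclidean distance in (0, thickness] mm
    from the lesion surface, computed with anisotropic spacing.

    The shell is disjoint from the lesion and deliberately NOT clipped to
    lung parenchyma; at the image boundary it is silently truncated.
    """
    if not mask.membership.any():
        raise ValueError("empty segmentation")
    sp = spacing if spacing is not None else mask.spacing
    dist = ndimage.distance_transform_edt(~mask.membership, sampling=sp)
    shell = (dist > 0) & (dist <= thickness)
    return LesionMask(membership=shell, spacing=tuple(sp))


def subsample_voxels(mask: LesionMask, fraction: float, seed: int) -> LesionMask:
    """Retain ``round(fraction * N)`` in-mask voxels uniformly without
    replacement; deterministic per seed."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return mask
    rng = np.random.default_rng(seed)
    idx = np.argwhere(mask.membership)
    n_keep = int(round(fraction * len(idx)))
    keep = rng.choice(len(idx), size=n_keep, replace=False)
    out = np.zeros_like(mask.membership)
    sel = idx[keep]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return LesionMask(membership=out, spacing=mask.spacing)
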