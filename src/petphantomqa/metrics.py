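"""Semi-quantitative PET image-quality metrics.

Implements the standard NEMA-style battery on voxel volumes and boolean
VOIs: background noise (CoV_BG), contrast-to-noise ratio with the Rose
visibility criterion (CNR >= 5), recovery coefficients (RC_mean, RC_max),
SUV_peak (mean over a 1 ml sphere at the hottest position), and SUV
differences versus a reference frame.  All statistics use the sample
standard deviation (n-1 denominator).

The pipeline works in activity-concentration units (kBq/ml); for a phantom
SUV is a global rescaling, and every metric here is either invariant under
that rescaling (CoV, CNR, RC) or transparent to it (SUV/deltaSUV values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import VoxelGrid, diameter_mm_from_volume
from .segmentation import VOISet

__all__ = [
    "BackgroundMetrics",
    "SphereMetrics",
    "ROSE_CNR_THRESHOLD",
    "cov_bg",
    "background_metrics",
    "cnr",
    "is_visible",
    "recovery_coefficients",
    "suv_peak",
    "delta_suv",
    "sphere_metrics",
]

#: Rose criterion: an object is considered visible when CNR >= 5.
ROSE_CNR_THRESHOLD = 5.0


@dataclass(frozen=True)
class BackgroundMetrics:
    per_voi_mean: tuple[float, ...]
    per_voi_sd: tuple[float, ...]
    cov_bg_percent: float


@dataclass(frozen=True)
class SphereMetrics:
    nominal_diameter_mm: float
    suv_mean: float
    suv_max: float
    suv_peak: float
    rc_mean: float
    rc_max: float
    cnr: float
    visible: bool


def background_metrics(image: np.ndarray, background_vois) -> BackgroundMetrics:
    """Per-VOI mean/SD and the mean coefficient of variation (percent)."""
    means, sds = [], []
    for m in background_vois:
        vals = image[m]
        if vals.size == 0:
            raise ValueError("empty background VOI")
        mu = float(vals.mean())
        if mu <= 0:
            raise ValueError(f"non-positive background VOI mean ({mu:g})")
        means.append(mu)
        sds.append(float(vals.std(ddof=1)))
    cov = float(np.mean([100.0 * s / m for s, m in zip(sds, means)]))
    return BackgroundMetrics(tuple(means), tuple(sds), cov)


def cov_bg(image: np.ndarray, background_vois) -> float:
    """Image noise CoV_BG: mean over the background VOIs of 100*SD/mean."""
    return background_metrics(image, background_vois).cov_bg_percent


def cnr(image: np.ndarray, sphere_mask: np.ndarray, background_vois) -> float:
    """Contrast-to-noise ratio of one sphere.

    (sphere VOI mean - mean of the three background VOI means) divided by
    the mean of the three background VOI standard deviations.  A noiseless
    image (zero background SD) yields +/-inf, reported as such rather than
    raising, so callers can serialize it distinctly.
    """
    if not np.any(sphere_mask):
        raise ValueError("empty sphere mask")
    bg = background_metrics(image, background_vois)
    mean_sd = float(np.mean(bg.per_voi_sd))
    contrast = float(image[sphere_mask].mean()) - float(np.mean(bg.per_voi_mean))
    if mean_sd == 0.0:
        return float("inf") if contrast > 0 else (float("-inf") if contrast < 0 else 0.0)
    return contrast / mean_sd


def is_visible(cnr_value: float) -> bool:
    """Rose criterion, boundary inclusive."""
    return bool(cnr_value >= ROSE_CNR_THRESHOLD)


def recovery_coefficients(
    image: np.ndarray, sphere_mask: np.ndarray, true_concentration: float
) -> tuple[float, float]:
    """(RC_mean, RC_max): VOI mean and maximum relative to the actual
    activity concentration in the sphere."""
    if true_concentration <= 0:
        raise ValueError("true_concentration must be positive")
    if not np.any(sphere_mask):
        raise ValueError("empty sphere mask")
    vals = image[sphere_mask]
    return float(vals.mean()) / true_concentration, float(vals.max()) / true_concentration


def _peak_kernel(grid: VoxelGrid, volume_ml: float) -> np.ndarray:
    """Boolean voxel ball approximating a ``volume_ml`` sphere."""
    r_mm = diameter_mm_from_volume(volume_ml) / 2.0
    half = [int(np.floor(r_mm / v)) for v in grid.voxel_size_mm]
    ax = [np.arange(-h, h + 1) * v for h, v in zip(half, grid.voxel_size_mm)]
    d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    return d2 <= r_mm**2


def suv_peak(
    image: np.ndarray,
    sphere_mask: np.ndarray,
    grid: VoxelGrid,
    peak_volume_ml: float = 1.0,
) -> float:
    """SUV_peak: mean over a 1 ml sphere centred at the position inside the
    mask maximizing that local mean (EANM convention).

    If the mask holds fewer voxels than the peak sphere, the plain mask mean
    is returned with a warning.
    """
    if not np.any(sphere_mask):
        raise ValueError("empty sphere mask")
    kernel = _peak_kernel(grid, peak_volume_ml)
    if int(np.count_nonzero(sphere_mask)) < int(kernel.sum()):
        warnings.warn(
            "sphere mask smaller than the SUV_peak sphere; falling back to mask mean",
            stacklevel=2,
        )
        return float(image[sphere_mask].mean())
    # local means only needed near the mask: crop to a padded bounding box
    idx = np.argwhere(sphere_mask)
    lo = np.maximum(idx.min(axis=0) - np.array(kernel.shape) // 2, 0)
    hi = np.minimum(idx.max(axis=0) + np.array(kernel.shape) // 2 + 1, image.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    local_mean = ndimage.correlate(
        np.asarray(image[sl], dtype=np.float64),
        kernel.astype(np.float64) / kernel.sum(),
        mode="nearest",
    )
    return float(local_mean[sphere_mask[sl]].max())


def delta_suv(
    image: np.ndarray,
    reference: np.ndarray,
    sphere_vois: dict[float, np.ndarray],
) -> dict:
    """Absolute per-sphere SUV_mean / SUV_max differences versus a
    reference frame, plus their mean and SD across spheres.

    Returns ``{"per_sphere": {d: (dmean, dmax)}, "mean_dmean", "sd_dmean",
    "mean_dmax", "sd_dmax"}``.
    """
    if image.shape != reference.shape:
        raise ValueError("image and reference must share a grid")
    per = {}
    for d, m in sphere_vois.items():
        dmean = abs(float(image[m].mean()) - float(reference[m].mean()))
        dmax = abs(float(image[m].max()) - float(reference[m].max()))
        per[d] = (dmean, dmax)
    dmeans = np.array([v[0] for v in per.values()])
    dmaxs = np.array([v[1] for v in per.values()])
    agg_sd = lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0
    return {
        "per_sphere": per,
        "mean_dmean": float(dmeans.mean()) if per else float("nan"),
        "sd_dmean": agg_sd(dmeans) if per else float("nan"),
        "mean_dmax": float(dmaxs.mean()) if per else float("nan"),
        "sd_dmax": agg_sd(dmaxs) if per else float("nan"),
    }


def sphere_metrics(
    image: np.ndarray,
    vois: VOISet,
    true_concentration: float,
    diameter_mm: float,
) -> SphereMetrics:
    """All per-sphere metrics for one segmented sphere of a VOI set."""
    mask = vois.sphere_vois[diameter_mm]
    rc_mean, rc_max = recovery_coefficients(image, mask, true_concentration)
    vals = image[mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        peak = suv_peak(image, mask, vois.grid)
    c = cnr(image, mask, vois.background_vois)
    return SphereMetrics(
        nominal_diameter_mm=diameter_mm,
        suv_mean=float(vals.mean()),
        suv_max=float(vals.max()),
        suv_peak=peak,
        rc_mean=rc_mean,
        rc_max=rc_max,
        cnr=c,
        visible=is_visible(c),
    )
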