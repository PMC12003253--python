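"""Analysis VOIs: background compartments and adaptive sphere isocontours.

The metric battery reads two kinds of regions: three large uniform
background VOIs (131 ml each by default) placed well clear of the spheres,
the lung insert and the phantom wall, and one mask per sphere obtained by a
background-corrected 50% isocontour:

    T = bg_mean + 0.5 * (max_in_region - bg_mean)

with the mask taken as the 26-connected component above T that contains
the regional maximum.  VOIs are segmented once on a setup's ground-truth
frame and then frozen for every other frame of that setup, mirroring how
phantom analyses keep a single VOI set per physical filling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import LABEL_BACKGROUND, LabelVolume, VoxelGrid
from .simulate import ScanVolume, fwhm_to_sigma_mm

__all__ = [
    "VOISet",
    "SegmentationError",
    "place_background_vois",
    "segment_sphere_isocontour",
    "build_voi_set",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Default background-VOI sphere centres (mm, phantom frame): 120 degree
#: spacing on a 75 mm ring, in a transaxial plane 70 mm below the sphere
#: plane.  Clears spheres, lung insert and shell by >= 15 mm for the
#: default geometry.
DEFAULT_BG_VOI_CENTERS_MM = (
    (75.0, 0.0, -35.0),
    (-37.5, 64.9519052838329, -35.0),
    (-37.5, -64.9519052838329, -35.0),
)


class SegmentationError(RuntimeError):
    """Raised when a requested region cannot be constructed."""


@dataclass
class VOISet:
    """Frozen analysis regions bound to one grid.

    ``sphere_vois`` maps nominal inner diameter (mm) to a boolean mask;
    spheres that could not be segmented are listed in ``missing_spheres``
    with the reason instead of being returned as empty masks.
    """

    grid: VoxelGrid
    background_vois: list[np.ndarray]
    sphere_vois: dict[float, np.ndarray]
    missing_spheres: dict[float, str] = field(default_factory=dict)
    segmented_on: str = ""

    def __post_init__(self) -> None:
        masks = list(self.background_vois) + list(self.sphere_vois.values())
        for i, a in enumerate(masks):
            for b in masks[i + 1 :]:
                if np.any(a & b):
                    raise ValueError("VOIs must be pairwise disjoint")


def place_background_vois(
    labels: LabelVolume,
    target_volume_ml: float = 131.0,
    n: int = 3,
    centers_mm=DEFAULT_BG_VOI_CENTERS_MM,
) -> list[np.ndarray]:
    """``n`` sphere-shaped background VOIs of ~``target_volume_ml`` each.

    Each VOI is grown around its centre to the voxel count nearest the
    target volume; all of its voxels must carry the background label, so a
    VOI that would spill into a sphere, the lung insert or outside the
    phantom raises a :class:`SegmentationError` reporting the achievable
    volume.
    """
    if n > len(centers_mm):
        raise ValueError(f"need {n} centres, got {len(centers_mm)}")
    vox_ml = labels.grid.voxel_volume_ml
    k_target = max(1, round(target_volume_ml / vox_ml))
    xs, ys, zs = labels.grid.axis_coordinates_mm()
    bg = labels.labels == LABEL_BACKGROUND
    out = []
    for c in centers_mm[:n]:
        d2 = (
            (xs[:, None, None] - c[0]) ** 2
            + (ys[None, :, None] - c[1]) ** 2
            + (zs[None, None, :] - c[2]) ** 2
        )
        order = np.argsort(d2, axis=None, kind="stable")[:k_target]
        mask = np.zeros(labels.labels.shape, dtype=bool)
        mask.flat[order] = True
        if not np.all(bg.flat[order]):
            achievable = int(np.count_nonzero(bg.flat[order])) * vox_ml
            raise SegmentationError(
                f"background VOI at {c} mm would leave the background "
                f"compartment; achievable volume {achievable:.1f} ml of "
                f"{target_volume_ml:.1f} ml requested"
            )
        out.append(mask)
    for i, a in enumerate(out):
        for b in out[i + 1 :]:
            if np.any(a & b):
                raise SegmentationError("background VOIs overlap; move centres apart")
    return out


def segment_sphere_isocontour(
    image: np.ndarray,
    search_region: np.ndarray,
    bg_mean: float,
) -> np.ndarray:
    """Background-corrected 50% isocontour mask within a search region.

    Threshold ``T = bg_mean + 0.5 * (max - bg_mean)`` with the maximum taken
    over the search region; the mask is the 26-connected component above T
    containing the maximum voxel (ties broken by lowest linear index).
    Raises :class:`SegmentationError` when the region holds no contrast
    above the background (a non-detectable sphere), never returning an
    empty mask silently.
    """
    if not np.any(search_region):
        raise ValueError("search_region is empty")
    vals = np.where(search_region, image, -np.inf)
    vmax = float(vals.max())
    # contrast must exceed background beyond float accumulation noise
    if not vmax - bg_mean > 1e-9 * max(abs(vmax), abs(bg_mean)):
        raise SegmentationError(
            f"sphere not segmentable: regional maximum {vmax:.4g} does not "
            f"exceed background mean {bg_mean:.4g}"
        )
    threshold = bg_mean + 0.5 * (vmax - bg_mean)
    above = search_region & (image >= threshold)
    comp, _ = ndimage.label(above, structure=_CONN26)
    max_index = int(np.flatnonzero(vals.reshape(-1) == vmax)[0])
    mask = comp == comp.flat[max_index]
    return mask


def build_voi_set(
    reference_scan: ScanVolume,
    labels: LabelVolume,
    target_volume_ml: float = 131.0,
    search_dilation_fwhm: float = 2.0,
    bg_centers_mm=DEFAULT_BG_VOI_CENTERS_MM,
) -> VOISet:
    """Segment every sphere on the ground-truth frame and freeze the VOIs.

    The search region for each sphere is the true sphere dilated by
    ``search_dilation_fwhm`` times the scan's PSF FWHM (at least one voxel),
    which keeps distant noise spikes from hijacking the adaptive threshold.
    Unsegmentable spheres are recorded in ``missing_spheres`` with the
    reason; the remaining VOIs are still returned.
    """
    grid = labels.grid
    bg_vois = place_background_vois(
        labels, target_volume_ml=target_volume_ml, centers_mm=bg_centers_mm
    )
    bg_mean = float(np.mean([reference_scan.values[m].mean() for m in bg_vois]))

    xs, ys, zs = grid.axis_coordinates_mm()
    margin = max(
        search_dilation_fwhm * reference_scan.psf_fwhm_mm, max(grid.voxel_size_mm)
    )
    sphere_vois: dict[float, np.ndarray] = {}
    missing: dict[float, str] = {}
    for k, d in enumerate(labels.sphere_diameters_mm):
        # analytic dilation: ball of radius r + margin around the true centre
        true_mask = labels.sphere_mask(d)
        idx = np.argwhere(true_mask)
        center = (
            xs[idx[:, 0]].mean(),
            ys[idx[:, 1]].mean(),
            zs[idx[:, 2]].mean(),
        )
        r = d / 2.0 + margin
        d2 = (
            (xs[:, None, None] - center[0]) ** 2
            + (ys[None, :, None] - center[1]) ** 2
            + (zs[None, None, :] - center[2]) ** 2
        )
        search = d2 <= r * r
        try:
            sphere_vois[d] = segment_sphere_isocontour(
                reference_scan.values, search, bg_mean
            )
        except SegmentationError as exc:
            missing[d] = str(exc)
    return VOISet(
        grid=grid,
        background_vois=bg_vois,
        sphere_vois=sphere_vois,
        missing_spheres=missing,
        segmented_on=f"{reference_scan.setup.name}_{reference_scan.duration_s:g}s",
    )
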