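"""Masked image-to-image comparison: SSIM, PSNR and MAE.

All three metrics compare a volume against the ground-truth frame inside a
phantom mask (voxel space outside the phantom excluded).  SSIM is the mean
of the local volumetric SSIM map over the mask (Gaussian window, sigma 1.5
voxels, K1=0.01, K2=0.03); its data range is taken from the reference
inside the mask, so the comparison depends on the reference only.  PSNR is
referenced to a caller-supplied peak — by convention SUV_peak of the
largest (37 mm) sphere in the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["SimilarityRecord", "masked_ssim", "masked_psnr", "masked_mae", "compare"]


@dataclass(frozen=True)
class SimilarityRecord:
    ssim: float
    psnr_db: float  # +inf for an exact match
    mae: float


def _check(image: np.ndarray, reference: np.ndarray, mask: np.ndarray) -> None:
    if image.shape != reference.shape or image.shape != mask.shape:
        raise ValueError("image, reference and mask must share a grid")
    if not np.any(mask):
        raise ValueError("mask is empty")


def masked_ssim(
    image: np.ndarray,
    reference: np.ndarray,
    phantom_mask: np.ndarray,
    sigma: float = 1.5,
) -> float:
    """Mean local SSIM over the mask, Gaussian-weighted 3D windows."""
    _check(image, reference, phantom_mask)
    data_range = float(reference[phantom_mask].max() - min(0.0, reference[phantom_mask].min()))
    if data_range <= 0:
        raise ValueError("reference has zero data range inside the mask")
    _, ssim_map = structural_similarity(
        np.asarray(reference, dtype=np.float64),
        np.asarray(image, dtype=np.float64),
        data_range=data_range,
        gaussian_weights=True,
        sigma=sigma,
        use_sample_covariance=False,
        full=True,
    )
    return float(ssim_map[phantom_mask].mean())


def masked_psnr(
    image: np.ndarray,
    reference: np.ndarray,
    phantom_mask: np.ndarray,
    peak: float,
) -> float:
    """10 log10(peak^2 / MSE) over mask voxels; +inf when MSE is zero."""
    _check(image, reference, phantom_mask)
    if peak <= 0:
        raise ValueError("peak must be positive")
    diff = np.asarray(image, dtype=np.float64)[phantom_mask] - np.asarray(
        reference, dtype=np.float64
    )[phantom_mask]
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def masked_mae(image: np.ndarray, reference: np.ndarray, phantom_mask: np.ndarray) -> float:
    """Mean absolute voxel difference over the mask."""
    _check(image, reference, phantom_mask)
    return float(
        np.mean(
            np.abs(
                np.asarray(image, dtype=np.float64)[phantom_mask]
                - np.asarray(reference, dtype=np.float64)[phantom_mask]
            )
        )
    )


def compare(
    image: np.ndarray,
    reference: np.ndarray,
    phantom_mask: np.ndarray,
    peak: float,
) -> SimilarityRecord:
    return SimilarityRecord(
        ssim=masked_ssim(image, reference, phantom_mask),
        psnr_db=masked_psnr(image, reference, phantom_mask, peak),
        mae=masked_mae(image, reference, phantom_mask),
    )
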