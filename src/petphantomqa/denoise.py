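"""Gaussian FWHM post-filtering and a pluggable denoiser contract.

Reconstruction post-filters are conventionally specified by their FWHM in
mm (G2 ... G20 for 2-20 mm).  This module applies them post hoc to the
simulated volumes — equivalent under the simulator's linear image model —
and exposes a uniform :class:`DenoiserSpec` slot so that any external
volume-to-volume denoiser (e.g. a trained network) can be benchmarked
through the same pipeline via a NIfTI file contract.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .simulate import ScanVolume

__all__ = [
    "DenoiserSpec",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "gaussian_postfilter",
    "apply_denoiser",
    "parse_denoiser_spec",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """sigma = FWHM / (2 sqrt(2 ln 2)) ~ FWHM / 2.35482."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    return fwhm_mm / _FWHM_PER_SIGMA


def sigma_to_fwhm(sigma_mm: float) -> float:
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    return sigma_mm * _FWHM_PER_SIGMA


@dataclass(frozen=True)
class DenoiserSpec:
    """A named denoiser: identity, gaussian:<fwhm>, median:<k>, or an
    external executable obeying the NIfTI in/out contract."""

    name: str
    kind: str = "identity"  # identity | gaussian | median | external
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in {"identity", "gaussian", "median", "external"}:
            raise ValueError(f"unknown denoiser kind {self.kind!r}")
        if self.kind == "gaussian" and not self.params.get("fwhm_mm", 0) > 0:
            raise ValueError("gaussian denoiser requires fwhm_mm > 0")
        if self.kind == "median" and not self.params.get("size", 0) >= 1:
            raise ValueError("median denoiser requires size >= 1")
        if self.kind == "external" and not self.params.get("command"):
            raise ValueError("external denoiser requires a command")


def parse_denoiser_spec(text: str) -> DenoiserSpec:
    """Parse ``identity | gaussian:<fwhm> | median:<k> | external:<cmd>``."""
    kind, _, arg = text.partition(":")
    if kind == "identity":
        return DenoiserSpec(name="identity")
    if kind == "gaussian":
        return DenoiserSpec(name=f"G{float(arg):g}", kind="gaussian", params={"fwhm_mm": float(arg)})
    if kind == "median":
        return DenoiserSpec(name=f"median{int(arg)}", kind="median", params={"size": int(arg)})
    if kind == "external":
        return DenoiserSpec(name="external", kind="external", params={"command": arg})
    raise ValueError(f"cannot parse denoiser spec {text!r}")


def gaussian_postfilter(image: ScanVolume, fwhm_mm: float) -> ScanVolume:
    """Separable Gaussian post-filter with per-axis sigma in voxels.

    Boundary mode is nearest-neighbour replication, which keeps the flat
    background flat at the volume edge; a constant image passes through
    unchanged and the DC level is preserved.
    """
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    sigma_vox = [sigma_mm / v for v in image.grid.voxel_size_mm]
    filtered = ndimage.gaussian_filter(
        np.asarray(image.values, dtype=np.float64), sigma_vox, mode="nearest"
    )
    return image.with_values(filtered, variant=f"G{fwhm_mm:g}")


def _run_external(command: str, image: ScanVolume, timeout_s: float) -> np.ndarray:
    from . import io as qa_io  # local import: io pulls in nibabel

    with tempfile.TemporaryDirectory() as td:
        src = Path(td) / "input.nii"
        dst = Path(td) / "output.nii"
        qa_io.write_nifti(src, image.values, image.grid)
        proc = subprocess.run(
            [*command.split(), str(src), str(dst)],
            capture_output=True,
            text=True,
            timeout=timeout_s,
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"external denoiser failed (exit {proc.returncode}): {proc.stderr[-500:]}"
            )
        values, grid = qa_io.read_nifti(dst)
        if values.shape != image.values.shape:
            raise RuntimeError(
                f"external denoiser changed the grid: {values.shape} != {image.values.shape}"
            )
        return values


def apply_denoiser(spec: DenoiserSpec, image: ScanVolume, timeout_s: float = 600.0) -> ScanVolume:
    """Apply a denoiser spec; the identity spec returns the input volume
    bit-identically (same array object semantics as a copy)."""
    if spec.kind == "identity":
        return image.with_values(image.values.copy(), variant=spec.name)
    if spec.kind == "gaussian":
        out = gaussian_postfilter(image, spec.params["fwhm_mm"])
        return out.with_values(out.values, variant=spec.name)
    if spec.kind == "median":
        k = int(spec.params["size"])
        filtered = ndimage.median_filter(
            np.asarray(image.values, dtype=np.float64), size=k, mode="nearest"
        )
        return image.with_values(filtered, variant=spec.name)
    if spec.kind == "external":
        values = _run_external(spec.params["command"], image, timeout_s)
        return image.with_values(np.asarray(values, dtype=np.float64), variant=spec.name)
    raise ValueError(f"unknown denoiser kind {spec.kind!r}")
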