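"""Synthetic PET acquisition model for the NEMA body phantom.

Generates reconstructed-image surrogates whose count statistics scale the
way list-mode rebinning does: expected true counts are exactly linear in
acquisition duration, reduced by a global attenuation factor for the obese
habitus, and contrast is set by the sphere-to-background ratio (SBR).

The forward model is deliberately simple: the activity map (kBq/ml) is
blurred with an isotropic Gaussian system PSF, converted to a per-voxel
Poisson mean

    lambda = concentration * voxel_volume_ml * duration_s * sensitivity
             * attenuation_factor,

and an independent Poisson count is drawn per voxel, then converted back to
a concentration estimate.  In a uniform region this reproduces the
characteristic noise scaling CoV = 100 / sqrt(lambda), hence a power law
CoV ~ t^(-1/2) across frame durations.  Real iterative reconstructions have
spatially correlated noise; see docs/methods.md for what this model does
and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator

import numpy as np
from scipy import ndimage

from .geometry import (
    LABEL_BACKGROUND,
    LABEL_LUNG,
    LABEL_OUTSIDE,
    SPHERE_LABEL_START,
    LabelVolume,
    VoxelGrid,
)

__all__ = [
    "Habitus",
    "AcquisitionSetup",
    "DurationSchedule",
    "ScanVolume",
    "duration_schedule",
    "activity_map",
    "expected_counts",
    "calibrate_sensitivity",
    "simulate",
    "generate_study_inputs",
    "default_setups",
    "fwhm_to_sigma_mm",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.35482


def fwhm_to_sigma_mm(fwhm_mm: float) -> float:
    return fwhm_mm / _FWHM_PER_SIGMA


class Habitus(str, Enum):
    THIN = "thin"
    OBESE = "obese"


@dataclass(frozen=True)
class AcquisitionSetup:
    """One phantom filling/wrapping condition.

    ``sbr`` is the sphere-to-background activity ratio (4 and 10 in the
    reference protocol); the obese habitus is emulated as a global true-count
    reduction ``attenuation_factor`` (default 0.53, the midpoint of the
    observed 52-54% count fraction) rather than a spatial attenuation map.
    ``sensitivity_cps_per_kBq`` is the calibration constant linking activity
    to detected true counts; see :func:`calibrate_sensitivity`.
    """

    sbr: float = 4.0
    habitus: Habitus = Habitus.THIN
    bg_activity_kBq_ml: float = 5.3
    obese_attenuation_factor: float = 0.53
    sensitivity_cps_per_kBq: float = 1.0

    def __post_init__(self) -> None:
        if self.sbr < 1:
            raise ValueError("sbr must be >= 1")
        if not 0 < self.obese_attenuation_factor <= 1:
            raise ValueError("obese_attenuation_factor must be in (0, 1]")
        if self.bg_activity_kBq_ml <= 0 or self.sensitivity_cps_per_kBq <= 0:
            raise ValueError("activity and sensitivity must be positive")

    @property
    def attenuation_factor(self) -> float:
        return 1.0 if self.habitus is Habitus.THIN else self.obese_attenuation_factor

    @property
    def name(self) -> str:
        return f"SBR{self.sbr:g}_{self.habitus.value}"

    def with_sensitivity(self, sensitivity: float) -> "AcquisitionSetup":
        return replace(self, sensitivity_cps_per_kBq=sensitivity)


def default_setups(sensitivity: float = 1.0) -> list[AcquisitionSetup]:
    """The four study conditions: {SBR4, SBR10} x {thin, obese}."""
    return [
        AcquisitionSetup(sbr=sbr, habitus=hab, sensitivity_cps_per_kBq=sensitivity)
        for sbr in (4.0, 10.0)
        for hab in (Habitus.THIN, Habitus.OBESE)
    ]


@dataclass(frozen=True)
class DurationSchedule:
    durations_s: tuple[float, ...]

    def __post_init__(self) -> None:
        d = self.durations_s
        if any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("durations must be positive and strictly increasing")

    def __len__(self) -> int:
        return len(self.durations_s)

    def __iter__(self):
        return iter(self.durations_s)


def duration_schedule() -> DurationSchedule:
    """The 13 frame durations: 5 s, 10 s, then 20 s to 200 s in 20 s steps,
    plus the full 900 s acquisition."""
    return DurationSchedule((5.0, 10.0) + tuple(float(t) for t in range(20, 201, 20)) + (900.0,))


class SimulationMode(str, Enum):
    SAMPLE = "sample"
    EXPECTATION = "expectation"


@dataclass
class ScanVolume:
    """A reconstructed-image surrogate: concentration estimates on a grid."""

    grid: VoxelGrid
    values: np.ndarray  # kBq/ml
    setup: AcquisitionSetup
    duration_s: float
    psf_fwhm_mm: float = 0.0
    seed: int | None = None
    expected_true_counts: float = 0.0
    mode: SimulationMode = SimulationMode.SAMPLE
    variant: str = "raw"

    def with_values(self, values: np.ndarray, variant: str | None = None) -> "ScanVolume":
        out = ScanVolume(**{**self.__dict__})
        out.values = values
        if variant is not None:
            out.variant = variant
        return out


def activity_map(labels: LabelVolume, setup: AcquisitionSetup) -> np.ndarray:
    """True activity concentration (kBq/ml) per voxel from compartment labels."""
    lab = labels.labels
    known = {LABEL_OUTSIDE, LABEL_BACKGROUND, LABEL_LUNG} | {
        SPHERE_LABEL_START + k for k in range(len(labels.sphere_diameters_mm))
    }
    present = set(np.unique(lab).tolist())
    if not present <= known:
        raise ValueError(f"unknown label codes: {sorted(present - known)}")
    act = np.zeros(lab.shape, dtype=np.float64)
    act[lab == LABEL_BACKGROUND] = setup.bg_activity_kBq_ml
    act[lab >= SPHERE_LABEL_START] = setup.sbr * setup.bg_activity_kBq_ml
    return act


def expected_counts(
    activity: np.ndarray,
    setup: AcquisitionSetup,
    duration_s: float,
    grid: VoxelGrid,
) -> np.ndarray:
    """Per-voxel Poisson mean of detected true counts for one frame."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    scale = (
        grid.voxel_volume_ml
        * duration_s
        * setup.sensitivity_cps_per_kBq
        * setup.attenuation_factor
    )
    return activity * scale


def calibrate_sensitivity(
    labels: LabelVolume,
    setup: AcquisitionSetup,
    reference_duration_s: float = 180.0,
    target_total_counts: float = 35e6,
) -> float:
    """Sensitivity making total expected true counts at the reference frame
    hit a target (default: 35 million at 180 s, the count level the study's
    ground-truth frames correspond to)."""
    if target_total_counts <= 0:
        raise ValueError("target_total_counts must be positive")
    unit = setup.with_sensitivity(1.0)
    total = float(
        expected_counts(activity_map(labels, unit), unit, reference_duration_s, labels.grid).sum()
    )
    if total <= 0:
        raise ValueError("phantom contains no activity; cannot calibrate")
    return target_total_counts / total


def simulate(
    activity: np.ndarray,
    setup: AcquisitionSetup,
    duration_s: float,
    grid: VoxelGrid,
    psf_fwhm_mm: float = 4.0,
    seed: int | None = None,
    mode: SimulationMode | str = SimulationMode.SAMPLE,
) -> ScanVolume:
    """Produce one reconstructed-image surrogate.

    ``mode='expectation'`` returns the PSF-blurred activity map exactly
    (noise-free limit, independent of seed and duration on the
    concentration scale); ``mode='sample'`` additionally draws independent
    per-voxel Poisson counts and converts them back to concentration.
    Identical seeds give bit-identical output.
    """
    mode = SimulationMode(mode)
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    if mode is SimulationMode.SAMPLE and seed is None:
        raise ValueError("sample mode requires a seed")

    if psf_fwhm_mm > 0:
        sigma_vox = [fwhm_to_sigma_mm(psf_fwhm_mm) / v for v in grid.voxel_size_mm]
        blurred = ndimage.gaussian_filter(
            np.asarray(activity, dtype=np.float64), sigma_vox, mode="constant", cval=0.0
        )
    else:
        blurred = np.asarray(activity, dtype=np.float64).copy()

    lam = expected_counts(blurred, setup, duration_s, grid)
    total = float(lam.sum())
    if mode is SimulationMode.EXPECTATION:
        values = blurred
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam)
        scale = (
            grid.voxel_volume_ml
            * duration_s
            * setup.sensitivity_cps_per_kBq
            * setup.attenuation_factor
        )
        values = counts / scale
    return ScanVolume(
        grid=grid,
        values=values,
        setup=setup,
        duration_s=float(duration_s),
        psf_fwhm_mm=float(psf_fwhm_mm),
        seed=seed,
        expected_true_counts=total,
        mode=mode,
    )


def scan_seed(master_seed: int, setup_index: int, duration_index: int) -> int:
    """Deterministic, collision-free per-scan seed from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(setup_index, duration_index))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def generate_study_inputs(
    labels: LabelVolume,
    setups: list[AcquisitionSetup] | None = None,
    schedule: DurationSchedule | None = None,
    psf_fwhm_mm: float = 4.0,
    master_seed: int = 0,
    mode: SimulationMode | str = SimulationMode.SAMPLE,
) -> Iterator[ScanVolume]:
    """Yield the full experimental grid, lazily.

    The default grid is {SBR4, SBR10} x {thin, obese} x 13 durations =
    52 scans, each with a distinct seed derived deterministically from
    ``master_seed``.  Activity is blurred once per setup and shared across
    that setup's frames.
    """
    setups = default_setups() if setups is None else setups
    schedule = duration_schedule() if schedule is None else schedule
    for i, setup in enumerate(setups):
        act = activity_map(labels, setup)
        for j, t in enumerate(schedule):
            yield simulate(
                act,
                setup,
                t,
                labels.grid,
                psf_fwhm_mm=psf_fwhm_mm,
                seed=scan_seed(master_seed, i, j),
                mode=mode,
            )
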