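"""Run the full phantom experiment grid and emit the study tables.

The default study reproduces the reference protocol: four phantom setups
({SBR4, SBR10} x {thin, obese}) each rebinned to 13 frame durations
(5 s ... 900 s), i.e. 52 datasets.  Per setup, a ground-truth frame is
selected (by default the frame whose expected true counts are nearest
35 million, which lands on the 180 s frame for SBR4-thin after
calibration), the VOI set is segmented once on that frame and frozen, and
every frame — plus every configured denoiser variant — is scored with the
full metric battery.  Background noise versus duration is summarized by a
log-log power-law fit per setup.

Outputs: a long-format record table (one row per scan x variant), an SSIM
grid (duration x setup), a Gaussian-filter comparison table for the anchor
scan, and a sphere-visibility matrix.  Everything is reproducible from the
master seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as qm
from . import similarity as sim
from .denoise import DenoiserSpec, apply_denoiser
from .geometry import (
    PhantomGeometry,
    VoxelGrid,
    default_grid,
    default_nema_geometry,
    rasterize,
)
from .segmentation import DEFAULT_BG_VOI_CENTERS_MM, VOISet, build_voi_set
from .simulate import (
    AcquisitionSetup,
    DurationSchedule,
    ScanVolume,
    SimulationMode,
    activity_map,
    calibrate_sensitivity,
    default_setups,
    duration_schedule,
    scan_seed,
    simulate,
)

__all__ = [
    "GroundTruthRule",
    "StudyConfig",
    "PowerLawFit",
    "StudyResult",
    "select_ground_truth",
    "fit_power_law",
    "run_study",
]


@dataclass(frozen=True)
class GroundTruthRule:
    """How each setup's reference frame is chosen.

    kind 'count_target': frame with expected true counts nearest ``target``
    (default 35e6); 'cov_target': frame with CoV_BG nearest ``target``
    percent; 'fixed_duration': exact schedule match required.  Ties go to
    the longer duration.
    """

    kind: str = "count_target"
    target: float = 35e6
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"count_target", "cov_target", "fixed_duration"}:
            raise ValueError(f"unknown ground-truth rule {self.kind!r}")


@dataclass(frozen=True)
class PowerLawFit:
    """CoV = a * t^b fitted by OLS on log-log axes."""

    a: float
    b: float
    r_squared: float


def fit_power_law(durations_s, cov_percent) -> PowerLawFit:
    t = np.asarray(durations_s, dtype=np.float64)
    c = np.asarray(cov_percent, dtype=np.float64)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(t <= 0) or np.any(c <= 0):
        raise ValueError("durations and CoV values must be positive (log fit)")
    x, y = np.log(t), np.log(c)
    b, log_a = np.polyfit(x, y, 1)
    resid = y - (log_a + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return PowerLawFit(a=float(np.exp(log_a)), b=float(b), r_squared=float("nan"))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(a=float(np.exp(log_a)), b=float(b), r_squared=r2)


def select_ground_truth(
    frames: list[ScanVolume],
    rule: GroundTruthRule,
    background_vois=None,
) -> int:
    """Index of the ground-truth frame among ``frames`` under ``rule``."""
    if not frames:
        raise ValueError("no frames")
    if rule.kind == "fixed_duration":
        for i, f in enumerate(frames):
            if f.duration_s == rule.duration_s:
                return i
        raise ValueError(f"duration {rule.duration_s} s not in schedule")
    if rule.kind == "count_target":
        scores = [abs(f.expected_true_counts - rule.target) for f in frames]
    else:  # cov_target
        if background_vois is None:
            raise ValueError("cov_target rule needs background VOIs")
        scores = [
            abs(qm.cov_bg(f.values, background_vois) - rule.target) for f in frames
        ]
    best = min(range(len(frames)), key=lambda i: (scores[i], -frames[i].duration_s))
    return best


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run."""

    geometry: PhantomGeometry | None = None
    voxel_size_mm: tuple[float, float, float] = (1.65, 1.65, 1.5)
    supersampling: int = 3
    setups: list[AcquisitionSetup] | None = None
    schedule: DurationSchedule | None = None
    psf_fwhm_mm: float = 4.0
    master_seed: int = 0
    bg_voi_volume_ml: float = 131.0
    bg_voi_centers_mm: tuple = DEFAULT_BG_VOI_CENTERS_MM
    calibration_duration_s: float = 180.0
    calibration_target_counts: float = 35e6
    ground_truth_rule: GroundTruthRule = field(default_factory=GroundTruthRule)
    denoisers: list[DenoiserSpec] = field(default_factory=list)
    denoise_scope: str = "anchor"  # 'anchor' | 'all'
    anchor_setup: str = "SBR4_thin"
    anchor_duration_s: float = 10.0
    compute_similarity: bool = True
    compute_spheres: bool = True

    def resolved(self) -> "StudyConfig":
        out = replace(self)
        if out.geometry is None:
            out.geometry = default_nema_geometry()
        if out.setups is None:
            out.setups = default_setups()
        if out.schedule is None:
            out.schedule = duration_schedule()
        if out.denoise_scope not in {"anchor", "all"}:
            raise ValueError("denoise_scope must be 'anchor' or 'all'")
        return out


@dataclass
class StudyResult:
    records: pd.DataFrame
    power_laws: dict[str, PowerLawFit]
    ground_truth_durations: dict[str, float]
    voi_sets: dict[str, VOISet]
    tables: dict[str, pd.DataFrame]


def _record_row(
    scan: ScanVolume,
    vois: VOISet,
    gt: ScanVolume,
    phantom_mask: np.ndarray,
    gt_peak: float | None,
    diameters,
    compute_similarity: bool,
    compute_spheres: bool = True,
) -> dict:
    row: dict = {
        "setup": scan.setup.name,
        "duration_s": scan.duration_s,
        "variant": scan.variant,
        "seed": scan.seed,
        "expected_true_counts": scan.expected_true_counts,
    }
    bg = qm.background_metrics(scan.values, vois.background_vois)
    row["cov_bg_percent"] = bg.cov_bg_percent

    if compute_spheres:
        true_conc = scan.setup.sbr * scan.setup.bg_activity_kBq_ml
        dsuv = qm.delta_suv(scan.values, gt.values, vois.sphere_vois)
        row.update(
            delta_suv_mean=dsuv["mean_dmean"],
            delta_suv_mean_sd=dsuv["sd_dmean"],
            delta_suv_max=dsuv["mean_dmax"],
            delta_suv_max_sd=dsuv["sd_dmax"],
        )
        for d in diameters:
            key = f"{d:g}mm"
            if d in vois.sphere_vois:
                sm = qm.sphere_metrics(scan.values, vois, true_conc, d)
                row[f"suv_mean_{key}"] = sm.suv_mean
                row[f"suv_max_{key}"] = sm.suv_max
                row[f"suv_peak_{key}"] = sm.suv_peak
                row[f"rc_mean_{key}"] = sm.rc_mean
                row[f"rc_max_{key}"] = sm.rc_max
                row[f"cnr_{key}"] = sm.cnr
                row[f"visible_{key}"] = sm.visible
            else:
                for col in ("suv_mean", "suv_max", "suv_peak", "rc_mean", "rc_max", "cnr"):
                    row[f"{col}_{key}"] = float("nan")
                row[f"visible_{key}"] = False
    if compute_similarity:
        peak = gt_peak if gt_peak and gt_peak > 0 else float(gt.values[phantom_mask].max())
        rec = sim.compare(scan.values, gt.values, phantom_mask, peak)
        row.update(ssim=rec.ssim, psnr_db=rec.psnr_db, mae=rec.mae)
    return row


def run_study(config: StudyConfig, out_dir=None) -> StudyResult:
    """Execute the configured grid; optionally write CSV outputs."""
    cfg = config.resolved()
    grid = default_grid(cfg.geometry, cfg.voxel_size_mm)
    labels = rasterize(cfg.geometry, grid, cfg.supersampling)
    diameters = labels.sphere_diameters_mm
    phantom_mask = labels.in_phantom()

    # one sensitivity for the whole study, anchored on the first setup
    sens = calibrate_sensitivity(
        labels,
        cfg.setups[0],
        reference_duration_s=cfg.calibration_duration_s,
        target_total_counts=cfg.calibration_target_counts,
    )
    setups = [s.with_sensitivity(sens) for s in cfg.setups]
    durations = list(cfg.schedule)

    rows: list[dict] = []
    power_laws: dict[str, PowerLawFit] = {}
    gt_durations: dict[str, float] = {}
    voi_sets: dict[str, VOISet] = {}

    for i, setup in enumerate(setups):
        act = activity_map(labels, setup)

        def frame(j: int) -> ScanVolume:
            return simulate(
                act,
                setup,
                durations[j],
                grid,
                psf_fwhm_mm=cfg.psf_fwhm_mm,
                seed=scan_seed(cfg.master_seed, i, j),
                mode=SimulationMode.SAMPLE,
            )

        # ground-truth selection without holding all frames in memory
        rule = cfg.ground_truth_rule
        if rule.kind == "cov_target":
            frames = [frame(j) for j in range(len(durations))]
            from .segmentation import place_background_vois

            bg_vois = place_background_vois(
                labels, cfg.bg_voi_volume_ml, centers_mm=cfg.bg_voi_centers_mm
            )
            gt_index = select_ground_truth(frames, rule, background_vois=bg_vois)
            del frames
        else:
            probes = [
                ScanVolume(
                    grid=grid,
                    values=np.empty(0),
                    setup=setup,
                    duration_s=t,
                    expected_true_counts=float(
                        act.sum()
                        * grid.voxel_volume_ml
                        * t
                        * setup.sensitivity_cps_per_kBq
                        * setup.attenuation_factor
                    ),
                )
                for t in durations
            ]
            gt_index = select_ground_truth(probes, rule)
        gt = frame(gt_index)
        gt_durations[setup.name] = gt.duration_s

        if cfg.compute_spheres:
            vois = build_voi_set(
                gt,
                labels,
                target_volume_ml=cfg.bg_voi_volume_ml,
                bg_centers_mm=cfg.bg_voi_centers_mm,
            )
        else:
            from .segmentation import place_background_vois

            vois = VOISet(
                grid=grid,
                background_vois=place_background_vois(
                    labels, cfg.bg_voi_volume_ml, centers_mm=cfg.bg_voi_centers_mm
                ),
                sphere_vois={},
                segmented_on=f"{setup.name}_{gt.duration_s:g}s",
            )
        voi_sets[setup.name] = vois

        gt_peak = None
        largest = max(diameters)
        if largest in vois.sphere_vois:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gt_peak = qm.suv_peak(gt.values, vois.sphere_vois[largest], grid)

        covs = []
        for j in range(len(durations)):
            scan = frame(j) if j != gt_index else gt
            variants = [scan]
            apply_here = cfg.denoise_scope == "all" or (
                setup.name == cfg.anchor_setup and scan.duration_s == cfg.anchor_duration_s
            )
            if apply_here:
                variants += [apply_denoiser(spec, scan) for spec in cfg.denoisers]
            for var_scan in variants:
                try:
                    row = _record_row(
                        var_scan,
                        vois,
                        gt,
                        phantom_mask,
                        gt_peak,
                        diameters,
                        cfg.compute_similarity,
                        cfg.compute_spheres,
                    )
                except Exception as exc:  # record, continue with the grid
                    row = {
                        "setup": setup.name,
                        "duration_s": var_scan.duration_s,
                        "variant": var_scan.variant,
                        "error": str(exc),
                    }
                rows.append(row)
                if var_scan.variant == "raw":
                    covs.append(row.get("cov_bg_percent", float("nan")))
        power_laws[setup.name] = fit_power_law(durations, covs)

    records = pd.DataFrame(rows)
    tables = _summary_tables(records, power_laws, diameters)
    result = StudyResult(
        records=records,
        power_laws=power_laws,
        ground_truth_durations=gt_durations,
        voi_sets=voi_sets,
        tables=tables,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _summary_tables(records: pd.DataFrame, power_laws, diameters) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    raw = records[records["variant"] == "raw"]
    if "ssim" in records.columns:
        tables["ssim_grid"] = raw.pivot_table(
            index="duration_s", columns="setup", values="ssim", sort=True
        )
    vis_cols = [c for c in records.columns if c.startswith("visible_")]
    if vis_cols:
        vis = raw.melt(
            id_vars=["setup", "duration_s"],
            value_vars=vis_cols,
            var_name="sphere",
            value_name="visible",
        )
        vis["sphere"] = vis["sphere"].str.removeprefix("visible_")
        tables["visibility"] = vis.pivot_table(
            index=["setup", "sphere"],
            columns="duration_s",
            values="visible",
            aggfunc="first",
        )
    tables["power_law"] = pd.DataFrame(
        [
            {"setup": name, "a": f.a, "b": f.b, "r_squared": f.r_squared}
            for name, f in power_laws.items()
        ]
    )
    # Gaussian/denoiser comparison at the anchor scan (all non-raw variants
    # plus the unfiltered anchor), mirroring the classic post-filter table
    nonraw = records[records["variant"] != "raw"]
    if len(nonraw):
        anchor_keys = nonraw[["setup", "duration_s"]].drop_duplicates()
        anchor_raw = raw.merge(anchor_keys, on=["setup", "duration_s"])
        cols = [
            c
            for c in [
                "setup",
                "duration_s",
                "variant",
                "cov_bg_percent",
                "ssim",
                "psnr_db",
                "mae",
                "delta_suv_mean",
                "delta_suv_mean_sd",
                "delta_suv_max",
                "delta_suv_max_sd",
            ]
            if c in records.columns
        ]
        tables["denoiser_comparison"] = pd.concat(
            [anchor_raw[cols], nonraw[cols]], ignore_index=True
        )
    return tables


def _write_outputs(result: StudyResult, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "records.csv", index=False, float_format="%.6g")
    for name, tab in result.tables.items():
        tab.to_csv(out / f"{name}.csv", float_format="%.6g")
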