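"""NIfTI and YAML interchange for volumes, label maps and configurations."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import LabelVolume, PhantomGeometry, SphereSpec, CylinderSpec, VoxelGrid
from .simulate import AcquisitionSetup, Habitus, ScanVolume, SimulationMode

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_labels",
    "write_scan",
    "read_scan",
    "geometry_to_dict",
    "geometry_from_dict",
]


def _grid_from_affine(affine: np.ndarray, shape) -> VoxelGrid:
    vs = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(v) for v in affine[:3, 3])
    return VoxelGrid(shape=tuple(int(s) for s in shape[:3]), voxel_size_mm=vs, origin_mm=origin)


def write_nifti(path, values: np.ndarray, grid: VoxelGrid, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=dtype), grid.affine())
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    return data, _grid_from_affine(img.affine, data.shape)


def write_labels(path, labels: LabelVolume) -> None:
    write_nifti(path, labels.labels, labels.grid, dtype=np.int16)


def write_scan(path, scan: ScanVolume) -> None:
    """Volume as NIfTI plus a YAML sidecar with acquisition metadata."""
    path = Path(path)
    write_nifti(path, scan.values, scan.grid)
    meta = {
        "setup": {
            "sbr": scan.setup.sbr,
            "habitus": scan.setup.habitus.value,
            "bg_activity_kBq_ml": scan.setup.bg_activity_kBq_ml,
            "obese_attenuation_factor": scan.setup.obese_attenuation_factor,
            "sensitivity_cps_per_kBq": scan.setup.sensitivity_cps_per_kBq,
        },
        "duration_s": scan.duration_s,
        "psf_fwhm_mm": scan.psf_fwhm_mm,
        "seed": scan.seed,
        "expected_true_counts": scan.expected_true_counts,
        "mode": scan.mode.value,
        "variant": scan.variant,
    }
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_scan(path) -> ScanVolume:
    path = Path(path)
    values, grid = read_nifti(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        setup = AcquisitionSetup(
            sbr=meta["setup"]["sbr"],
            habitus=Habitus(meta["setup"]["habitus"]),
            bg_activity_kBq_ml=meta["setup"]["bg_activity_kBq_ml"],
            obese_attenuation_factor=meta["setup"]["obese_attenuation_factor"],
            sensitivity_cps_per_kBq=meta["setup"]["sensitivity_cps_per_kBq"],
        )
        return ScanVolume(
            grid=grid,
            values=values,
            setup=setup,
            duration_s=meta["duration_s"],
            psf_fwhm_mm=meta["psf_fwhm_mm"],
            seed=meta["seed"],
            expected_true_counts=meta["expected_true_counts"],
            mode=SimulationMode(meta["mode"]),
            variant=meta.get("variant", "raw"),
        )
    return ScanVolume(
        grid=grid, values=values, setup=AcquisitionSetup(), duration_s=0.0,
        mode=SimulationMode.EXPECTATION,
    )


def geometry_to_dict(geom: PhantomGeometry) -> dict:
    d = {
        "body_half_straight_mm": geom.body_half_straight_mm,
        "body_radius_mm": geom.body_radius_mm,
        "axial_length_mm": geom.axial_length_mm,
        "spheres": [
            {"inner_diameter_mm": s.inner_diameter_mm, "center_mm": list(s.center_mm)}
            for s in geom.spheres
        ],
    }
    if geom.lung_insert is not None:
        d["lung_insert"] = {
            "radius_mm": geom.lung_insert.radius_mm,
            "center_xy_mm": list(geom.lung_insert.center_xy_mm),
        }
    return d


def geometry_from_dict(d: dict) -> PhantomGeometry:
    lung = None
    if "lung_insert" in d:
        lung = CylinderSpec(
            radius_mm=d["lung_insert"]["radius_mm"],
            center_xy_mm=tuple(d["lung_insert"].get("center_xy_mm", (0.0, 0.0))),
        )
    return PhantomGeometry(
        spheres=tuple(
            SphereSpec(s["inner_diameter_mm"], tuple(s["center_mm"])) for s in d["spheres"]
        ),
        lung_insert=lung,
        body_half_straight_mm=d.get("body_half_straight_mm", 35.0),
        body_radius_mm=d.get("body_radius_mm", 115.0),
        axial_length_mm=d.get("axial_length_mm", 180.0),
    )
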