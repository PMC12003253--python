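"""Parametric NEMA IEC body-phantom model and voxel rasterization.

The NEMA IEC body phantom is a torso-shaped fillable shell containing six
hollow spheres (inner diameters 10-37 mm) and a central low-density "lung"
insert.  This module describes that hardware parametrically (millimetre
world coordinates, phantom-centred frame) and rasterizes it onto a voxel
grid as an integer label volume that the simulator and the metric battery
share.

Label codes: 0 outside, 1 background compartment, 2 lung insert,
3..8 spheres ordered by ascending inner diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SphereSpec",
    "PhantomGeometry",
    "VoxelGrid",
    "LabelVolume",
    "LABEL_OUTSIDE",
    "LABEL_BACKGROUND",
    "LABEL_LUNG",
    "SPHERE_LABEL_START",
    "sphere_volume_ml",
    "diameter_mm_from_volume",
    "default_nema_geometry",
    "default_grid",
    "rasterize",
]

LABEL_OUTSIDE = 0
LABEL_BACKGROUND = 1
LABEL_LUNG = 2
SPHERE_LABEL_START = 3

#: Inner diameters of the six NEMA spheres, ascending (mm).
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


def sphere_volume_ml(inner_diameter_mm: float) -> float:
    """Volume of a sphere in ml from its inner diameter in mm.

    V = (pi/6) d^3, converted from mm^3 to ml (cm^3).  The 37 mm NEMA
    sphere, for example, holds 26.5 ml.
    """
    d = float(inner_diameter_mm)
    if not d > 0:
        raise ValueError(f"sphere diameter must be positive, got {inner_diameter_mm!r}")
    return math.pi / 6.0 * d**3 / 1000.0


def diameter_mm_from_volume(volume_ml: float) -> float:
    """Inner diameter in mm of a sphere holding ``volume_ml`` (exact inverse
    of :func:`sphere_volume_ml`)."""
    v = float(volume_ml)
    if not v > 0:
        raise ValueError(f"sphere volume must be positive, got {volume_ml!r}")
    return (6.0 * v * 1000.0 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SphereSpec:
    """One fillable sphere: inner diameter and centre in phantom frame (mm)."""

    inner_diameter_mm: float
    center_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.inner_diameter_mm > 0:
            raise ValueError("inner_diameter_mm must be positive")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.inner_diameter_mm

    @property
    def volume_ml(self) -> float:
        return sphere_volume_ml(self.inner_diameter_mm)


@dataclass(frozen=True)
class CylinderSpec:
    """Axial cylinder (the lung insert): radius and axial extent in mm."""

    radius_mm: float
    center_xy_mm: tuple[float, float] = (0.0, 0.0)
    z_range_mm: tuple[float, float] | None = None  # None = full phantom length


@dataclass(frozen=True)
class PhantomGeometry:
    """Body shell + lung insert + spheres.

    The body cross-section is a stadium (rectangle capped by two half
    discs): ``|dist((x, y), segment[-a..a on x])| <= body_radius_mm`` with
    ``a = body_half_straight_mm``.  The default reproduces the ~300 x 230 mm
    interior of the NEMA IEC shell.  The shell is extruded along z over
    ``[-axial_length_mm/2, +axial_length_mm/2]``.
    """

    spheres: tuple[SphereSpec, ...]
    lung_insert: CylinderSpec | None = CylinderSpec(radius_mm=25.0)
    body_half_straight_mm: float = 35.0
    body_radius_mm: float = 115.0
    axial_length_mm: float = 180.0

    def __post_init__(self) -> None:
        if not self.axial_length_mm > 0:
            raise ValueError("axial_length_mm must be positive")
        for s in self.spheres:
            if not self.contains_point(s.center_mm):
                raise ValueError(f"sphere centre {s.center_mm} outside body outline")
        # pairwise non-overlap of spheres
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1 :]:
                gap = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
                if gap < a.radius_mm + b.radius_mm:
                    raise ValueError("spheres overlap")
        if self.lung_insert is not None:
            for s in self.spheres:
                dxy = math.hypot(
                    s.center_mm[0] - self.lung_insert.center_xy_mm[0],
                    s.center_mm[1] - self.lung_insert.center_xy_mm[1],
                )
                if dxy < self.lung_insert.radius_mm + s.radius_mm:
                    raise ValueError("lung insert intersects a sphere")

    # -- point / array containment tests (world mm, phantom frame) --------

    def _outline_distance(self, x, y):
        """Distance of (x, y) to the stadium axis segment."""
        dx = np.maximum(np.abs(x) - self.body_half_straight_mm, 0.0)
        return np.hypot(dx, y)

    def contains_xy(self, x, y):
        return self._outline_distance(x, y) <= self.body_radius_mm

    def contains_point(self, p) -> bool:
        x, y, z = p
        return bool(
            self.contains_xy(np.asarray(x), np.asarray(y))
            and abs(z) <= self.axial_length_mm / 2.0
        )

    def bounding_box_mm(self) -> tuple[np.ndarray, np.ndarray]:
        half = np.array(
            [
                self.body_half_straight_mm + self.body_radius_mm,
                self.body_radius_mm,
                self.axial_length_mm / 2.0,
            ]
        )
        return -half, half

    def with_spheres(self, spheres) -> "PhantomGeometry":
        return replace(self, spheres=tuple(spheres))


def default_nema_geometry(
    sphere_ring_radius_mm: float = 57.2,
    sphere_plane_z_mm: float = 35.0,
    diameters_mm=NEMA_SPHERE_DIAMETERS_MM,
) -> PhantomGeometry:
    """The standard six-sphere arrangement.

    Sphere centres sit on a ring of radius 57.2 mm at 60 degree spacing in
    one transaxial plane, ordered by ascending diameter; the lung insert is
    a central 50 mm cylinder running the phantom's full length.  The result
    is deterministic.
    """
    spheres = []
    for k, d in enumerate(sorted(diameters_mm)):
        ang = math.radians(90.0 - 60.0 * k)
        spheres.append(
            SphereSpec(
                inner_diameter_mm=float(d),
                center_mm=(
                    sphere_ring_radius_mm * math.cos(ang),
                    sphere_ring_radius_mm * math.sin(ang),
                    sphere_plane_z_mm,
                ),
            )
        )
    return PhantomGeometry(spheres=tuple(spheres))


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice.

    ``origin_mm`` is the world coordinate of the centre of voxel (0, 0, 0);
    world = origin + index * voxel_size.  Indices are 0-based, axis order
    (x, y, z).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.65, 1.65, 1.5)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def axis_coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin_mm[a] + self.voxel_size_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 voxel-to-world affine."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff


def default_grid(
    geometry: PhantomGeometry,
    voxel_size_mm: tuple[float, float, float] = (1.65, 1.65, 1.5),
    margin_mm: float = 6.0,
) -> VoxelGrid:
    """Smallest grid covering the phantom plus a uniform margin."""
    lo, hi = geometry.bounding_box_mm()
    lo = lo - margin_mm
    hi = hi + margin_mm
    vs = np.asarray(voxel_size_mm, dtype=float)
    shape = tuple(int(math.ceil(e)) for e in (hi - lo) / vs)
    return VoxelGrid(shape=shape, voxel_size_mm=tuple(vs), origin_mm=tuple(lo + vs / 2.0))


@dataclass
class LabelVolume:
    """Integer compartment labels on a grid (codes in module docstring)."""

    grid: VoxelGrid
    labels: np.ndarray
    sphere_diameters_mm: tuple[float, ...] = field(default=NEMA_SPHERE_DIAMETERS_MM)

    def sphere_label(self, diameter_mm: float) -> int:
        idx = self.sphere_diameters_mm.index(diameter_mm)
        return SPHERE_LABEL_START + idx

    def sphere_mask(self, diameter_mm: float) -> np.ndarray:
        return self.labels == self.sphere_label(diameter_mm)

    def in_phantom(self) -> np.ndarray:
        return self.labels != LABEL_OUTSIDE

    def compartment_volume_ml(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.grid.voxel_volume_ml


def rasterize(
    geometry: PhantomGeometry,
    grid: VoxelGrid,
    supersampling: int = 3,
) -> LabelVolume:
    """Rasterize a phantom onto a grid by sub-voxel occupancy.

    Each voxel is probed at ``supersampling**3`` regularly spaced interior
    points; a voxel is assigned to a compartment when at least half of its
    probes fall inside that compartment (spheres and lung take precedence
    over the surrounding background).  Raises if the grid is too coarse to
    give any sphere at least one voxel.
    """
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    nx, ny, nz = grid.shape
    xs, ys, zs = grid.axis_coordinates_mm()
    n_probe = supersampling**3

    inside_body = np.zeros(grid.shape, dtype=np.uint16)
    inside_lung = np.zeros(grid.shape, dtype=np.uint16)
    inside_sph = [np.zeros(grid.shape, dtype=np.uint16) for _ in geometry.spheres]

    offsets = (np.arange(supersampling) + 0.5) / supersampling - 0.5
    vs = grid.voxel_size_mm
    half_len = geometry.axial_length_mm / 2.0
    for ox in offsets:
        X = (xs + ox * vs[0])[:, None, None]
        for oy in offsets:
            Y = (ys + oy * vs[1])[None, :, None]
            body_xy = geometry.contains_xy(X, Y)  # (nx, ny, 1)
            if geometry.lung_insert is not None:
                cyl = geometry.lung_insert
                lung_xy = (
                    np.hypot(X - cyl.center_xy_mm[0], Y - cyl.center_xy_mm[1])
                    <= cyl.radius_mm
                )
            for oz in offsets:
                Z = (zs + oz * vs[2])[None, None, :]
                in_z = np.abs(Z) <= half_len
                inside_body += (body_xy & in_z).astype(np.uint16)
                if geometry.lung_insert is not None:
                    cz = geometry.lung_insert.z_range_mm
                    in_cz = in_z if cz is None else (Z >= cz[0]) & (Z <= cz[1])
                    inside_lung += (lung_xy & in_cz & body_xy).astype(np.uint16)
                for s, acc in zip(geometry.spheres, inside_sph):
                    cx, cy, czs = s.center_mm
                    d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - czs) ** 2
                    acc += (d2 <= s.radius_mm**2).astype(np.uint16)

    half = n_probe / 2.0
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[inside_body >= half] = LABEL_BACKGROUND
    lung_vox = inside_lung >= half
    labels[lung_vox] = LABEL_LUNG
    for k, acc in enumerate(inside_sph):
        labels[acc >= half] = SPHERE_LABEL_START + k

    for k, s in enumerate(geometry.spheres):
        if geometry.spheres and not np.any(labels == SPHERE_LABEL_START + k):
            raise ValueError(
                f"grid too coarse: sphere {s.inner_diameter_mm} mm rasterized "
                f"to zero voxels (voxel size {grid.voxel_size_mm} mm)"
            )

    diam = tuple(s.inner_diameter_mm for s in geometry.spheres)
    return LabelVolume(grid=grid, labels=labels, sphere_diameters_mm=diam)
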