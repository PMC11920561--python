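"""Geometric phantom definitions and voxelization.

Two phantom families are modelled:

* a homogeneously filled cylinder (uniformity / noise / sensitivity work), and
* the NEMA IEC body phantom: a torso-shaped fillable shell with six hot
  spheres (inner diameters 10-37 mm) on a ring of revolution radius 57.2 mm
  and a cold cylindrical lung insert (outer diameter 50 mm) on the axis.

The NEMA interior cross-section is modelled as two half-cylinders joined by a
box.  The half-cylinder radius is fixed (80 mm) and the box width is fitted
so the modelled fillable volume equals the recorded fill volume, which keeps
recorded activities and concentrations mutually consistent.

Voxelization assigns a voxel to a compartment iff its center lies inside the
compartment geometry; partial-volume effects enter downstream through the
detector response, as they do physically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .core import (LABEL_BACKGROUND, LABEL_LUNG, LABEL_SPHERE_BASE,
                   LabeledVolume, VoxelGrid)
from .presets import CYLINDER_PRESETS, NEMA_PRESETS, NEMA_SPHERE_DIAMETERS_MM

# Linear attenuation coefficients at 81 keV [cm^-1]
MU_WATER_81KEV_PER_CM = 0.184
MU_LUNG_81KEV_PER_CM = 0.05

# NEMA IEC interior geometry defaults [mm]
NEMA_INTERIOR_LENGTH_MM = 180.0
NEMA_HALF_CYLINDER_RADIUS_MM = 80.0
NEMA_SPHERE_RING_RADIUS_MM = 57.2
NEMA_SPHERE_PLANE_FROM_END_MM = 70.0
NEMA_LUNG_OUTER_DIAMETER_MM = 50.0


class VoxelizationError(ValueError):
    """Raised when a grid cannot faithfully represent the phantom."""


def sphere_analytic_volume(inner_diameter_mm: float) -> float:
    """Analytic sphere volume in mL, 4/3 pi (d/2)^3."""
    if inner_diameter_mm <= 0:
        raise ValueError("sphere diameter must be positive")
    r = inner_diameter_mm / 2.0
    return 4.0 / 3.0 * math.pi * r**3 / 1000.0


@dataclass(frozen=True)
class SphereInsertSpec:
    """A fillable hot sphere: center (mm, phantom frame), inner diameter, fill."""

    center_mm: tuple[float, float, float]
    inner_diameter_mm: float
    concentration_mbq_ml: float

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0:
            raise ValueError("inner_diameter must be positive")
        if self.concentration_mbq_ml < 0:
            raise ValueError("concentration must be nonnegative")

    @property
    def volume_ml(self) -> float:
        return sphere_analytic_volume(self.inner_diameter_mm)


@dataclass(frozen=True)
class LungInsertSpec:
    """Cold low-density cylinder along z through the full interior length."""

    outer_diameter_mm: float = NEMA_LUNG_OUTER_DIAMETER_MM
    axis_xy_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.outer_diameter_mm <= 0:
            raise ValueError("lung diameter must be positive")


@dataclass
class PhantomSpec:
    """Complete phantom description.

    ``kind`` is ``"cylinder"`` (fields ``diameter_mm``, ``length_mm``) or
    ``"nema_iec"`` (fields ``body_radius_mm``, ``body_box_width_mm``,
    ``length_mm``, ``spheres``, ``lung``).  ``background_concentration`` is
    MBq/mL in the fillable background; ``fill_ratio`` the nominal
    sphere-to-background concentration ratio R used for CRC.
    """

    kind: str
    diameter_mm: float = 0.0
    length_mm: float = 0.0
    body_radius_mm: float = NEMA_HALF_CYLINDER_RADIUS_MM
    body_box_width_mm: float = 0.0
    background_concentration_mbq_ml: float = 0.0
    spheres: list[SphereInsertSpec] = field(default_factory=list)
    lung: Optional[LungInsertSpec] = None
    meta: dict[str, Any] = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------

    @property
    def fill_ratio(self) -> float:
        """Nominal sphere-to-background concentration ratio R."""
        if not self.spheres:
            return 0.0
        cs = self.spheres[0].concentration_mbq_ml
        cb = self.background_concentration_mbq_ml
        if cb == 0:
            return math.inf if cs > 0 else 0.0
        return cs / cb

    @property
    def interior_cross_section_mm2(self) -> float:
        if self.kind == "cylinder":
            return math.pi * (self.diameter_mm / 2.0) ** 2
        r, w = self.body_radius_mm, self.body_box_width_mm
        return 2.0 * r * w + math.pi * r**2

    @property
    def interior_volume_ml(self) -> float:
        return self.interior_cross_section_mm2 * self.length_mm / 1000.0

    @property
    def background_volume_ml(self) -> float:
        v = self.interior_volume_ml
        if self.lung is not None:
            v -= math.pi * (self.lung.outer_diameter_mm / 2.0) ** 2 * self.length_mm / 1000.0
        v -= sum(s.volume_ml for s in self.spheres)
        return v

    @property
    def total_activity_mbq(self) -> float:
        """Integral of concentration over the fillable volume."""
        a = self.background_concentration_mbq_ml * self.background_volume_ml
        a += sum(s.concentration_mbq_ml * s.volume_ml for s in self.spheres)
        return a

    @property
    def sphere_plane_z_mm(self) -> float:
        """z of the transaxial sphere-center plane (phantom centered at 0)."""
        return self.length_mm / 2.0 - NEMA_SPHERE_PLANE_FROM_END_MM


def make_cylinder_spec(
    diameter_mm: float | None = None,
    length_mm: float | None = None,
    volume_ml: float | None = None,
    activity_mbq: float = 0.0,
    preset: str | None = None,
) -> PhantomSpec:
    """Homogeneous cylinder phantom.

    Either give ``diameter_mm`` + ``volume_ml`` (length derived), or all of
    diameter/length/volume (checked for consistency within 2%), or a center
    ``preset`` name.  Concentration is ``activity / volume``.
    """
    meta: dict[str, Any] = {}
    if preset is not None:
        if preset not in CYLINDER_PRESETS:
            raise KeyError(f"unknown cylinder preset {preset!r}; "
                           f"choose from {sorted(CYLINDER_PRESETS)}")
        p = CYLINDER_PRESETS[preset]
        diameter_mm = p["diameter_mm"]
        volume_ml = p["volume_ml"]
        activity_mbq = p["activity_mbq"]
        meta["preset"] = preset
    if diameter_mm is None or diameter_mm <= 0:
        raise ValueError("cylinder diameter must be positive")
    if volume_ml is None or volume_ml <= 0:
        raise ValueError("cylinder volume must be positive")
    if activity_mbq < 0:
        raise ValueError("activity must be nonnegative")
    area = math.pi * (diameter_mm / 2.0) ** 2
    derived_length = volume_ml * 1000.0 / area
    if length_mm is None:
        length_mm = derived_length
    elif abs(length_mm - derived_length) / derived_length > 0.02:
        raise ValueError(
            f"inconsistent cylinder geometry: length {length_mm:.1f} mm vs "
            f"{derived_length:.1f} mm implied by volume {volume_ml:.0f} mL"
        )
    meta.update(volume_ml=volume_ml, activity_mbq=activity_mbq)
    return PhantomSpec(
        kind="cylinder",
        diameter_mm=diameter_mm,
        length_mm=length_mm,
        background_concentration_mbq_ml=activity_mbq / volume_ml,
        meta=meta,
    )


def make_nema_spec(
    preset: str | None = None,
    background_volume_ml: float | None = None,
    background_activity_mbq: float | None = None,
    spheres_volume_ml: float | None = None,
    spheres_activity_mbq: float | None = None,
    alternate_sphere_configuration: bool = False,
    body_radius_mm: float = NEMA_HALF_CYLINDER_RADIUS_MM,
    interior_length_mm: float = NEMA_INTERIOR_LENGTH_MM,
) -> PhantomSpec:
    """NEMA IEC body phantom with the standard six-sphere ring and lung insert.

    Either a center ``preset`` name or explicit background/sphere
    volumes (mL) and activities (MBq).  The nominal ratio R is computed from
    the resulting concentrations.  ``alternate_sphere_configuration``
    reverses the sphere-diameter ordering around the ring (the swapped
    placement used on two survey scanners).
    """
    meta: dict[str, Any] = {}
    if preset is not None:
        if preset not in NEMA_PRESETS:
            raise KeyError(f"unknown NEMA preset {preset!r}; "
                           f"choose from {sorted(NEMA_PRESETS)}")
        p = NEMA_PRESETS[preset]
        background_volume_ml = p["background_volume_ml"]
        background_activity_mbq = p["background_activity_mbq"]
        if spheres_volume_ml is None:
            spheres_volume_ml = p["spheres_volume_ml"]
        if spheres_activity_mbq is None:
            spheres_activity_mbq = p["spheres_activity_mbq"]
        meta["preset"] = preset
        meta["fill_sheet_ratio"] = p["fill_sheet_ratio"]
    for name, v in (("background_volume_ml", background_volume_ml),
                    ("spheres_volume_ml", spheres_volume_ml)):
        if v is None or v <= 0:
            raise ValueError(f"{name} must be positive")
    for name, v in (("background_activity_mbq", background_activity_mbq),
                    ("spheres_activity_mbq", spheres_activity_mbq)):
        if v is None or v < 0:
            raise ValueError(f"{name} must be nonnegative")

    c_bg = background_activity_mbq / background_volume_ml
    c_sp = spheres_activity_mbq / spheres_volume_ml
    lung = LungInsertSpec()

    # Fit the box width so the modelled fillable interior matches the
    # recorded fill volume (background + spheres + lung displacement).
    v_lung_ml = math.pi * (lung.outer_diameter_mm / 2.0) ** 2 * interior_length_mm / 1000.0
    v_interior_ml = background_volume_ml + spheres_volume_ml + v_lung_ml
    area_mm2 = v_interior_ml * 1000.0 / interior_length_mm
    box_width = (area_mm2 - math.pi * body_radius_mm**2) / (2.0 * body_radius_mm)
    if box_width <= 0:
        raise ValueError(
            f"fill volume {background_volume_ml:.0f} mL too small for a body "
            f"of half-cylinder radius {body_radius_mm:.0f} mm"
        )

    z_plane = interior_length_mm / 2.0 - NEMA_SPHERE_PLANE_FROM_END_MM
    diameters = list(NEMA_SPHERE_DIAMETERS_MM)
    if alternate_sphere_configuration:
        diameters = diameters[::-1]
    spheres = []
    for i, d in enumerate(diameters):
        ang = math.radians(90.0 - 60.0 * i)
        cx = NEMA_SPHERE_RING_RADIUS_MM * math.cos(ang)
        cy = NEMA_SPHERE_RING_RADIUS_MM * math.sin(ang)
        spheres.append(SphereInsertSpec((cx, cy, z_plane), d, c_sp))
    spheres.sort(key=lambda s: s.inner_diameter_mm)

    spec = PhantomSpec(
        kind="nema_iec",
        length_mm=interior_length_mm,
        body_radius_mm=body_radius_mm,
        body_box_width_mm=box_width,
        background_concentration_mbq_ml=c_bg,
        spheres=spheres,
        lung=lung,
        meta=meta,
    )
    spec.meta.update(
        background_volume_ml=background_volume_ml,
        background_activity_mbq=background_activity_mbq,
        spheres_volume_ml=spheres_volume_ml,
        spheres_activity_mbq=spheres_activity_mbq,
        alternate_sphere_configuration=alternate_sphere_configuration,
    )
    _check_spheres_inside(spec)
    return spec


def _check_spheres_inside(spec: PhantomSpec) -> None:
    for s in spec.spheres:
        x, y, z = s.center_mm
        r = s.inner_diameter_mm / 2.0
        if abs(z) + r > spec.length_mm / 2.0:
            raise ValueError(f"sphere at {s.center_mm} exits the phantom axially")
        if not _inside_body_xy(spec, np.array([x]), np.array([y]),
                               margin=r)[0]:
            raise ValueError(f"sphere at {s.center_mm} exits the body cross-section")


def _inside_body_xy(spec: PhantomSpec, x: np.ndarray, y: np.ndarray,
                    margin: float = 0.0) -> np.ndarray:
    """Membership test for the transaxial cross-section (any z)."""
    if spec.kind == "cylinder":
        r = spec.diameter_mm / 2.0 - margin
        return x**2 + y**2 <= r**2
    r = spec.body_radius_mm - margin
    half_w = spec.body_box_width_mm / 2.0
    in_box = (np.abs(x) <= half_w) & (np.abs(y) <= r)
    dx = np.abs(x) - half_w
    in_caps = (dx > 0) & (dx**2 + y**2 <= r**2)
    return in_box | in_caps


def voxelize_phantom(
    spec: PhantomSpec,
    grid: VoxelGrid,
    mu_water_per_cm: float = MU_WATER_81KEV_PER_CM,
    mu_lung_per_cm: float = MU_LUNG_81KEV_PER_CM,
    require_cover: bool = True,
) -> LabeledVolume:
    """Voxelize a phantom spec onto a grid by voxel-center membership.

    Raises :class:`VoxelizationError` if any sphere receives zero voxels or
    (with ``require_cover``) the grid does not cover the phantom bounding box.
    """
    X, Y, Z = grid.coordinate_arrays()
    if require_cover:
        lo, hi = grid.bounding_box()
        half = spec.length_mm / 2.0
        if spec.kind == "cylinder":
            rx = ry = spec.diameter_mm / 2.0
        else:
            rx = spec.body_box_width_mm / 2.0 + spec.body_radius_mm
            ry = spec.body_radius_mm
        if (lo[0] > -rx or hi[0] < rx or lo[1] > -ry or hi[1] < ry
                or lo[2] > -half or hi[2] < half):
            raise VoxelizationError("grid does not cover the phantom bounding box")

    in_z = np.abs(Z) <= spec.length_mm / 2.0
    body = _inside_body_xy(spec, X, Y) & in_z

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[body] = LABEL_BACKGROUND

    if spec.lung is not None:
        ax, ay = spec.lung.axis_xy_mm
        rl = spec.lung.outer_diameter_mm / 2.0
        lung = ((X - ax) ** 2 + (Y - ay) ** 2 <= rl**2) & in_z & body
        labels[lung] = LABEL_LUNG

    for i, s in enumerate(spec.spheres):
        cx, cy, cz = s.center_mm
        r = s.inner_diameter_mm / 2.0
        mask = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2
        if not mask.any():
            raise VoxelizationError(
                f"grid spacing {grid.spacing} too coarse: sphere "
                f"d={s.inner_diameter_mm} mm at {s.center_mm} has no voxels"
            )
        labels[mask] = LABEL_SPHERE_BASE + i

    activity = np.zeros(grid.shape, dtype=np.float64)
    activity[labels == LABEL_BACKGROUND] = spec.background_concentration_mbq_ml
    for i, s in enumerate(spec.spheres):
        activity[labels == LABEL_SPHERE_BASE + i] = s.concentration_mbq_ml

    attenuation = np.zeros(grid.shape, dtype=np.float64)
    attenuation[labels == LABEL_BACKGROUND] = mu_water_per_cm
    attenuation[labels >= LABEL_SPHERE_BASE] = mu_water_per_cm
    attenuation[labels == LABEL_LUNG] = mu_lung_per_cm

    return LabeledVolume(activity, attenuation, labels, grid,
                         meta={"kind": spec.kind, **spec.meta})
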