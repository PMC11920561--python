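"""Volumes of interest for the metric suite.

All masks are boolean voxel-center tests on a :class:`VoxelGrid`:

* six spherical VOIs true to physical inner diameter, centered on the
  (optionally rigidly transformed) sphere positions;
* a Ø 30 mm cylindrical lung VOI spanning the interior length;
* a cylindrical-shell background VOI (radius of revolution 57 mm, thickness
  37 mm, height 50 mm) around the lung axis, axially midway between the
  sphere-center plane and the far interior end-wall, with sphere and lung
  voxels excluded;
* a 30 mm Euclidean erosion of the cylinder support for the noise VOI;
* per-slice disk masks (support dilated 5 voxels) for the axial profile.

Rigid placement comes either from a known transform (synthetic data) or from
moment-based registration of two phantom-support volumes (center of mass +
principal axes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LABEL_LUNG, LABEL_SPHERE_BASE, VolumeImage, VoxelGrid
from .phantom import PhantomSpec

BACKGROUND_SHELL_REVOLUTION_RADIUS_MM = 57.0
BACKGROUND_SHELL_THICKNESS_MM = 37.0
BACKGROUND_SHELL_HEIGHT_MM = 50.0
LUNG_VOI_DIAMETER_MM = 30.0
NOISE_VOI_EROSION_MM = 30.0
PROFILE_MASK_DILATION_VOXELS = 5


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``x' = R x + t`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_angle_z(cls, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        a = math.radians(angle_deg)
        r = np.array([[math.cos(a), -math.sin(a), 0.0],
                      [math.sin(a), math.cos(a), 0.0],
                      [0.0, 0.0, 1.0]])
        return cls(r, np.asarray(translation, dtype=float))


@dataclass
class VOISet:
    """Named boolean masks on one grid, with the transform that placed them."""

    masks: dict[str, np.ndarray]
    grid: VoxelGrid
    transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def sphere_names(self) -> list[str]:
        return sorted((n for n in self.masks if n.startswith("sphere_")),
                      key=lambda n: float(n.split("_")[1]))


def _coords(grid: VoxelGrid):
    return grid.coordinate_arrays()


def make_sphere_vois(spec: PhantomSpec, grid: VoxelGrid,
                     transform: RigidTransform | None = None) -> dict[str, np.ndarray]:
    """Spherical VOIs true to physical inner diameter, one per insert."""
    if spec.kind != "nema_iec":
        raise ValueError("sphere VOIs require a NEMA IEC spec")
    transform = transform or RigidTransform.identity()
    X, Y, Z = _coords(grid)
    lo, hi = grid.bounding_box()
    masks = {}
    for s in spec.spheres:
        c = transform.apply(np.asarray(s.center_mm))
        r = s.inner_diameter_mm / 2.0
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise ValueError(f"sphere VOI at {c} exits the grid")
        m = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2
        masks[f"sphere_{s.inner_diameter_mm:g}"] = m
    return masks


def make_lung_voi(spec: PhantomSpec, grid: VoxelGrid,
                  transform: RigidTransform | None = None,
                  voi_diameter_mm: float = LUNG_VOI_DIAMETER_MM) -> np.ndarray:
    """Ø 30 mm cylindrical VOI on the lung axis over the interior length."""
    if spec.lung is None:
        raise ValueError("phantom has no lung insert")
    transform = transform or RigidTransform.identity()
    X, Y, Z = _coords(grid)
    ax, ay = spec.lung.axis_xy_mm
    p0 = transform.apply(np.array([ax, ay, -spec.length_mm / 2.0]))
    p1 = transform.apply(np.array([ax, ay, +spec.length_mm / 2.0]))
    return _cylinder_mask(X, Y, Z, p0, p1, voi_diameter_mm / 2.0)


def _cylinder_mask(X, Y, Z, p0, p1, radius):
    axis = p1 - p0
    length = np.linalg.norm(axis)
    u = axis / length
    dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
    proj = dx * u[0] + dy * u[1] + dz * u[2]
    d2 = (dx - proj * u[0]) ** 2 + (dy - proj * u[1]) ** 2 + (dz - proj * u[2]) ** 2
    return (proj >= 0) & (proj <= length) & (d2 <= radius**2)


def make_background_shell_voi(
    spec: PhantomSpec, grid: VoxelGrid,
    transform: RigidTransform | None = None,
    exclude: list[np.ndarray] | None = None,
    axial_center_offset_mm: float | None = None,
) -> np.ndarray:
    """Cylindrical-shell background VOI around the lung axis.

    Radial bounds 57 ± 18.5 mm, height 50 mm.  The axial center defaults to
    midway between the sphere-center plane and the interior end-wall away
    from the spheres; ``axial_center_offset_mm`` overrides it (phantom-frame
    z).  Voxels of any mask in ``exclude`` are removed.
    """
    if spec.kind != "nema_iec":
        raise ValueError("background shell requires a NEMA IEC spec")
    transform = transform or RigidTransform.identity()
    if axial_center_offset_mm is None:
        z_shell = (spec.sphere_plane_z_mm + (-spec.length_mm / 2.0)) / 2.0
    else:
        z_shell = axial_center_offset_mm
    half_h = BACKGROUND_SHELL_HEIGHT_MM / 2.0
    r_in = BACKGROUND_SHELL_REVOLUTION_RADIUS_MM - BACKGROUND_SHELL_THICKNESS_MM / 2.0
    r_out = BACKGROUND_SHELL_REVOLUTION_RADIUS_MM + BACKGROUND_SHELL_THICKNESS_MM / 2.0
    ax, ay = spec.lung.axis_xy_mm if spec.lung else (0.0, 0.0)

    X, Y, Z = _coords(grid)
    inv = transform.inverse()
    # evaluate in the phantom frame: map voxel centers back
    Xp = inv.rotation[0, 0] * X + inv.rotation[0, 1] * Y + inv.rotation[0, 2] * Z + inv.translation[0]
    Yp = inv.rotation[1, 0] * X + inv.rotation[1, 1] * Y + inv.rotation[1, 2] * Z + inv.translation[1]
    Zp = inv.rotation[2, 0] * X + inv.rotation[2, 1] * Y + inv.rotation[2, 2] * Z + inv.translation[2]
    r2 = (Xp - ax) ** 2 + (Yp - ay) ** 2
    m = (r2 >= r_in**2) & (r2 <= r_out**2) & (np.abs(Zp - z_shell) <= half_h)
    for other in exclude or []:
        m &= ~other
    return m


def eroded_cylinder_voi(support_mask: np.ndarray, grid: VoxelGrid,
                        erosion_mm: float = NOISE_VOI_EROSION_MM) -> np.ndarray:
    """Erode a phantom support mask by a Euclidean margin (mm) in 3-D."""
    support_mask = np.asarray(support_mask, dtype=bool)
    if not support_mask.any():
        raise ValueError("support mask is empty")
    if erosion_mm == 0:
        return support_mask.copy()
    dist = ndimage.distance_transform_edt(support_mask, sampling=grid.spacing)
    out = dist > erosion_mm
    if not out.any():
        raise ValueError(f"erosion by {erosion_mm} mm empties the mask")
    return out


def axial_profile_mask(support_mask: np.ndarray, grid: VoxelGrid,
                       dilation_voxels: int = PROFILE_MASK_DILATION_VOXELS) -> np.ndarray:
    """Per-slice cross-section masks dilated outward by N voxels in-plane."""
    support_mask = np.asarray(support_mask, dtype=bool)
    if dilation_voxels == 0:
        return support_mask.copy()
    yy, xx = np.mgrid[-dilation_voxels:dilation_voxels + 1,
                      -dilation_voxels:dilation_voxels + 1]
    disk = xx**2 + yy**2 <= dilation_voxels**2
    out = np.zeros_like(support_mask)
    for k in range(support_mask.shape[2]):
        sl = support_mask[:, :, k]
        if sl.any():
            out[:, :, k] = ndimage.binary_dilation(sl, structure=disk)
    return out


def build_voi_set(spec: PhantomSpec, grid: VoxelGrid,
                  transform: RigidTransform | None = None) -> VOISet:
    """All NEMA VOIs (spheres, lung, background shell) in one deterministic call."""
    transform = transform or RigidTransform.identity()
    masks = make_sphere_vois(spec, grid, transform)
    masks["lung"] = make_lung_voi(spec, grid, transform)
    masks["background_shell"] = make_background_shell_voi(
        spec, grid, transform, exclude=list(masks.values()))
    return VOISet(masks, grid, transform)


def label_masks(labels: np.ndarray, spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Masks straight from voxelized compartment labels (ground-truth VOIs)."""
    masks = {}
    for i, s in enumerate(spec.spheres):
        masks[f"sphere_{s.inner_diameter_mm:g}"] = labels == LABEL_SPHERE_BASE + i
    masks["lung"] = labels == LABEL_LUNG
    return masks


def register_rigid(moving: VolumeImage, reference: VolumeImage,
                   threshold: float = 0.0) -> RigidTransform:
    """Moment-based rigid registration of two phantom-support volumes.

    Aligns centers of mass and principal axes of the binarized supports and
    returns the transform mapping moving-frame points into the reference
    frame.  Near-degenerate inertia spectra (axially symmetric phantoms)
    trigger a warning and a translation-only result.
    """
    def moments(img: VolumeImage):
        m = np.asarray(img.values) > threshold
        if not m.any():
            raise ValueError("volume not binarizable to a phantom support")
        idx = np.argwhere(m).astype(float)
        pts = idx * np.asarray(img.grid.spacing) + np.asarray(img.grid.origin)
        com = pts.mean(axis=0)
        cov = np.cov((pts - com).T)
        return com, cov

    com_m, cov_m = moments(moving)
    com_r, cov_r = moments(reference)
    w_m, v_m = np.linalg.eigh(cov_m)
    w_r, v_r = np.linalg.eigh(cov_r)

    rel_gap = np.min(np.abs(np.diff(np.sort(w_m)))) / max(w_m.max(), 1e-12)
    if rel_gap < 0.02:
        warnings.warn("degenerate support symmetry: rotation unobservable, "
                      "returning center-of-mass alignment only", RuntimeWarning)
        rot = np.eye(3)
    else:
        # align eigenvector signs so the rotation is the small one
        for k in range(3):
            if np.dot(v_m[:, k], v_r[:, k]) < 0:
                v_m[:, k] = -v_m[:, k]
        rot = v_r @ v_m.T
        if np.linalg.det(rot) < 0:
            v_m[:, 0] = -v_m[:, 0]
            rot = v_r @ v_m.T
    return RigidTransform(rot, com_r - rot @ com_m)
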