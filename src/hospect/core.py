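"""Core spatial containers shared by every stage of the pipeline.

Conventions (fixed package-wide):

* Arrays are indexed ``[x, y, z]`` with ``z`` the phantom/scanner axis.
* All distances are millimetres; voxel indices are 0-based.
* World coordinates map voxel *centers*: ``world = origin + index * spacing``
  (right-handed frame).
* Activity is MBq/mL, attenuation is cm^-1 at 81 keV, time is seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing
        Voxel size in mm along (x, y, z); must be positive.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(cls, shape, spacing) -> "VoxelGrid":
        """Grid whose world origin (0,0,0) sits at the lattice center."""
        shape = tuple(int(n) for n in np.broadcast_to(shape, 3))
        spacing = tuple(float(s) for s in np.broadcast_to(spacing, 3))
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls(shape, spacing, origin)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coordinate_arrays(self):
        """Broadcastable (X, Y, Z) world-coordinate arrays."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def bounding_box(self):
        lo = np.asarray(self.origin) - np.asarray(self.spacing) / 2.0
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return lo, hi


@dataclass
class VolumeImage:
    """A scalar 3-D image on a :class:`VoxelGrid` (reconstructed counts, CT, ...)."""

    values: np.ndarray
    grid: VoxelGrid
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy_with(self, values: np.ndarray, **meta) -> "VolumeImage":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return VolumeImage(values, self.grid, new_meta)


@dataclass
class LabeledVolume:
    """Voxelized phantom: activity, attenuation and compartment labels on one grid.

    ``activity`` is MBq/mL per voxel, ``attenuation`` is cm^-1 at 81 keV and
    ``labels`` an integer compartment id (0 = outside the phantom).
    """

    activity: np.ndarray
    attenuation: np.ndarray
    labels: np.ndarray
    grid: VoxelGrid
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("activity", "attenuation", "labels"):
            arr = np.asarray(getattr(self, name))
            if tuple(arr.shape) != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)
        if np.any(self.activity < 0):
            raise ValueError("negative activity concentration")
        if np.any(self.attenuation < 0):
            raise ValueError("negative attenuation coefficient")

    @property
    def support(self) -> np.ndarray:
        return self.labels > 0

    @property
    def total_activity_mbq(self) -> float:
        return float(self.activity.sum()) * self.grid.voxel_volume_ml


# Compartment label ids used by the voxelizer and the VOI builders.
LABEL_BACKGROUND = 1
LABEL_LUNG = 2
LABEL_SPHERE_BASE = 10  # sphere i (ascending diameter) -> 10 + i
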