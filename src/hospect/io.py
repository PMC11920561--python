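"""File formats: NIfTI volumes, DICOM series (read-only), projection
archives, and phantom/config (de)serialization.

NIfTI is the canonical on-disk volume format (one well-specified affine
convention); the package's (x, y, z) array axes map directly onto NIfTI
i, j, k with a diagonal affine built from spacing and origin.  A projection
archive is a directory with one NIfTI stack per energy window plus a
schema-validated JSON sidecar carrying windows, timing, activity, collimator
and seed.  Units are fixed across all files: mm, s, MBq, counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import yaml

from .core import LabeledVolume, VolumeImage, VoxelGrid
from .phantom import PhantomSpec, make_cylinder_spec, make_nema_spec
from .presets import COLLIMATORS
from .simulate import AcquisitionConfig, EnergyWindow, ProjectionSet

SIDECAR_REQUIRED_KEYS = {"windows", "time_per_projection_s", "n_projections",
                         "activity_mbq", "collimator", "seed", "spacing_mm"}


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def write_volume(image: VolumeImage, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(image.values, dtype=np.float64),
                             _affine(image.grid)), str(path))
    return path


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI file or a DICOM series directory into a VolumeImage."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError(f"non-axis-aligned affine in {path}")
    spacing = tuple(float(s) for s in np.diag(aff[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"malformed header (non-positive spacing) in {path}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    grid = VoxelGrid(tuple(data.shape), spacing, tuple(float(v) for v in aff[:3, 3]))
    return VolumeImage(data, grid, meta={"path": str(path)})


def _read_dicom_series(directory: Path) -> VolumeImage:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(str(p)) for p in files]
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    z = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    dz = np.diff(z)
    if len(dz) and (dz.max() - dz.min()) > 1e-3 * abs(dz.mean()):
        raise ValueError(f"inconsistent DICOM slice spacing in {directory}")
    px = [float(v) for v in slices[0].PixelSpacing]
    spacing = (px[1], px[0], float(dz.mean()) if len(dz) else 1.0)
    vol = np.stack([d.pixel_array.T for d in slices], axis=2).astype(np.float64)
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    inter = float(getattr(slices[0], "RescaleIntercept", 0.0))
    vol = vol * slope + inter
    origin = (float(slices[0].ImagePositionPatient[0]),
              float(slices[0].ImagePositionPatient[1]), float(z[0]))
    grid = VoxelGrid(tuple(vol.shape), spacing, origin)
    return VolumeImage(vol, grid, meta={"path": str(directory), "format": "dicom"})


def write_labeled_volume(phantom: LabeledVolume, stem: str | Path) -> dict[str, Path]:
    """Write activity/attenuation/labels as three NIfTI files sharing one affine."""
    stem = Path(stem)
    out = {}
    for name, arr in (("activity", phantom.activity),
                      ("attenuation", phantom.attenuation),
                      ("labels", phantom.labels.astype(np.int16))):
        p = stem.parent / f"{stem.name}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64),
                                 _affine(phantom.grid)), str(p))
        out[name] = p
    return out


# ---------------------------------------------------------------------------
# Projection archive
# ---------------------------------------------------------------------------


def write_projection_archive(pset: ProjectionSet, directory: str | Path,
                             include_ground_truth: bool = True) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = pset.config
    sidecar: dict[str, Any] = {
        "units": {"distance": "mm", "time": "s", "activity": "MBq",
                  "counts": "counts"},
        "windows": [asdict(w) for w in cfg.windows],
        "time_per_projection_s": cfg.time_per_projection_s,
        "n_projections": cfg.n_projections,
        "activity_mbq": pset.activity_mbq,
        "collimator": cfg.collimator.name,
        "orbit_radius_mm": cfg.orbit_radius_mm,
        "seed": cfg.seed,
        "spacing_mm": list(pset.grid.spacing),
        "grid_shape": list(pset.grid.shape),
        "grid_origin_mm": list(pset.grid.origin),
        "stacks": {},
        "ground_truth": {},
    }
    aff = np.eye(4)
    for role, arr in pset.counts.items():
        fname = f"counts_{role}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff),
                 str(directory / fname))
        sidecar["stacks"][role] = fname
    if include_ground_truth and pset.ground_truth is not None:
        for role, comps in pset.ground_truth.items():
            entry = {}
            for comp, arr in comps.items():
                fname = f"gt_{role}_{comp}.nii.gz"
                nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff),
                         str(directory / fname))
                entry[comp] = fname
            sidecar["ground_truth"][role] = entry
    (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_projection_archive(directory: str | Path) -> ProjectionSet:
    directory = Path(directory)
    sc_path = directory / "sidecar.json"
    if not sc_path.exists():
        raise FileNotFoundError(f"missing sidecar: {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    missing = SIDECAR_REQUIRED_KEYS - sidecar.keys()
    if missing:
        raise ValueError(f"sidecar missing keys: {sorted(missing)}")
    windows = [EnergyWindow(**w) for w in sidecar["windows"]]
    if len(sidecar["stacks"]) != len(windows):
        raise ValueError("sidecar window count does not match stack count")
    cfg = AcquisitionConfig(
        n_projections=sidecar["n_projections"],
        time_per_projection_s=sidecar["time_per_projection_s"],
        orbit_radius_mm=sidecar.get("orbit_radius_mm", 250.0),
        windows=windows,
        collimator=COLLIMATORS[sidecar["collimator"]],
        seed=sidecar["seed"],
    )
    counts = {}
    for role, fname in sidecar["stacks"].items():
        counts[role] = np.asarray(nib.load(str(directory / fname)).dataobj,
                                  dtype=np.float64)
    gt = None
    if sidecar.get("ground_truth"):
        gt = {}
        for role, entry in sidecar["ground_truth"].items():
            gt[role] = {comp: np.asarray(nib.load(str(directory / f)).dataobj,
                                         dtype=np.float64)
                        for comp, f in entry.items()}
    grid = VoxelGrid(tuple(sidecar["grid_shape"]),
                     tuple(sidecar["spacing_mm"]),
                     tuple(sidecar.get("grid_origin_mm", (0.0, 0.0, 0.0))))
    return ProjectionSet(counts, cfg, sidecar["activity_mbq"], grid,
                         ground_truth=gt, meta={"path": str(directory)})


# ---------------------------------------------------------------------------
# Phantom spec serialization
# ---------------------------------------------------------------------------


def phantom_spec_to_dict(spec: PhantomSpec) -> dict[str, Any]:
    d: dict[str, Any] = {"kind": spec.kind, "meta": dict(spec.meta)}
    if spec.kind == "cylinder":
        d.update(diameter_mm=spec.diameter_mm,
                 volume_ml=spec.meta.get("volume_ml", spec.interior_volume_ml),
                 activity_mbq=spec.meta.get(
                     "activity_mbq", spec.total_activity_mbq))
    else:
        d.update(background_volume_ml=spec.meta["background_volume_ml"],
                 background_activity_mbq=spec.meta["background_activity_mbq"],
                 spheres_volume_ml=spec.meta["spheres_volume_ml"],
                 spheres_activity_mbq=spec.meta["spheres_activity_mbq"],
                 alternate_sphere_configuration=spec.meta.get(
                     "alternate_sphere_configuration", False))
    return d


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(phantom_spec_to_dict(spec)))
    return path


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such phantom spec: {path}")
    d = yaml.safe_load(path.read_text())
    kind = d.pop("kind")
    d.pop("meta", None)
    if kind == "cylinder":
        return make_cylinder_spec(diameter_mm=d["diameter_mm"],
                                  volume_ml=d["volume_ml"],
                                  activity_mbq=d["activity_mbq"])
    if kind == "nema_iec":
        return make_nema_spec(
            background_volume_ml=d["background_volume_ml"],
            background_activity_mbq=d["background_activity_mbq"],
            spheres_volume_ml=d["spheres_volume_ml"],
            spheres_activity_mbq=d["spheres_activity_mbq"],
            alternate_sphere_configuration=d.get(
                "alternate_sphere_configuration", False))
    raise ValueError(f"unknown phantom kind {kind!r}")
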