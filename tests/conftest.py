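"""Shared fixtures: small voxelized phantoms and a cached simulated session.

Everything is generated programmatically; grids are kept at desk scale
(32³–64³) so the whole suite runs on one CPU in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import hospect as h
from hospect.pipeline import default_desk_scale_nema

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*zero sensitivity.*")


@pytest.fixture(scope="session")
def grid64():
    return h.VoxelGrid.centered(64, 4.8)


@pytest.fixture(scope="session")
def cylinder_spec():
    return h.make_cylinder_spec(preset="UMCU")


@pytest.fixture(scope="session")
def cylinder64(cylinder_spec, grid64):
    return h.voxelize_phantom(cylinder_spec, grid64)


@pytest.fixture(scope="session")
def nema_spec():
    return default_desk_scale_nema()


@pytest.fixture(scope="session")
def nema64(nema_spec, grid64):
    return h.voxelize_phantom(nema_spec, grid64)


@pytest.fixture(scope="session")
def small_cylinder():
    """A compact cylinder on a 32³ grid for fast reconstruction tests."""
    spec = h.make_cylinder_spec(diameter_mm=120.0, volume_ml=1357.0,
                                activity_mbq=100.0)
    grid = h.VoxelGrid.centered(32, 6.0)
    return spec, h.voxelize_phantom(spec, grid)


@pytest.fixture(scope="session")
def small_noisefree_pset(small_cylinder):
    _, vol = small_cylinder
    cfg = h.AcquisitionConfig(n_projections=24, poisson=False)
    return h.simulate_projection_set(vol, cfg)


@pytest.fixture(scope="session")
def cylinder_session(cylinder_spec, cylinder64, grid64):
    """One noisy 64³/60-projection cylinder acquisition, reconstructed with
    all three scatter-correction methods — shared by the uniformity, noise
    and direction-of-effect tests."""
    from hospect.metrics import axial_uniformity, coefficient_of_variation
    from hospect.recon import ReconConfig, reconstruct_projection_set
    from hospect.scatter import ScatterConfig, estimate_scatter
    from hospect.voi import axial_profile_mask, eroded_cylinder_voi

    cfg = h.AcquisitionConfig(n_projections=60, seed=11)
    pset = h.simulate_projection_set(cylinder64, cfg)
    profile_mask = axial_profile_mask(cylinder64.support, grid64)
    noise_voi = eroded_cylinder_voi(cylinder64.support, grid64)
    out = {"pset": pset, "curvature": {}, "cov": {}, "volumes": {}}
    rc = ReconConfig(iterations=4, subsets=8)
    for method in ("dew", "tew", "oracle"):
        est = estimate_scatter(pset, ScatterConfig(method=method))
        vol = reconstruct_projection_set(pset, cylinder64.attenuation, est, rc)
        out["volumes"][method] = vol
        out["curvature"][method] = axial_uniformity(
            vol, profile_mask, length_mm=cylinder_spec.length_mm).curvature
        out["cov"][method] = coefficient_of_variation(vol, noise_voi).mean_cov
    return out
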