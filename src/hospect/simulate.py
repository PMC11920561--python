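"""Digital-phantom SPECT simulation with multi-energy-window ground truth.

The acquisition model is parallel-beam with a circular orbit.  For each
energy window the expected projection counts decompose into three retained
components:

``mean_w = t * [ a_w * P + b_w * (K (*) P) + c_w * D ]``

* ``P`` — attenuated, detector-response-blurred projection of the activity
  map ("primary"), normalized so the photopeak-window *total* sensitivity
  (summed counts / (t n A)) equals the configured value;
* ``K (*) P`` — a broad 2-D Gaussian acting on ``P`` ("photopeak scatter",
  which for ¹⁶⁶Ho also folds in bremsstrahlung and lead x-ray contamination);
* ``D`` — an attenuation-free, even broader projection of the total activity
  ("downscatter" from the high-energy emissions, dominant in the 118 keV
  window and present in all windows).

Energy spectra are not simulated: each window receives component amplitudes
directly, scaled with collimator geometric efficiency so vendor hardware
contrasts (MEGP vs MELP) propagate to sensitivity and resolution.  Poisson
sampling is seeded and the noise-free component decomposition is retained as
ground truth, which is what the oracle scatter correction reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Optional

import numpy as np
from scipy import ndimage

from .core import LabeledVolume, VolumeImage, VoxelGrid
from .presets import (MELP, SENSITIVITY_CALIBRATION_CPS_PER_MBQ,
                      CollimatorPreset)

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (8.0 * np.log(2.0)) ** 0.5

WINDOW_ROLES = ("photopeak", "lower_scatter", "upper_scatter", "downscatter_118")


@dataclass(frozen=True)
class EnergyWindow:
    """An energy acceptance window, center (keV) and fractional width."""

    center_kev: float
    width_fraction: float
    role: str

    def __post_init__(self) -> None:
        if not 0 < self.width_fraction < 1:
            raise ValueError("width_fraction must be in (0, 1)")
        if self.center_kev <= 0:
            raise ValueError("center_kev must be positive")
        if self.role not in WINDOW_ROLES:
            raise ValueError(f"unknown window role {self.role!r}")

    @property
    def width_kev(self) -> float:
        return self.center_kev * self.width_fraction

    @property
    def bounds_kev(self) -> tuple[float, float]:
        half = self.width_fraction / 2.0
        return self.center_kev * (1 - half), self.center_kev * (1 + half)


def default_energy_windows() -> list[EnergyWindow]:
    """The ¹⁶⁶Ho four-window scheme: 81 keV/15% photopeak, two adjacent 8%
    windows, and the 118 keV/12% window used for dual-window correction."""
    pk = EnergyWindow(81.0, 0.15, "photopeak")
    lo_bound, hi_bound = pk.bounds_kev
    low_center = lo_bound / 1.04    # upper edge of an 8% window touches pk
    high_center = hi_bound / 0.96   # lower edge of an 8% window touches pk
    return [
        pk,
        EnergyWindow(low_center, 0.08, "lower_scatter"),
        EnergyWindow(high_center, 0.08, "upper_scatter"),
        EnergyWindow(118.0, 0.12, "downscatter_118"),
    ]


#: Per-window component fractions (primary, photopeak-scatter, downscatter)
#: relative to the photopeak primary amplitude.  The adjacent-window scatter
#: and downscatter fractions scale with keV window width on the photopeak
#: energy scale (0.30 * 6.48/12.15 = 0.16 per window).  The 118 keV
#: amplitudes put that window's total at ~0.26x the photopeak total, so the
#: k = 1.05 dual-window estimate slightly under-subtracts the true
#: contamination (0.27 vs 0.29 of the photopeak total) on top of its flatter
#: spatial shape — the qualitative behaviour seen for this isotope.
DEFAULT_COMPONENT_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "photopeak": (1.0, 0.30, 0.10),
    "lower_scatter": (0.02, 0.16, 0.053),
    "upper_scatter": (0.01, 0.16, 0.053),
    "downscatter_118": (0.0, 0.10, 0.26),
}


@dataclass
class AcquisitionConfig:
    """Acquisition geometry, timing, windows and contamination amplitudes.

    Defaults mirror the survey protocol: 120 projections over 360°, 20 s per
    projection, 128x128 matrix.  ``window_sensitivities`` (cps/MBq, total per
    window) overrides the collimator-derived values when given.
    """

    n_projections: int = 120
    time_per_projection_s: float = 20.0
    orbit_radius_mm: float = 250.0
    matrix: Optional[tuple[int, int]] = None  # derived from the grid if None
    windows: list[EnergyWindow] = field(default_factory=default_energy_windows)
    collimator: CollimatorPreset = MELP
    window_sensitivities: Optional[dict[str, float]] = None
    component_fractions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_FRACTIONS))
    scatter_kernel_fwhm_mm: float = 100.0
    downscatter_kernel_fwhm_mm: float = 200.0
    model_psf: bool = True
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if self.time_per_projection_s <= 0:
            raise ValueError("time_per_projection must be positive")
        roles = [w.role for w in self.windows]
        if roles.count("photopeak") != 1:
            raise ValueError("windows must include exactly one photopeak")
        for fr in self.component_fractions.values():
            if any(f < 0 for f in fr):
                raise ValueError("component fractions must be nonnegative")

    @property
    def photopeak(self) -> EnergyWindow:
        return next(w for w in self.windows if w.role == "photopeak")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_projections) * 360.0 / self.n_projections

    def photopeak_sensitivity_cps_per_mbq(self) -> float:
        """Total photopeak-window system sensitivity for this collimator."""
        if self.window_sensitivities and "photopeak" in self.window_sensitivities:
            return float(self.window_sensitivities["photopeak"])
        return (SENSITIVITY_CALIBRATION_CPS_PER_MBQ
                * self.collimator.geometric_efficiency())

    def window_sensitivity_cps_per_mbq(self, role: str) -> float:
        """Total sensitivity of any window under the component model."""
        if self.window_sensitivities and role in self.window_sensitivities:
            return float(self.window_sensitivities[role])
        s_peak = self.photopeak_sensitivity_cps_per_mbq()
        peak_sum = sum(self.component_fractions["photopeak"])
        return s_peak * sum(self.component_fractions[role]) / peak_sum


@dataclass
class ProjectionSet:
    """Per-window projection count stacks plus acquisition bookkeeping.

    ``counts[role]`` has shape (n_projections, nu, nv) where (nu, nv) is the
    detector matrix (u along rotated x, v along the scanner axis z).
    ``ground_truth[role]`` holds the noise-free ``primary`` /
    ``photopeak_scatter`` / ``downscatter`` components, which sum to the
    Poisson mean used for sampling.
    """

    counts: dict[str, np.ndarray]
    config: AcquisitionConfig
    activity_mbq: float
    grid: VoxelGrid
    ground_truth: Optional[dict[str, dict[str, np.ndarray]]] = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.counts.values()}
        if len(shapes) != 1:
            raise ValueError("all window stacks must share one shape")
        for role, arr in self.counts.items():
            if np.any(arr < 0):
                raise ValueError(f"negative counts in window {role!r}")

    @property
    def total_counts(self) -> dict[str, float]:
        return {role: float(arr.sum()) for role, arr in self.counts.items()}


# ---------------------------------------------------------------------------
# Projector
# ---------------------------------------------------------------------------


class Projector:
    """Rotation-based parallel-beam projector with attenuation and a
    distance-dependent Gaussian detector response.

    The detector sits at ``y = +orbit_radius`` in the rotated frame; rays run
    along +y.  The same operator (and its adjoint) serves simulation and
    OSEM reconstruction.  Per-angle transmission maps are cached in float32.
    """

    def __init__(
        self,
        grid: VoxelGrid,
        angles_deg: np.ndarray,
        attenuation_per_cm: Optional[np.ndarray] = None,
        collimator: Optional[CollimatorPreset] = None,
        orbit_radius_mm: float = 250.0,
    ) -> None:
        self.grid = grid
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.orbit_radius_mm = float(orbit_radius_mm)
        self.collimator = collimator
        if attenuation_per_cm is not None:
            attenuation_per_cm = np.asarray(attenuation_per_cm)
            if tuple(attenuation_per_cm.shape) != grid.shape:
                raise ValueError("attenuation grid mismatch")
        self.attenuation = attenuation_per_cm
        self._transmission: dict[int, np.ndarray] = {}
        self._depth_groups = self._build_depth_groups()

    # -- geometry helpers ---------------------------------------------------

    def _build_depth_groups(self):
        """Group depth indices by (rounded) PSF sigma to batch the blurs."""
        ny = self.grid.shape[1]
        y_world = self.grid.axis_coords(1)
        if self.collimator is None:
            return [(None, np.arange(ny))]
        dist = np.clip(self.orbit_radius_mm - y_world, 0.0, None)
        fwhm = np.sqrt(
            self.collimator.intrinsic_fwhm_mm**2
            + np.array([self.collimator.collimator_fwhm_mm(d) for d in dist]) ** 2
        )
        sig_u = fwhm * GAUSSIAN_FWHM_TO_SIGMA / self.grid.spacing[0]
        sig_v = fwhm * GAUSSIAN_FWHM_TO_SIGMA / self.grid.spacing[2]
        key = np.round(sig_u * 4.0) / 4.0
        groups = []
        for k in np.unique(key):
            idx = np.nonzero(key == k)[0]
            sv = float(np.mean(sig_v[idx]))
            groups.append(((float(k), sv), idx))
        return groups

    def _rotate(self, vol: np.ndarray, angle_deg: float) -> np.ndarray:
        if angle_deg % 360.0 == 0.0:
            return vol
        return ndimage.rotate(vol, angle_deg, axes=(0, 1), reshape=False,
                              order=1, mode="constant", cval=0.0,
                              prefilter=False)

    def _transmission_for(self, i: int) -> Optional[np.ndarray]:
        """exp(-integral of mu from voxel to detector) in the rotated frame."""
        if self.attenuation is None:
            return None
        t = self._transmission.get(i)
        if t is None:
            mu_rot = self._rotate(self.attenuation, self.angles_deg[i])
            dy_cm = self.grid.spacing[1] / 10.0
            # path from each voxel (exclusive of half of itself) to +y edge
            above = np.cumsum(mu_rot[:, ::-1, :], axis=1)[:, ::-1, :]
            path = (above - 0.5 * mu_rot) * dy_cm
            t = np.exp(-path).astype(np.float32)
            self._transmission[i] = t
        return t

    # -- operators ----------------------------------------------------------

    def forward_one(self, vol: np.ndarray, i: int) -> np.ndarray:
        rot = self._rotate(np.asarray(vol, dtype=np.float32), self.angles_deg[i])
        t = self._transmission_for(i)
        if t is not None:
            rot = rot * t
        out = np.zeros((self.grid.shape[0], self.grid.shape[2]), dtype=np.float32)
        for sig, idx in self._depth_groups:
            partial = rot[:, idx, :].sum(axis=1)
            if sig is not None and max(sig) > 0:
                partial = ndimage.gaussian_filter(partial, sigma=sig)
            out += partial
        return out

    def forward(self, vol: np.ndarray) -> np.ndarray:
        return np.stack([self.forward_one(vol, i)
                         for i in range(len(self.angles_deg))])

    def adjoint_one(self, proj: np.ndarray, i: int) -> np.ndarray:
        t = self._transmission_for(i)
        acc = np.zeros(self.grid.shape, dtype=np.float32)
        proj = np.asarray(proj, dtype=np.float32)
        for sig, idx in self._depth_groups:
            p = proj
            if sig is not None and max(sig) > 0:
                p = ndimage.gaussian_filter(p, sigma=sig)
            sl = p[:, None, :]
            if t is not None:
                acc[:, idx, :] += sl * t[:, idx, :]
            else:
                acc[:, idx, :] += sl
        return self._rotate(acc, -self.angles_deg[i])

    def adjoint(self, stack: np.ndarray) -> np.ndarray:
        acc = np.zeros(self.grid.shape, dtype=np.float32)
        for i in range(len(self.angles_deg)):
            acc += self.adjoint_one(stack[i], i)
        return acc


def forward_project(
    activity: np.ndarray,
    attenuation_per_cm: Optional[np.ndarray],
    grid: VoxelGrid,
    angle_deg: float,
    collimator: Optional[CollimatorPreset] = None,
    orbit_radius_mm: float = 250.0,
) -> np.ndarray:
    """Single-angle attenuated projection (expected-counts image, linear in
    the activity)."""
    proj = Projector(grid, np.array([angle_deg]), attenuation_per_cm,
                     collimator, orbit_radius_mm)
    return proj.forward_one(activity, 0)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _blur_stack(stack: np.ndarray, fwhm_mm: float, grid: VoxelGrid) -> np.ndarray:
    """Broad in-plane blur of a projection stack, renormalized so the kernel
    redistributes rather than removes counts at the detector edge."""
    if fwhm_mm <= 0:
        return stack.copy()
    sig = (fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / grid.spacing[0],
           fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / grid.spacing[2])
    out = np.empty_like(stack)
    for i in range(stack.shape[0]):
        out[i] = ndimage.gaussian_filter(stack[i], sigma=sig)
    s_in, s_out = stack.sum(), out.sum()
    if s_out > 0:
        out *= s_in / s_out
    return out


def simulate_projection_set(
    phantom: LabeledVolume,
    config: AcquisitionConfig,
) -> ProjectionSet:
    """Generate seeded multi-window projection data for a voxelized phantom.

    The returned ground truth satisfies, per window and exactly,
    ``primary + photopeak_scatter + downscatter == Poisson mean``.
    """
    grid = phantom.grid
    if config.matrix is not None and tuple(config.matrix) != (grid.shape[0], grid.shape[2]):
        raise ValueError(
            f"matrix {config.matrix} does not match grid detector plane "
            f"({grid.shape[0]}, {grid.shape[2]})")
    angles = config.angles_deg
    n, t = config.n_projections, config.time_per_projection_s
    activity_mbq = phantom.total_activity_mbq

    proj_att = Projector(grid, angles, phantom.attenuation,
                         config.collimator if config.model_psf else None,
                         config.orbit_radius_mm)
    p_raw = proj_att.forward(phantom.activity).astype(np.float64)
    proj_free = Projector(grid, angles, None, None, config.orbit_radius_mm)
    u_raw = proj_free.forward(phantom.activity).astype(np.float64)

    if activity_mbq > 0 and p_raw.sum() > 0:
        p_hat = p_raw * (n * activity_mbq / p_raw.sum())
        u_hat = u_raw * (n * activity_mbq / u_raw.sum())
    else:
        p_hat = np.zeros_like(p_raw)
        u_hat = np.zeros_like(u_raw)

    kp = _blur_stack(p_hat, config.scatter_kernel_fwhm_mm, grid)
    dn = _blur_stack(u_hat, config.downscatter_kernel_fwhm_mm, grid)

    peak_sum = sum(config.component_fractions["photopeak"])
    rng = np.random.default_rng(config.seed)
    counts: dict[str, np.ndarray] = {}
    ground_truth: dict[str, dict[str, np.ndarray]] = {}
    for w in config.windows:
        pf, sf, ds = config.component_fractions[w.role]
        frac_sum = pf + sf + ds
        total_sens = config.window_sensitivity_cps_per_mbq(w.role)
        amp = total_sens / frac_sum if frac_sum > 0 else 0.0
        primary = t * amp * pf * p_hat
        scat = t * amp * sf * kp
        down = t * amp * ds * dn
        mean = primary + scat + down
        ground_truth[w.role] = {
            "primary": primary, "photopeak_scatter": scat, "downscatter": down,
        }
        if config.poisson:
            counts[w.role] = rng.poisson(mean).astype(np.int64)
        else:
            counts[w.role] = mean
    return ProjectionSet(counts, config, activity_mbq, grid,
                         ground_truth=ground_truth,
                         meta={"angles_deg": angles.tolist()})


def simulate_reconstructed_volume(
    phantom: LabeledVolume,
    psf_fwhm_mm: float = 0.0,
    residual_scatter_fraction: float = 0.0,
    curvature: float = 0.0,
    noise_sigma_frac: float = 0.0,
    poisson_counts_per_mbq_ml: Optional[float] = None,
    seed: int = 0,
) -> VolumeImage:
    """Image-domain shortcut: emulate a reconstructed volume without running
    a reconstruction.

    Useful for testing the metric suite in isolation: Gaussian system blur,
    an optional residual scatter background (fraction of a broadly blurred
    activity field), an axial modulation ``1 + curvature * (z/L)^2`` that
    emulates scatter-correction under/over-correction, and seeded noise.
    The noise-free image is retained in ``meta['noiseless']``.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm must be >= 0")
    grid = phantom.grid
    img = np.asarray(phantom.activity, dtype=np.float64)
    if psf_fwhm_mm > 0:
        sig = [psf_fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / s for s in grid.spacing]
        img = ndimage.gaussian_filter(img, sigma=sig)
    if residual_scatter_fraction > 0:
        sig = [100.0 * GAUSSIAN_FWHM_TO_SIGMA / s for s in grid.spacing]
        img = img + residual_scatter_fraction * ndimage.gaussian_filter(
            np.asarray(phantom.activity, dtype=np.float64), sigma=sig)
    if curvature != 0.0:
        zmask = phantom.support.any(axis=(0, 1))
        z = grid.axis_coords(2)
        if zmask.any():
            zc = z[zmask].mean()
            length = zmask.sum() * grid.spacing[2]
        else:
            zc, length = 0.0, grid.shape[2] * grid.spacing[2]
        mod = 1.0 + curvature * ((z - zc) / length) ** 2
        img = img * mod[None, None, :]
    noiseless = img.copy()
    rng = np.random.default_rng(seed)
    if poisson_counts_per_mbq_ml is not None and poisson_counts_per_mbq_ml > 0:
        img = rng.poisson(img * poisson_counts_per_mbq_ml) / poisson_counts_per_mbq_ml
    elif noise_sigma_frac > 0:
        scale = noise_sigma_frac * img[phantom.support].mean() if phantom.support.any() else 0.0
        img = np.clip(img + rng.normal(0.0, scale, img.shape), 0.0, None)
    return VolumeImage(img, grid, meta={"noiseless": noiseless,
                                        "psf_fwhm_mm": psf_fwhm_mm,
                                        "curvature": curvature,
                                        "seed": seed})
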