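"""The five image-quality metrics and cross-scanner aggregation.

* **System sensitivity** per energy window: summed projection counts
  divided by (time per projection × number of projections × activity),
  in cps/MBq.
* **Axial uniformity**: per-slice masked sums over the cylinder, normalized
  by the profile mean, fitted with ``f(x) = c + A (x/L)^2`` by ordinary
  least squares; A near 0 means a flat profile (accurate scatter
  correction), A < 0 a central count excess (under-correction).
* **Noise**: per-slice coefficient of variation σ/μ (population SD) in an
  eroded cylinder VOI, averaged over included slices.
* **CRC**: ``(C/C_B - 1)/(R - 1)`` per insert with R the nominal
  sphere-to-background concentration ratio (R = 0 for the cold lung, so its
  CRC is ``1 - C_L/C_B``).
* **CNR**: ``(C - C_B)/σ_B`` per insert (negative for cold inserts).

CRC, CNR and COV are ratios, invariant under global count rescaling;
sensitivity scales linearly with counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd

from .core import VolumeImage
from .simulate import ProjectionSet
from .voi import VOISet

MIN_SLICE_VOXELS = 10


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class SensitivityResult:
    sensitivity_cps_per_mbq: dict[str, float]
    counts: dict[str, float]
    time_per_projection_s: float
    n_projections: int
    activity_mbq: float


@dataclass
class UniformityResult:
    profile: np.ndarray          # per-slice masked sums (included slices)
    x_mm: np.ndarray             # slice-center offsets from the phantom middle
    length_mm: float
    curvature: float             # fitted A of c + A (x/L)^2
    offset: float                # fitted c
    residual_rms: float

    @property
    def normalized_profile(self) -> np.ndarray:
        return self.profile / self.profile.mean()


@dataclass
class NoiseResult:
    cov_per_slice: np.ndarray
    slice_indices: np.ndarray
    mean_cov: float


@dataclass
class InsertContrast:
    name: str
    mean_counts: float           # C (C_S for spheres, C_L for the lung)
    background_mean: float       # C_B
    background_sd: float         # sigma_B (population)
    nominal_ratio: float         # R (0 for the lung)
    crc: float
    cnr: float


@dataclass
class ContrastResult:
    inserts: dict[str, InsertContrast]
    background_mean: float
    background_sd: float

    def crc(self, name: str) -> float:
        return self.inserts[name].crc

    def cnr(self, name: str) -> float:
        return self.inserts[name].cnr


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def system_sensitivity(projections: ProjectionSet) -> SensitivityResult:
    """Per-window system sensitivity from summed projection counts."""
    cfg = projections.config
    a = projections.activity_mbq
    if a <= 0:
        raise ValueError("activity must be positive")
    t, n = cfg.time_per_projection_s, cfg.n_projections
    counts = projections.total_counts
    sens = {role: c / (t * n * a) for role, c in counts.items()}
    return SensitivityResult(sens, counts, t, n, a)


def sensitivity_from_counts(total_counts: float, time_per_projection_s: float,
                            n_projections: int, activity_mbq: float) -> float:
    """Scalar form counts / (t · n · A), for tabulated inputs."""
    if activity_mbq <= 0 or time_per_projection_s <= 0 or n_projections < 1:
        raise ValueError("t, n and A must be positive")
    return total_counts / (time_per_projection_s * n_projections * activity_mbq)


def axial_uniformity(
    volume: VolumeImage,
    profile_mask: np.ndarray,
    length_mm: Optional[float] = None,
    min_voxels: int = MIN_SLICE_VOXELS,
    trim_slices: int = 3,
) -> UniformityResult:
    """Fit the curvature coefficient A to the masked axial profile.

    Slices with fewer than ``min_voxels`` masked voxels are excluded, and
    ``trim_slices`` further slices are dropped at each end of the profile to
    keep partial-volume end effects out of the fit (the default of 3 slices
    is about one detector-response FWHM at typical voxel sizes).  The fit
    model is
    ``normalized profile ≈ c + A (x/L)^2`` with an estimated offset c so the
    normalization convention cannot bias A.
    """
    vals = np.asarray(volume.values, dtype=np.float64)
    mask = np.asarray(profile_mask, dtype=bool)
    nz = mask.shape[2]
    counts_per_slice = mask.reshape(-1, nz).sum(axis=0)
    usable = np.nonzero(counts_per_slice >= min_voxels)[0]
    if trim_slices > 0 and len(usable) > 2 * trim_slices:
        usable = usable[trim_slices:-trim_slices]
    if len(usable) < 3:
        raise ValueError("fewer than 3 usable slices for the axial profile")
    profile = np.array([vals[:, :, k][mask[:, :, k]].sum() for k in usable])
    if np.all(profile == 0):
        raise ValueError("degenerate all-zero axial profile")
    z = volume.grid.axis_coords(2)[usable]
    if length_mm is None:
        length_mm = z[-1] - z[0] + volume.grid.spacing[2]
    x = z - (z[0] + z[-1]) / 2.0
    norm = profile / profile.mean()
    design = np.column_stack([np.ones_like(x), (x / length_mm) ** 2])
    coef, *_ = np.linalg.lstsq(design, norm, rcond=None)
    resid = norm - design @ coef
    return UniformityResult(profile, x, float(length_mm),
                            curvature=float(coef[1]), offset=float(coef[0]),
                            residual_rms=float(np.sqrt(np.mean(resid**2))))


def coefficient_of_variation(
    volume: VolumeImage,
    voi: np.ndarray,
    min_voxels: int = MIN_SLICE_VOXELS,
) -> NoiseResult:
    """Mean over slices of the per-slice population σ/μ inside the VOI."""
    vals = np.asarray(volume.values, dtype=np.float64)
    mask = np.asarray(voi, dtype=bool)
    covs, idx = [], []
    for k in range(mask.shape[2]):
        m = mask[:, :, k]
        if m.sum() < min_voxels:
            continue
        v = vals[:, :, k][m]
        mu = v.mean()
        if mu <= 0:
            raise ValueError(f"zero-mean slice {k} in the noise VOI")
        covs.append(v.std(ddof=0) / mu)
        idx.append(k)
    if not covs:
        raise ValueError("noise VOI empty on every slice")
    covs = np.asarray(covs)
    return NoiseResult(covs, np.asarray(idx), float(covs.mean()))


def contrast_recovery(
    volume: VolumeImage,
    vois: VOISet,
    nominal_ratio: float,
) -> ContrastResult:
    """CRC and CNR for every sphere VOI and the lung VOI.

    ``nominal_ratio`` is the nominal sphere-to-background concentration
    ratio R (never re-estimated from the image); the lung uses R = 0.
    """
    if nominal_ratio == 1.0:
        raise ValueError("R = 1 makes sphere CRC undefined")
    vals = np.asarray(volume.values, dtype=np.float64)
    bg = vois["background_shell"]
    if not bg.any():
        raise ValueError("background VOI is empty")
    c_b = float(vals[bg].mean())
    s_b = float(vals[bg].std(ddof=0))
    inserts: dict[str, InsertContrast] = {}
    for name in vois.sphere_names() + ["lung"]:
        m = vois[name]
        if not m.any():
            raise ValueError(f"VOI {name!r} is empty")
        c = float(vals[m].mean())
        r = 0.0 if name == "lung" else nominal_ratio
        crc = (c / c_b - 1.0) / (r - 1.0)
        cnr = (c - c_b) / s_b if s_b > 0 else np.nan
        inserts[name] = InsertContrast(name, c, c_b, s_b, r, crc, cnr)
    return ContrastResult(inserts, c_b, s_b)


def contrast_to_noise(volume: VolumeImage, vois: VOISet,
                      nominal_ratio: float = 8.0) -> ContrastResult:
    """CNR per insert; same container as :func:`contrast_recovery`.

    ``nominal_ratio`` only affects the CRC fields carried along (CNR itself
    does not depend on R).  Raises if the background SD is zero (CNR
    undefined on a noiseless constant background).
    """
    res = contrast_recovery(volume, vois, nominal_ratio)
    if res.background_sd == 0:
        raise ValueError("sigma_B = 0: CNR undefined")
    return res


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class HarmonizationReport:
    """Per-scanner × per-method metric table with cross-scanner aggregates.

    ``table`` columns: scanner, method, metric, insert (optional), value.
    ``aggregates`` carries mean, sample SD and range per (metric, insert,
    method); ``comparisons`` the labelled pairwise percent differences under
    both conventions (per-scanner relative change averaged over scanners,
    and relative change of the cross-scanner means).
    """

    table: pd.DataFrame
    aggregates: pd.DataFrame
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    meta: dict[str, Any] = field(default_factory=dict)


def records_to_frame(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records)
    required = {"scanner", "method", "metric", "value"}
    if not records or not required.issubset(df.columns):
        raise ValueError(f"records need at least columns {sorted(required)}")
    if "insert" not in df.columns:
        df["insert"] = ""
    df["insert"] = df["insert"].fillna("")
    return df


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD (range) per metric/insert/method across scanners."""
    def agg(g: pd.Series) -> pd.Series:
        return pd.Series({
            "mean": g.mean(),
            "sd": g.std(ddof=1) if len(g) > 1 else 0.0,
            "min": g.min(),
            "max": g.max(),
            "n": len(g),
        })
    return (df.groupby(["metric", "insert", "method"])["value"]
              .apply(agg).unstack().reset_index())


def percent_difference_per_scanner(df: pd.DataFrame, metric: str,
                                   method_a: str, method_b: str,
                                   insert: str = "") -> float:
    """Mean over scanners of 100·(a − b)/b, pairing methods per scanner."""
    sel = df[(df["metric"] == metric) & (df["insert"] == insert)]
    a = sel[sel["method"] == method_a].set_index("scanner")["value"]
    b = sel[sel["method"] == method_b].set_index("scanner")["value"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no scanners share both methods")
    return float((100.0 * (a[common] - b[common]) / b[common]).mean())


def percent_difference_of_means(df: pd.DataFrame, metric: str,
                                method_a: str, method_b: str,
                                insert: str = "") -> float:
    """100·(mean_a − mean_b)/mean_b with means over all measurements."""
    sel = df[(df["metric"] == metric) & (df["insert"] == insert)]
    ma = sel[sel["method"] == method_a]["value"].mean()
    mb = sel[sel["method"] == method_b]["value"].mean()
    return float(100.0 * (ma - mb) / mb)


def percent_difference_between_groups(df: pd.DataFrame, metric: str,
                                      group_col: str, group_a: str,
                                      group_b: str, insert: str = "",
                                      method: str | None = None) -> float:
    """100·(mean_a − mean_b)/mean_b between two scanner groups (e.g. vendors)."""
    sel = df[(df["metric"] == metric) & (df["insert"] == insert)]
    if method is not None:
        sel = sel[sel["method"] == method]
    ma = sel[sel[group_col] == group_a]["value"].mean()
    mb = sel[sel[group_col] == group_b]["value"].mean()
    return float(100.0 * (ma - mb) / mb)


def aggregate_report(records: list[dict],
                     comparisons: list[tuple[str, str, str, str]] | None = None
                     ) -> HarmonizationReport:
    """Build the harmonization report from per-scanner/per-method records.

    ``comparisons`` lists (metric, insert, method_a, method_b) pairs; for
    each, both percent-difference conventions are reported and labelled.
    """
    df = records_to_frame(records)
    aggregates = summarize(df)
    rows = []
    for metric, insert, ma, mb in comparisons or []:
        for convention, fn in (
                ("per_scanner_mean", percent_difference_per_scanner),
                ("of_means", percent_difference_of_means)):
            try:
                val = fn(df, metric, ma, mb, insert)
            except (ValueError, ZeroDivisionError):
                val = np.nan
            rows.append({"metric": metric, "insert": insert,
                         "method_a": ma, "method_b": mb,
                         "convention": convention, "percent_difference": val})
    return HarmonizationReport(df, aggregates, pd.DataFrame(rows))
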