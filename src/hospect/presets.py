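"""Study presets: collimators, phantom fills, and multi-center reference tables.

The preset data encode the acquisition conditions of a seven-scanner,
five-center ¹⁶⁶Ho-SPECT/CT image-quality survey (two GE systems with MEGP
collimators, five Siemens systems with MELP collimators).  Phantom fills are
given at scan start; the cylinder was filled homogeneously and the NEMA IEC
body phantom at a nominal sphere-to-background concentration ratio of ~8:1
with a cold lung insert.

The ``SURVEY_*`` tables hold the measured per-scanner metric values from that
survey.  They are *inputs* to the aggregation routines in
:mod:`hospect.metrics` (cross-scanner means, relative differences) and to the
example scripts; nothing in the simulator is fitted to them.
"""

from __future__ import annotations

from dataclasses import dataclass

# ---------------------------------------------------------------------------
# Collimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollimatorPreset:
    """Parallel-hole collimator geometry driving sensitivity and resolution.

    ``hole_diameter``/``septal_thickness``/``hole_length`` are mm; the
    intrinsic detector resolution is mm FWHM (9.5 mm NaI crystal class).
    """

    name: str
    hole_diameter_mm: float
    septal_thickness_mm: float
    hole_length_mm: float
    intrinsic_fwhm_mm: float = 3.8

    def __post_init__(self) -> None:
        for f in ("hole_diameter_mm", "septal_thickness_mm", "hole_length_mm",
                  "intrinsic_fwhm_mm"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def effective_hole_length_mm(self, mu_septa_per_mm: float = 2.75) -> float:
        """Hole length reduced by septal penetration, L_eff = L - 2/mu."""
        return self.hole_length_mm - 2.0 / mu_septa_per_mm

    def geometric_efficiency(self, mu_septa_per_mm: float = 2.75) -> float:
        """Point-source geometric efficiency, (d^2 / (L_eff (d + s)))^2."""
        d, s = self.hole_diameter_mm, self.septal_thickness_mm
        leff = self.effective_hole_length_mm(mu_septa_per_mm)
        return (d * d / (leff * (d + s))) ** 2

    def collimator_fwhm_mm(self, distance_mm: float,
                           mu_septa_per_mm: float = 2.75) -> float:
        """Distance-dependent collimator resolution, d (L_eff + z) / L_eff."""
        leff = self.effective_hole_length_mm(mu_septa_per_mm)
        return self.hole_diameter_mm * (leff + max(distance_mm, 0.0)) / leff


#: Medium-energy general-purpose collimator (GE Discovery class).
MEGP = CollimatorPreset("MEGP", hole_diameter_mm=3.0, septal_thickness_mm=1.05,
                        hole_length_mm=58.0)
#: Medium-energy low-penetration collimator (Siemens Symbia class).
MELP = CollimatorPreset("MELP", hole_diameter_mm=2.94, septal_thickness_mm=1.14,
                        hole_length_mm=40.64)

COLLIMATORS = {"MEGP": MEGP, "MELP": MELP}

#: Calibration from geometric efficiency to photopeak system sensitivity
#: [cps/MBq], chosen so the MELP photopeak sensitivity lands near the
#: survey's ~7 cps/MBq scale.  The MEGP/MELP *ratio* comes from geometry.
SENSITIVITY_CALIBRATION_CPS_PER_MBQ = 2485.0


# ---------------------------------------------------------------------------
# Phantom fill presets (volumes mL, activities MBq at scan start)
# ---------------------------------------------------------------------------

#: Homogeneous cylinder fills per imaging center.  Diameters in the survey
#: were 20-21.5 cm; a representative diameter in that range is assigned per
#: center (the analysis depends on volume and concentration, not on the exact
#: diameter/length split).
CYLINDER_PRESETS: dict[str, dict[str, float]] = {
    "LUMC":       {"volume_ml": 6800.0, "activity_mbq": 269.0, "diameter_mm": 210.0},
    "MUMC":       {"volume_ml": 6816.0, "activity_mbq": 281.0, "diameter_mm": 210.0},
    "NKI":        {"volume_ml": 9325.0, "activity_mbq": 293.0, "diameter_mm": 215.0},
    "Radboudumc": {"volume_ml": 6283.0, "activity_mbq": 289.0, "diameter_mm": 200.0},
    "UMCU":       {"volume_ml": 6266.0, "activity_mbq": 332.0, "diameter_mm": 200.0},
}

#: NEMA IEC body-phantom fills per imaging center: background and total
#: sphere volume/activity, plus the ratio printed on the fill sheet.  The
#: nominal ratio used for CRC is always recomputed from the concentrations;
#: for NKI the fill-sheet ratio (7.4) is not consistent with its recorded
#: volumes/activities (concentration ratio ~7.1) and both are retained.
NEMA_PRESETS: dict[str, dict[str, float]] = {
    "LUMC":       {"background_volume_ml": 9756.0, "background_activity_mbq": 261.0,
                   "spheres_volume_ml": 48.0, "spheres_activity_mbq": 10.0,
                   "fill_sheet_ratio": 8.0},
    "MUMC":       {"background_volume_ml": 9772.0, "background_activity_mbq": 259.0,
                   "spheres_volume_ml": 48.0, "spheres_activity_mbq": 10.0,
                   "fill_sheet_ratio": 8.0},
    "NKI":        {"background_volume_ml": 9883.0, "background_activity_mbq": 289.0,
                   "spheres_volume_ml": 48.0, "spheres_activity_mbq": 10.0,
                   "fill_sheet_ratio": 7.4},
    "Radboudumc": {"background_volume_ml": 9775.0, "background_activity_mbq": 279.0,
                   "spheres_volume_ml": 48.0, "spheres_activity_mbq": 11.0,
                   "fill_sheet_ratio": 8.0},
    "UMCU":       {"background_volume_ml": 9756.0, "background_activity_mbq": 342.0,
                   "spheres_volume_ml": 48.0, "spheres_activity_mbq": 13.0,
                   "fill_sheet_ratio": 8.0},
}

#: NEMA IEC sphere inner diameters, mm (ascending).
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


# ---------------------------------------------------------------------------
# Multi-center survey reference tables
# ---------------------------------------------------------------------------

#: Scanner id -> vendor for the seven survey systems.
SURVEY_SCANNER_VENDOR = {
    "GE 670": "GE", "GE 870": "GE",
    "Siemens Intevo 1": "Siemens", "Siemens Intevo 2": "Siemens",
    "Siemens Symbia 1": "Siemens", "Siemens Symbia 2": "Siemens",
    "Siemens Symbia 3": "Siemens",
}

#: Measured system sensitivity [cps/MBq] per scanner per energy window
#: (cylinder projection data): lower scatter, 81 keV photopeak, upper
#: adjacent scatter, 118 keV window.
SURVEY_SENSITIVITY_CPS_PER_MBQ = {
    "GE 670":           {"lower_scatter": 2.16, "photopeak": 4.54, "upper_scatter": 1.42, "downscatter_118": 2.67},
    "GE 870":           {"lower_scatter": 2.00, "photopeak": 4.50, "upper_scatter": 1.29, "downscatter_118": 2.28},
    "Siemens Intevo 1": {"lower_scatter": 2.70, "photopeak": 6.64, "upper_scatter": 1.57, "downscatter_118": 2.51},
    "Siemens Intevo 2": {"lower_scatter": 2.96, "photopeak": 7.04, "upper_scatter": 1.79, "downscatter_118": 2.83},
    "Siemens Symbia 1": {"lower_scatter": 2.68, "photopeak": 6.53, "upper_scatter": 1.63, "downscatter_118": 2.44},
    "Siemens Symbia 2": {"lower_scatter": 2.85, "photopeak": 7.03, "upper_scatter": 1.89, "downscatter_118": 2.77},
    "Siemens Symbia 3": {"lower_scatter": 3.15, "photopeak": 7.72, "upper_scatter": 2.09, "downscatter_118": 3.00},
}

#: Measured cylinder COV per scanner per scatter-correction method.  GE
#: scanners were reconstructed at both 4i8s and 10i8s for DEW/TEW; Siemens at
#: 10i8s; the Monte-Carlo-corrected reference reconstruction at 10i8s.
SURVEY_COV = {
    "GE 670":           {"dew_4i8s": 0.28, "dew_10i8s": 0.53, "tew_4i8s": 0.27, "tew_10i8s": 0.60, "mc": 0.38},
    "GE 870":           {"dew_4i8s": 0.23, "dew_10i8s": 0.44, "tew_4i8s": 0.28, "tew_10i8s": 0.54, "mc": 0.28},
    "Siemens Intevo 1": {"dew": 0.22, "tew": 0.27, "mc": 0.22},
    "Siemens Intevo 2": {"dew": 0.20, "tew": 0.26, "mc": 0.20},
    "Siemens Symbia 1": {"dew": 0.22, "tew": 0.26, "mc": 0.19},
    "Siemens Symbia 2": {"dew": 0.21, "tew": 0.26, "mc": 0.20},
    "Siemens Symbia 3": {"dew": 0.18, "tew": 0.22, "mc": 0.17},
}

#: Cross-scanner mean CRC per insert per scatter-correction method (all
#: survey measurements pooled).  Keys are sphere inner diameter in mm, plus
#: the cold lung insert.
SURVEY_CRC_MEAN = {
    "dew": {10: 0.04, 13: 0.08, 17: 0.12, 22: 0.22, 28: 0.34, 37: 0.44, "lung": 0.62},
    "tew": {10: 0.04, 13: 0.05, 17: 0.14, 22: 0.26, 28: 0.40, 37: 0.54, "lung": 0.59},
    "mc":  {10: 0.04, 13: 0.10, 17: 0.15, 22: 0.32, 28: 0.49, 37: 0.62, "lung": 0.73},
}


def dew_cov(scanner: str) -> float:
    """DEW COV for a scanner; GE systems at 4 iterations / 8 subsets."""
    row = SURVEY_COV[scanner]
    return row.get("dew", row.get("dew_4i8s"))


def tew_cov(scanner: str) -> float:
    """TEW COV for a scanner; GE systems at 4 iterations / 8 subsets."""
    row = SURVEY_COV[scanner]
    return row.get("tew", row.get("tew_4i8s"))
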