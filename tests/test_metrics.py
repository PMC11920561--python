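"""Metric definitions on constructed volumes, plus survey aggregation."""

import numpy as np
import pandas as pd
import pytest

import hospect as h
from hospect.metrics import (aggregate_report, axial_uniformity,
                             coefficient_of_variation, contrast_recovery,
                             contrast_to_noise,
                             percent_difference_between_groups,
                             percent_difference_of_means,
                             percent_difference_per_scanner, records_to_frame,
                             sensitivity_from_counts, summarize)
from hospect.presets import (SURVEY_CRC_MEAN, SURVEY_SCANNER_VENDOR,
                             SURVEY_SENSITIVITY_CPS_PER_MBQ, dew_cov, tew_cov)


class TestSensitivity:
    def test_worked_example(self):
        assert sensitivity_from_counts(2_400_000, 20.0, 120, 300.0) == \
            pytest.approx(3.3333, abs=1e-4)

    def test_linear_in_counts(self):
        a = sensitivity_from_counts(1000.0, 10.0, 60, 100.0)
        b = sensitivity_from_counts(3000.0, 10.0, 60, 100.0)
        assert b == pytest.approx(3 * a)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sensitivity_from_counts(1.0, 0.0, 60, 100.0)
        with pytest.raises(ValueError):
            sensitivity_from_counts(1.0, 10.0, 60, 0.0)


def _uniform_cylinder(grid, radius_mm=80.0, value=1.0):
    X, Y, _ = grid.coordinate_arrays()
    mask = np.broadcast_to(X**2 + Y**2 <= radius_mm**2, grid.shape).copy()
    vals = np.where(mask, value, 0.0)
    return h.VolumeImage(vals, grid), mask


class TestUniformity:
    def test_flat_profile_zero_curvature(self, grid64):
        img, mask = _uniform_cylinder(grid64)
        res = axial_uniformity(img, mask)
        assert res.curvature == pytest.approx(0.0, abs=1e-10)
        assert res.offset == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("a_true", [-0.4, 0.0, 0.15])
    def test_constructed_curvature_recovery(self, grid64, a_true):
        """A quadratic axial modulation comes back as the fitted A.

        The fit normalizes by the profile mean, so the recovered value is
        a_true scaled by 1/mean(1 + a_true (x/L)^2); the test compares
        against that exact expectation.
        """
        img, mask = _uniform_cylinder(grid64)
        z = grid64.axis_coords(2)
        length = z[-1] - z[0] + grid64.spacing[2]
        mod = 1.0 + a_true * ((z - z.mean()) / length) ** 2
        vals = img.values * mod[None, None, :]
        res = axial_uniformity(h.VolumeImage(vals, grid64), mask,
                               length_mm=length, trim_slices=0)
        x = z - z.mean()
        expected = a_true / np.mean(1.0 + a_true * (x / length) ** 2)
        assert res.curvature == pytest.approx(expected, abs=1e-6)
        assert abs(res.curvature - a_true) < 0.02

    def test_trim_drops_end_slices(self, grid64):
        img, mask = _uniform_cylinder(grid64)
        vals = img.values.copy()
        vals[:, :, :2] *= 0.1  # corrupt ends
        vals[:, :, -2:] *= 0.1
        res = axial_uniformity(h.VolumeImage(vals, grid64), mask, trim_slices=3)
        assert res.curvature == pytest.approx(0.0, abs=1e-10)

    def test_too_few_slices(self, grid64):
        img, mask = _uniform_cylinder(grid64)
        m = np.zeros_like(mask)
        m[:, :, 30:32] = mask[:, :, 30:32]
        with pytest.raises(ValueError):
            axial_uniformity(img, m, trim_slices=0)


class TestCov:
    def test_two_point_distribution(self, grid64):
        """Half 1s half 3s per slice: sigma/mu = 1/2 exactly."""
        vals = np.zeros(grid64.shape)
        vals[:16, :16, :] = 1.0
        vals[16:32, :16, :] = 3.0
        voi = np.zeros(grid64.shape, bool)
        voi[:32, :16, :] = True
        res = coefficient_of_variation(h.VolumeImage(vals, grid64), voi)
        assert res.mean_cov == pytest.approx(0.5)
        np.testing.assert_allclose(res.cov_per_slice, 0.5)

    def test_poisson_cov_inverse_sqrt_lambda(self, grid64):
        """COV of Poisson(lambda) noise ~ 1/sqrt(lambda) within 10%."""
        rng = np.random.default_rng(2024)
        for lam in (25.0, 100.0, 400.0):
            vals = rng.poisson(lam, grid64.shape).astype(float)
            voi = np.ones(grid64.shape, bool)
            res = coefficient_of_variation(h.VolumeImage(vals, grid64), voi)
            assert res.mean_cov == pytest.approx(1 / np.sqrt(lam), rel=0.10)

    def test_scale_invariance(self, grid64):
        rng = np.random.default_rng(3)
        vals = rng.poisson(50.0, grid64.shape).astype(float) + 1.0
        voi = np.ones(grid64.shape, bool)
        a = coefficient_of_variation(h.VolumeImage(vals, grid64), voi)
        b = coefficient_of_variation(h.VolumeImage(7.0 * vals, grid64), voi)
        assert b.mean_cov == pytest.approx(a.mean_cov, rel=1e-12)

    def test_zero_mean_slice_rejected(self, grid64):
        vals = np.zeros(grid64.shape)
        voi = np.ones(grid64.shape, bool)
        with pytest.raises(ValueError):
            coefficient_of_variation(h.VolumeImage(vals, grid64), voi)


def _synthetic_vois(nema_spec, grid):
    return h.build_voi_set(nema_spec, grid)


class TestContrast:
    def test_perfect_image_crc_one(self, nema_spec, nema64, grid64):
        """On the noiseless voxelized phantom every CRC is 1 by definition."""
        img = h.VolumeImage(nema64.activity, grid64)
        vois = _synthetic_vois(nema_spec, grid64)
        res = contrast_recovery(img, vois, nema_spec.fill_ratio)
        for name in vois.sphere_names():
            assert res.inserts[name].crc == pytest.approx(1.0, abs=0.02)
        assert res.inserts["lung"].crc == pytest.approx(1.0, abs=0.02)

    def test_no_contrast_gives_zero(self, nema_spec, grid64):
        img = h.VolumeImage(np.ones(grid64.shape), grid64)
        vois = _synthetic_vois(nema_spec, grid64)
        res = contrast_recovery(img, vois, 8.0)
        for ins in res.inserts.values():
            assert ins.crc == pytest.approx(0.0, abs=1e-12)

    def test_r_equal_one_rejected(self, nema_spec, grid64):
        img = h.VolumeImage(np.ones(grid64.shape), grid64)
        with pytest.raises(ValueError, match="R = 1"):
            contrast_recovery(img, _synthetic_vois(nema_spec, grid64), 1.0)

    def test_cnr_constructed_value(self, nema_spec, grid64):
        """Background mean 10, sd 2, sphere mean 16 -> CNR = 3."""
        rng = np.random.default_rng(5)
        vois = _synthetic_vois(nema_spec, grid64)
        vals = np.full(grid64.shape, 10.0)
        bg = vois["background_shell"]
        noise = rng.choice([-2.0, 2.0], size=int(bg.sum()))
        # force an exactly balanced +-2 pattern: sd exactly 2
        half = len(noise) // 2
        noise = np.concatenate([np.full(half, 2.0),
                                np.full(len(noise) - half, -2.0)])
        vals[bg] = 10.0 + noise
        name = vois.sphere_names()[-1]
        vals[vois[name]] = 16.0 + (10.0 + noise.mean() - 10.0)
        res = contrast_to_noise(h.VolumeImage(vals, grid64), vois, 8.0)
        got = res.inserts[name]
        assert got.background_sd == pytest.approx(2.0, rel=1e-3)
        assert got.cnr == pytest.approx(3.0, rel=5e-3)

    def test_cold_insert_negative_cnr(self, nema_spec, nema64, grid64):
        rng = np.random.default_rng(6)
        vals = nema64.activity + rng.normal(0, 1e-3, grid64.shape)
        vois = _synthetic_vois(nema_spec, grid64)
        res = contrast_to_noise(h.VolumeImage(vals, grid64), vois, 8.0)
        assert res.inserts["lung"].cnr < 0

    def test_scale_invariance(self, nema_spec, nema64, grid64):
        rng = np.random.default_rng(7)
        vals = nema64.activity + rng.normal(0, 0.005, grid64.shape)
        vois = _synthetic_vois(nema_spec, grid64)
        a = contrast_recovery(h.VolumeImage(vals, grid64), vois, 8.0)
        b = contrast_recovery(h.VolumeImage(4.0 * vals, grid64), vois, 8.0)
        for name in a.inserts:
            assert b.inserts[name].crc == pytest.approx(a.inserts[name].crc,
                                                        rel=1e-9)
            assert b.inserts[name].cnr == pytest.approx(a.inserts[name].cnr,
                                                        rel=1e-9)

    def test_sigma_zero_cnr_rejected(self, nema_spec, grid64):
        img = h.VolumeImage(np.ones(grid64.shape), grid64)
        with pytest.raises(ValueError, match="sigma_B"):
            contrast_to_noise(img, _synthetic_vois(nema_spec, grid64), 8.0)


class TestAggregation:
    def test_records_to_frame_validation(self):
        with pytest.raises(ValueError):
            records_to_frame([{"scanner": "a", "value": 1.0}])

    def test_summarize_mean_and_sample_sd(self):
        recs = [{"scanner": s, "method": "tew", "metric": "cov", "value": v}
                for s, v in (("a", 0.2), ("b", 0.3), ("c", 0.4))]
        out = summarize(records_to_frame(recs))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["sd"] == pytest.approx(0.1)  # ddof=1
        assert row["n"] == 3

    def test_percent_difference_conventions_differ(self):
        recs = [
            {"scanner": "a", "method": "x", "metric": "m", "value": 1.0},
            {"scanner": "a", "method": "y", "metric": "m", "value": 2.0},
            {"scanner": "b", "method": "x", "metric": "m", "value": 30.0},
            {"scanner": "b", "method": "y", "metric": "m", "value": 40.0},
        ]
        df = records_to_frame(recs)
        per = percent_difference_per_scanner(df, "m", "x", "y")
        of_means = percent_difference_of_means(df, "m", "x", "y")
        assert per == pytest.approx((-50.0 + -25.0) / 2)
        assert of_means == pytest.approx(100 * (15.5 - 21.0) / 21.0)
        assert per != of_means

    def test_survey_vendor_sensitivity_gap_35_percent(self):
        """Mean GE photopeak sensitivity sits ~35% below the Siemens mean."""
        recs = [{"scanner": s, "vendor": SURVEY_SCANNER_VENDOR[s],
                 "method": "acq", "metric": "sens",
                 "value": row["photopeak"]}
                for s, row in SURVEY_SENSITIVITY_CPS_PER_MBQ.items()]
        df = records_to_frame(recs)
        gap = percent_difference_between_groups(df, "sens", "vendor",
                                                "GE", "Siemens")
        assert gap == pytest.approx(-35.35, abs=0.05)
        assert round(-gap) == 35

    def test_survey_largest_sphere_crc_23_percent(self):
        dew, tew = SURVEY_CRC_MEAN["dew"][37], SURVEY_CRC_MEAN["tew"][37]
        diff = 100.0 * (tew - dew) / dew
        assert diff == pytest.approx(22.7, abs=0.05)
        assert round(diff) == 23

    def test_survey_cov_reduction_16_percent(self):
        """Per-scanner DEW-vs-TEW COV change averages ~-15.5% (16 +- 1)."""
        recs = []
        for s in SURVEY_SCANNER_VENDOR:
            recs.append({"scanner": s, "method": "dew", "metric": "cov",
                         "value": dew_cov(s)})
            recs.append({"scanner": s, "method": "tew", "metric": "cov",
                         "value": tew_cov(s)})
        df = records_to_frame(recs)
        red = percent_difference_per_scanner(df, "cov", "dew", "tew")
        assert abs(-red - 16.0) <= 1.0

    def test_aggregate_report_shapes(self):
        recs = [
            {"scanner": "a", "method": "dew", "metric": "cov", "value": 0.2},
            {"scanner": "a", "method": "tew", "metric": "cov", "value": 0.25},
        ]
        rep = aggregate_report(recs, comparisons=[("cov", "", "dew", "tew")])
        assert isinstance(rep.table, pd.DataFrame)
        assert set(rep.comparisons["convention"]) == {"per_scanner_mean",
                                                      "of_means"}
        assert np.isfinite(rep.comparisons["percent_difference"]).all()
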