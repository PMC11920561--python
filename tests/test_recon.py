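"""OSEM reconstruction: invariants, count consistency, post-filter."""

import numpy as np
import pytest

import hospect as h
from hospect.recon import (ReconConfig, _bit_reversed_subsets,
                           osem_reconstruct, post_filter,
                           reconstruct_projection_set)
from hospect.scatter import ScatterConfig, estimate_scatter
from hospect.simulate import Projector


class TestConfigAndSubsets:
    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ReconConfig(iterations=0)
        with pytest.raises(ValueError):
            ReconConfig(subsets=0)
        with pytest.raises(ValueError):
            ReconConfig(post_filter_fwhm_mm=-1.0)

    def test_subsets_partition_all_angles(self):
        for n_angles, n_sub in ((24, 8), (60, 8), (7, 4), (10, 1)):
            subsets = _bit_reversed_subsets(n_angles, n_sub)
            allidx = np.sort(np.concatenate(subsets))
            np.testing.assert_array_equal(allidx, np.arange(n_angles))

    def test_bit_reversed_order(self):
        subsets = _bit_reversed_subsets(16, 8)
        firsts = [s[0] for s in subsets]
        assert firsts == [0, 4, 2, 6, 1, 5, 3, 7]


class TestOsem:
    def test_zero_data_gives_zero_image(self, small_cylinder):
        _, vol = small_cylinder
        angles = np.arange(8) * 45.0
        y = np.zeros((8, 32, 32))
        img = osem_reconstruct(y, vol.grid, angles,
                               config=ReconConfig(iterations=2, subsets=4))
        assert np.all(img.values == 0)

    def test_nonnegativity(self, small_cylinder, small_noisefree_pset):
        _, vol = small_cylinder
        img = reconstruct_projection_set(
            small_noisefree_pset, vol.attenuation,
            estimate_scatter(small_noisefree_pset, ScatterConfig(method="oracle")),
            ReconConfig(iterations=2, subsets=4))
        assert img.values.min() >= 0

    def test_point_source_localization(self):
        grid = h.VoxelGrid.centered(32, 6.0)
        act = np.zeros(grid.shape)
        act[20, 14, 16] = 5.0
        angles = np.arange(16) * 22.5
        proj = Projector(grid, angles)
        y = proj.forward(act)
        img = osem_reconstruct(y, grid, angles,
                               config=ReconConfig(iterations=5, subsets=4,
                                                  attenuation_correction=False))
        assert np.unravel_index(np.argmax(img.values), grid.shape) == (20, 14, 16)

    def test_count_consistency_one_percent(self, small_cylinder,
                                           small_noisefree_pset):
        """Total counts of the reprojected estimate match the true primary
        counts to 1% after 10i8s with attenuation + oracle scatter."""
        _, vol = small_cylinder
        pset = small_noisefree_pset
        img = reconstruct_projection_set(
            pset, vol.attenuation,
            estimate_scatter(pset, ScatterConfig(method="oracle")),
            ReconConfig(iterations=10, subsets=8))
        proj = Projector(vol.grid, pset.config.angles_deg, vol.attenuation)
        refit = proj.forward(img.values).sum()
        truth = pset.ground_truth["photopeak"]["primary"].sum()
        assert refit == pytest.approx(truth, rel=0.01)

    def test_angle_mismatch_rejected(self, small_cylinder):
        _, vol = small_cylinder
        with pytest.raises(ValueError, match="angle"):
            osem_reconstruct(np.zeros((8, 32, 32)), vol.grid,
                             np.arange(4) * 90.0)

    def test_scatter_shape_mismatch_rejected(self, small_cylinder):
        _, vol = small_cylinder
        with pytest.raises(ValueError, match="congruent"):
            osem_reconstruct(np.zeros((8, 32, 32)), vol.grid,
                             np.arange(8) * 45.0,
                             scatter_estimate=np.zeros((8, 16, 16)))

    def test_deterministic(self, small_cylinder, small_noisefree_pset):
        _, vol = small_cylinder
        rc = ReconConfig(iterations=2, subsets=4)
        a = reconstruct_projection_set(small_noisefree_pset, vol.attenuation,
                                       None, rc)
        b = reconstruct_projection_set(small_noisefree_pset, vol.attenuation,
                                       None, rc)
        np.testing.assert_array_equal(a.values, b.values)

    def test_provenance_recorded(self, small_cylinder, small_noisefree_pset):
        _, vol = small_cylinder
        img = reconstruct_projection_set(
            small_noisefree_pset, vol.attenuation, None,
            ReconConfig(iterations=2, subsets=4))
        assert img.meta["recon"]["iterations"] == 2
        assert img.meta["recon"]["subsets"] == 4


class TestMoreUpdates:
    def test_more_updates_raise_crc_and_cov(self, cylinder_session,
                                            cylinder64, grid64):
        """Going from 4i8s to 10i8s on the same noisy data must not reduce
        resolution or noise: COV increases; the reconstruction moves closer
        to the data (count consistency improves)."""
        from hospect.metrics import coefficient_of_variation
        from hospect.voi import eroded_cylinder_voi
        pset = cylinder_session["pset"]
        est = estimate_scatter(pset, ScatterConfig(method="oracle"))
        vol10 = reconstruct_projection_set(pset, cylinder64.attenuation, est,
                                           ReconConfig(iterations=10, subsets=8))
        voi = eroded_cylinder_voi(cylinder64.support, grid64)
        cov4 = cylinder_session["cov"]["oracle"]
        cov10 = coefficient_of_variation(vol10, voi).mean_cov
        assert cov10 > cov4


class TestPostFilter:
    def test_zero_fwhm_identity(self, cylinder64, grid64):
        img = h.VolumeImage(cylinder64.activity, grid64)
        out = post_filter(img, 0.0)
        np.testing.assert_array_equal(out.values, img.values)

    def test_preserves_total_counts(self, cylinder64, grid64):
        img = h.VolumeImage(cylinder64.activity, grid64)
        out = post_filter(img, 10.0)
        assert out.values.sum() == pytest.approx(img.values.sum(), rel=1e-3)

    def test_reduces_variance(self, grid64):
        rng = np.random.default_rng(0)
        img = h.VolumeImage(rng.poisson(50.0, grid64.shape).astype(float), grid64)
        out = post_filter(img, 10.0)
        assert out.values.var() < img.values.var()

    def test_semigroup_property(self, grid64):
        """Two Gaussian passes compose like one with fwhm = sqrt(f1²+f2²).

        Kernels at least ~2.5 voxels FWHM keep the sampled-Gaussian
        composition error negligible.
        """
        rng = np.random.default_rng(1)
        img = h.VolumeImage(rng.random(grid64.shape), grid64)
        twice = post_filter(post_filter(img, 16.0), 12.0)
        once = post_filter(img, float(np.hypot(16.0, 12.0)))
        interior = np.s_[10:-10, 10:-10, 10:-10]
        np.testing.assert_allclose(twice.values[interior], once.values[interior],
                                   atol=1e-4, rtol=0)

    def test_negative_fwhm_rejected(self, grid64):
        img = h.VolumeImage(np.zeros(grid64.shape), grid64)
        with pytest.raises(ValueError):
            post_filter(img, -1.0)
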