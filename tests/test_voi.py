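"""VOIs: analytic volumes, disjointness, morphology, rigid registration."""

import numpy as np
import pytest
from scipy import ndimage

import hospect as h
from hospect.voi import (BACKGROUND_SHELL_HEIGHT_MM,
                         BACKGROUND_SHELL_REVOLUTION_RADIUS_MM,
                         BACKGROUND_SHELL_THICKNESS_MM, RigidTransform,
                         axial_profile_mask, build_voi_set,
                         eroded_cylinder_voi, label_masks,
                         make_background_shell_voi, make_lung_voi,
                         make_sphere_vois, register_rigid)


def _voi_volume_ml(mask, grid):
    return mask.sum() * grid.voxel_volume_ml


class TestRigidTransform:
    def test_identity_roundtrip(self):
        t = RigidTransform.from_angle_z(30.0, (5.0, -3.0, 2.0))
        pts = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-12)

    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]))

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0)


class TestSphereVois:
    def test_volumes_match_analytic(self, nema_spec):
        grid = h.VoxelGrid.centered((180, 180, 60), 2.0)
        masks = make_sphere_vois(nema_spec, grid)
        for s in nema_spec.spheres:
            analytic = h.sphere_analytic_volume(s.inner_diameter_mm)
            got = _voi_volume_ml(masks[f"sphere_{s.inner_diameter_mm:g}"], grid)
            assert got == pytest.approx(analytic, rel=0.08)

    def test_disjoint(self, nema_spec, grid64):
        vois = build_voi_set(nema_spec, grid64)
        total = np.zeros(grid64.shape, dtype=int)
        for m in vois.masks.values():
            total += m.astype(int)
        assert total.max() <= 1

    def test_sphere_exits_grid_rejected(self, nema_spec):
        grid = h.VoxelGrid.centered(16, 6.0)  # 96 mm box, spheres at r=57 mm
        with pytest.raises(ValueError, match="exits"):
            make_sphere_vois(nema_spec, grid)

    def test_requires_nema_spec(self, cylinder_spec, grid64):
        with pytest.raises(ValueError):
            make_sphere_vois(cylinder_spec, grid64)

    def test_sphere_names_sorted(self, nema_spec, grid64):
        vois = build_voi_set(nema_spec, grid64)
        diam = [float(n.split("_")[1]) for n in vois.sphere_names()]
        assert diam == sorted(diam) and len(diam) == 6


class TestShellAndLung:
    def test_shell_volume_analytic(self, nema_spec):
        """Annulus volume pi(r_out^2 - r_in^2) h before exclusions."""
        grid = h.VoxelGrid.centered(160, 2.0)
        m = make_background_shell_voi(nema_spec, grid)
        r_in = BACKGROUND_SHELL_REVOLUTION_RADIUS_MM - BACKGROUND_SHELL_THICKNESS_MM / 2
        r_out = BACKGROUND_SHELL_REVOLUTION_RADIUS_MM + BACKGROUND_SHELL_THICKNESS_MM / 2
        analytic = np.pi * (r_out**2 - r_in**2) * BACKGROUND_SHELL_HEIGHT_MM / 1000.0
        assert _voi_volume_ml(m, grid) == pytest.approx(analytic, rel=0.03)

    def test_shell_inside_background_compartment(self, nema_spec, nema64, grid64):
        vois = build_voi_set(nema_spec, grid64)
        shell = vois["background_shell"]
        from hospect.core import LABEL_BACKGROUND
        assert np.all(nema64.labels[shell] == LABEL_BACKGROUND)

    def test_lung_voi_inside_lung(self, nema_spec, nema64, grid64):
        m = make_lung_voi(nema_spec, grid64)
        from hospect.core import LABEL_LUNG
        # restrict to the interior axial span actually labelled
        frac = (nema64.labels[m] == LABEL_LUNG).mean()
        assert frac > 0.95

    def test_label_masks_match_spec(self, nema_spec, nema64):
        masks = label_masks(nema64.labels, nema_spec)
        assert set(masks) == {f"sphere_{s.inner_diameter_mm:g}"
                              for s in nema_spec.spheres} | {"lung"}
        for m in masks.values():
            assert m.any()


class TestMorphology:
    def test_erosion_analytic_cylinder(self, cylinder_spec, cylinder64, grid64):
        """Eroding the D=200 mm cylinder by 30 mm leaves ~a D=140 mm one."""
        voi = eroded_cylinder_voi(cylinder64.support, grid64, erosion_mm=30.0)
        r = cylinder_spec.diameter_mm / 2 - 30.0
        length = cylinder_spec.length_mm - 60.0
        analytic = np.pi * r**2 * length / 1000.0
        assert _voi_volume_ml(voi, grid64) == pytest.approx(analytic, rel=0.10)

    def test_zero_erosion_identity(self, cylinder64, grid64):
        voi = eroded_cylinder_voi(cylinder64.support, grid64, erosion_mm=0.0)
        np.testing.assert_array_equal(voi, cylinder64.support)

    def test_over_erosion_raises(self, cylinder64, grid64):
        with pytest.raises(ValueError, match="empties"):
            eroded_cylinder_voi(cylinder64.support, grid64, erosion_mm=150.0)

    def test_empty_mask_raises(self, grid64):
        with pytest.raises(ValueError, match="empty"):
            eroded_cylinder_voi(np.zeros(grid64.shape, bool), grid64)

    def test_profile_mask_grows_in_plane_only(self, cylinder64, grid64):
        out = axial_profile_mask(cylinder64.support, grid64)
        assert out.sum() > cylinder64.support.sum()
        assert np.all(out[cylinder64.support])
        # no new slices appear along z
        orig_z = cylinder64.support.any(axis=(0, 1))
        np.testing.assert_array_equal(out.any(axis=(0, 1)), orig_z)


class TestRegistration:
    def test_identity_on_same_volume(self, nema64, grid64):
        img = h.VolumeImage(nema64.support.astype(float), grid64)
        t = register_rigid(img, img)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-6)

    def test_translation_recovery(self, nema64, grid64):
        ref = h.VolumeImage(nema64.support.astype(float), grid64)
        shifted_grid = h.VoxelGrid(grid64.shape, grid64.spacing,
                                   tuple(o + d for o, d in
                                         zip(grid64.origin, (9.6, -4.8, 14.4))))
        mov = h.VolumeImage(nema64.support.astype(float), shifted_grid)
        t = register_rigid(mov, ref)
        np.testing.assert_allclose(t.translation, (-9.6, 4.8, -14.4), atol=0.5)

    def test_rotation_recovery(self, nema64, grid64):
        angle = 6.0
        rot = ndimage.rotate(nema64.support.astype(float), angle,
                             axes=(0, 1), reshape=False, order=1)
        ref = h.VolumeImage(rot, grid64)
        mov = h.VolumeImage(nema64.support.astype(float), grid64)
        t = register_rigid(mov, ref, threshold=0.5)
        got_angle = np.degrees(np.arctan2(t.rotation[1, 0], t.rotation[0, 0]))
        assert abs(got_angle) == pytest.approx(angle, abs=1.5)
        # the transform must actually overlay the supports
        pts = np.argwhere(nema64.support).astype(float)
        pts_mm = pts * np.asarray(grid64.spacing) + np.asarray(grid64.origin)
        mapped = t.apply(pts_mm)
        idx = np.round((mapped - np.asarray(grid64.origin))
                       / np.asarray(grid64.spacing)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(grid64.shape)), axis=1)
        hits = rot[idx[ok, 0], idx[ok, 1], idx[ok, 2]] > 0.5
        assert hits.mean() > 0.9

    def test_cylinder_degeneracy_warns(self, cylinder64, grid64):
        img = h.VolumeImage(cylinder64.support.astype(float), grid64)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            t = register_rigid(img, img)
        np.testing.assert_allclose(t.rotation, np.eye(3))

    def test_empty_volume_rejected(self, grid64):
        img = h.VolumeImage(np.zeros(grid64.shape), grid64)
        with pytest.raises(ValueError):
            register_rigid(img, img)
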