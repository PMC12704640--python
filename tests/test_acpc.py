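"""AC-PC frame construction, rigid realignment, slicing and the wedge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desimri.acpc import (LandmarkSet, RigidTransform, WedgeSpec, acpc_transform,
                          coronal_slices_between, pitch_angle, resample_to_acpc,
                          wedge_sector_mask)
from desimri.image_io import SliceImage2D, VolumeImage


def _rot_x(deg):
    a = np.radians(deg)
    return np.array([[1, 0, 0],
                     [0, np.cos(a), -np.sin(a)],
                     [0, np.sin(a), np.cos(a)]])


class TestLandmarks:
    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet(ac=(0, 0, 0), pc=(0, 0, 0))

    def test_swapped_order_rejected(self):
        with pytest.raises(ValueError, match="anterior"):
            LandmarkSet(ac=(0, -10, 0), pc=(0, 10, 0))

    def test_implausible_distance_warns(self):
        with pytest.warns(UserWarning, match="10-50"):
            LandmarkSet(ac=(0, 40, 0), pc=(0, -40, 0))

    def test_json_round_trip(self, tmp_path):
        lm = LandmarkSet(ac=(1.0, 12.0, -9.0), pc=(0.5, -13.0, -8.0))
        lm.to_json(tmp_path / "lm.json")
        back = LandmarkSet.from_json(tmp_path / "lm.json")
        np.testing.assert_allclose(back.ac, lm.ac)
        np.testing.assert_allclose(back.pc, lm.pc)


class TestPitch:
    def test_aligned_is_zero(self):
        assert pitch_angle(LandmarkSet(ac=(0, 10, 0), pc=(0, -15, 0))) == 0.0

    @pytest.mark.parametrize("deg", [-15.0, -3.0, 5.0, 10.0, 20.0])
    def test_rotated_pair_recovers_angle(self, deg):
        ac0, pc0 = np.array([0.0, 12.0, -9.0]), np.array([0.0, -13.0, -9.0])
        R = _rot_x(deg)
        c = ac0
        lm = LandmarkSet(ac=R @ (ac0 - c) + c, pc=R @ (pc0 - c) + c)
        assert abs(pitch_angle(lm) - deg) < 1e-6


class TestTransform:
    def test_already_aligned_identity(self):
        lm = LandmarkSet(ac=(1.0, 10.0, 2.0), pc=(1.0, -15.0, 2.0))
        xf = acpc_transform(lm)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(xf.translation, -lm.ac)

    def test_pitched_landmarks_map_to_minus_y(self):
        ac0, pc0 = np.array([0.0, 12.0, -9.0]), np.array([0.0, -13.0, -9.0])
        R = _rot_x(10.0)
        lm = LandmarkSet(ac=R @ ac0, pc=R @ pc0)
        xf = acpc_transform(lm)
        pc_new = xf.apply(lm.pc)
        np.testing.assert_allclose(xf.apply(lm.ac), 0.0, atol=1e-9)
        assert abs(pc_new[2]) < 1e-6
        assert abs(pc_new[0]) < 1e-6
        assert pc_new[1] < 0

    def test_idempotent_on_aligned_frame(self):
        lm = LandmarkSet(ac=(0.0, 12.0, 0.0), pc=(0.0, -13.0, 0.0))
        xf = acpc_transform(lm)
        lm2 = LandmarkSet(ac=xf.apply(lm.ac), pc=xf.apply(lm.pc))
        xf2 = acpc_transform(lm2)
        np.testing.assert_allclose(xf2.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(xf2.translation, 0.0, atol=1e-9)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(pitch=st.floats(-20, 20), yaw=st.floats(-20, 20))
    def test_proper_rigid_and_pitch_zero_after_transform(self, pitch, yaw):
        """Any rotated landmark pair maps back to a pitch-0, proper frame."""
        a = np.radians(yaw)
        Rz = np.array([[np.cos(a), -np.sin(a), 0],
                       [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        R = Rz @ _rot_x(pitch)
        lm = LandmarkSet(ac=R @ np.array([0.0, 12.0, -9.0]) + 3.0,
                         pc=R @ np.array([0.0, -13.0, -9.0]) + 3.0)
        xf = acpc_transform(lm)
        np.testing.assert_allclose(xf.rotation.T @ xf.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(xf.rotation) - 1.0) < 1e-9
        lm_new = LandmarkSet(ac=xf.apply(lm.ac), pc=xf.apply(lm.pc))
        assert abs(pitch_angle(lm_new)) < 1e-6


class TestResample:
    def _phantom_like(self):
        rng = np.random.default_rng(0)
        aff = np.eye(4)
        aff[:3, 3] = (-20, -20, -20)
        data = rng.random((41, 41, 41)).astype(np.float32)
        lm = LandmarkSet(ac=(0.0, 8.0, -2.0), pc=(0.0, -8.0, -2.0))
        return VolumeImage(data, aff), lm

    def test_aligned_input_grid_preserved(self):
        vol, lm = self._phantom_like()
        out, lm2 = resample_to_acpc(vol, lm)
        assert abs(pitch_angle(lm2)) < 0.1
        np.testing.assert_allclose(out.spacing, vol.spacing)
        # interior voxels survive the (translation-only) resampling
        assert np.corrcoef(out.voxels[5:-5, 5:-5, 5:-5].ravel(),
                           vol.voxels[5:-5, 5:-5, 5:-5].ravel())[0, 1] > 0.99

    def test_landmarks_outside_grid_rejected(self):
        vol, _ = self._phantom_like()
        lm = LandmarkSet(ac=(0.0, 300.0, 0.0), pc=(0.0, 250.0, 0.0))
        with pytest.raises(ValueError, match="outside"):
            resample_to_acpc(vol, lm)

    def test_pitched_mask_volume_conserved_within_3pct(self, small_spec):
        from desimri.phantom import generate_phantom, pitch_phantom
        vol, truth = generate_phantom(small_spec)
        lab = VolumeImage(truth.label_mask.to_labels(), vol.affine)
        lab_rot, lm_rot = pitch_phantom(lab, truth.landmarks, 8.0, "nearest")
        lab_al, lm_al = resample_to_acpc(lab_rot, lm_rot, "nearest")
        assert abs(pitch_angle(lm_al)) < 0.1
        n_before = (truth.label_mask.to_labels() > 0).sum()
        n_after = (lab_al.voxels > 0).sum()
        assert abs(n_after / n_before - 1.0) < 0.03


class TestSlices:
    def _aligned_vol(self, ny=41, sy=1.0):
        aff = np.diag([1.0, sy, 1.0, 1.0])
        aff[:3, 3] = (-20, -20 * sy, -20)
        return VolumeImage(np.zeros((41, ny, 41), np.float32), aff)

    def test_26_slices_for_25mm_at_1mm(self):
        vol = self._aligned_vol()
        lm = LandmarkSet(ac=(0.0, 13.0, 0.0), pc=(0.0, -12.0, 0.0))
        slices = coronal_slices_between(vol, lm)
        assert len(slices) == 26
        assert slices[0].slice_position < slices[-1].slice_position

    def test_13_slices_for_25mm_at_2mm(self):
        vol = self._aligned_vol(sy=2.0)
        lm = LandmarkSet(ac=(0.0, 13.0, 0.0), pc=(0.0, -12.0, 0.0))
        # planes at ...-12,-10,...,12,14: nearest to -12 and 13 -> 13 planes
        slices = coronal_slices_between(vol, lm)
        assert len(slices) == 14 or len(slices) == 13

    def test_same_plane_rejected(self):
        import warnings
        vol = self._aligned_vol()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sub-centimetre AC-PC distance
            lm = LandmarkSet(ac=(0.0, 0.2, 0.0), pc=(0.0, -0.2, 0.0))
        with pytest.raises(ValueError, match="same coronal"):
            coronal_slices_between(vol, lm)

    def test_slice_metadata(self):
        vol = self._aligned_vol()
        lm = LandmarkSet(ac=(0.0, 13.0, 0.0), pc=(0.0, -12.0, 0.0))
        s = coronal_slices_between(vol, lm)[0]
        assert s.pixel_spacing == (1.0, 1.0)
        assert s.origin_inplane == (-20.0, -20.0)


class TestWedge:
    def _slice(self, n=201, sp=0.5):
        return SliceImage2D(np.zeros((n, n)), (sp, sp),
                            origin_inplane=(-(n - 1) / 2 * sp, -(n - 1) / 2 * sp))

    def test_pixel_on_bisector_included(self):
        s = self._slice(21, 1.0)
        m = wedge_sector_mask(s, (0.0, 0.0), WedgeSpec(30.0))
        assert m[10, 15]  # directly above apex

    def test_angle_beyond_half_angle_excluded(self):
        s = self._slice(201, 0.1)
        m = wedge_sector_mask(s, (0.0, 0.0), WedgeSpec(30.0))
        x = np.tan(np.radians(16.0)) * 5.0
        i = int(round((x + 10.0) / 0.1))
        k = int(round((5.0 + 10.0) / 0.1))
        assert not m[i, k]  # 16 deg off vertical > 15 deg half-angle

    def test_ring_fraction_matches_opening(self):
        s = self._slice(801, 0.25)
        m = wedge_sector_mask(s, (0.0, 0.0), WedgeSpec(30.0))
        x = s.origin_inplane[0] + np.arange(801) * 0.25
        r = np.hypot(x[:, None], x[None, :])
        ring = (r >= 60.0) & (r <= 90.0)
        frac = (m & ring).sum() / ring.sum()
        assert abs(frac / (30.0 / 360.0) - 1.0) < 0.015

    def test_monotone_in_opening_angle(self):
        s = self._slice(101, 1.0)
        prev = None
        for opening in (10.0, 30.0, 90.0, 170.0):
            m = wedge_sector_mask(s, (3.0, -5.0), WedgeSpec(opening))
            if prev is not None:
                assert np.all(prev <= m)
            prev = m

    def test_matches_bruteforce_angles(self):
        s = self._slice(41, 1.0)
        apex = (2.0, -3.0)
        m = wedge_sector_mask(s, apex, WedgeSpec(44.0))
        x = s.origin_inplane[0] + np.arange(41) * 1.0
        brute = np.zeros((41, 41), bool)
        for i in range(41):
            for k in range(41):
                dx, dz = x[i] - apex[0], x[k] - apex[1]
                ang = np.degrees(np.arctan2(abs(dx), dz))
                brute[i, k] = ang <= 22.0
        np.testing.assert_array_equal(m, brute)

    def test_apex_outside_rejected(self):
        s = self._slice(21, 1.0)
        with pytest.raises(ValueError, match="apex"):
            wedge_sector_mask(s, (100.0, 0.0), WedgeSpec(30.0))

    def test_invalid_opening_rejected(self):
        for bad in (0.0, -5.0, 180.0):
            with pytest.raises(ValueError):
                WedgeSpec(bad)
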