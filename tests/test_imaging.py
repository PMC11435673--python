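"""NIfTI round trips, SUV conversion and mask propagation."""

import nibabel as nib
import numpy as np
import pytest

from hypofrac import (
    EmptyMaskError,
    Role,
    RoiMask,
    ScanMeta,
    Units,
    VolumeImage,
    activity_to_suv,
    load_mask,
    load_volume,
    propagate_mask,
    save_mask,
    save_volume,
)


def make_volume(data, spacing=(1.0, 1.0, 1.0), units=Units.SUV):
    affine = np.diag([*spacing, 1.0])
    return VolumeImage(data=data, spacing=spacing, affine=affine, units=units)


class TestIO:
    def test_round_trip_is_voxel_exact_for_float32(self, tmp_path):
        rng = np.random.default_rng(0)
        v = make_volume(rng.normal(size=(9, 8, 7)).astype(np.float32), spacing=(2.8, 2.8, 2.8))
        p = tmp_path / "v.nii.gz"
        save_volume(v, p)
        v2 = load_volume(p)
        np.testing.assert_array_equal(v2.data, v.data)
        np.testing.assert_allclose(v2.affine, v.affine, atol=1e-6)
        assert v2.spacing == pytest.approx((2.8, 2.8, 2.8))

    def test_mask_round_trip(self, tmp_path):
        data = np.zeros((6, 6, 6), dtype=np.uint8)
        data[2:4, 2:4, 2:4] = 1
        m = RoiMask(data=data, role=Role.TUMOR, spacing=(1, 1, 2.5), affine=np.diag([1, 1, 2.5, 1]))
        save_mask(m, tmp_path / "m.nii.gz")
        m2 = load_mask(tmp_path / "m.nii.gz", Role.TUMOR)
        np.testing.assert_array_equal(m2.data, m.data)

    def test_overwrite_succeeds(self, tmp_path):
        v = make_volume(np.ones((4, 4, 4), dtype=np.float32))
        p = tmp_path / "v.nii.gz"
        save_volume(v, p)
        save_volume(v, p)
        assert load_volume(p).data.shape == (4, 4, 4)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope.nii.gz")

    def test_4d_file_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3), dtype=np.float32), np.eye(4))
        p = tmp_path / "v4.nii.gz"
        nib.save(img, str(p))
        with pytest.raises(ValueError, match="3D"):
            load_volume(p)

    def test_non_finite_voxels_rejected_with_count(self, tmp_path):
        data = np.zeros((4, 4, 4), dtype=np.float32)
        data[0, 0, :2] = np.nan
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "bad.nii.gz"))
        with pytest.raises(ValueError, match="2 non-finite"):
            load_volume(tmp_path / "bad.nii.gz")


class TestSuv:
    def test_known_conversion(self):
        # 2751.8 Bq/mL, 75 kg, 469 MBq decayed over 130 min -> SUV ~ 1.0
        meta = ScanMeta(injected_activity_mbq=469, injection_to_scan_min=130, body_weight_kg=75)
        v = make_volume(np.full((3, 3, 3), 2751.8), units=Units.BQ_PER_ML)
        out = activity_to_suv(v, meta)
        expected = 2751.8 * 75e3 / (469e6 * 2 ** (-130 / 109.77))
        assert out.units is Units.SUV
        np.testing.assert_allclose(out.data, expected)
        assert expected == pytest.approx(1.000, abs=1e-3)

    def test_zero_activity_maps_to_zero(self):
        meta = ScanMeta(469, 130, 75)
        v = make_volume(np.zeros((3, 3, 3)), units=Units.BQ_PER_ML)
        assert np.all(activity_to_suv(v, meta).data == 0)

    def test_linearity(self):
        meta = ScanMeta(400, 90, 80)
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 5000, (4, 4, 4))
        v1 = activity_to_suv(make_volume(c, units=Units.BQ_PER_ML), meta)
        v2 = activity_to_suv(make_volume(2 * c, units=Units.BQ_PER_ML), meta)
        np.testing.assert_allclose(v2.data, 2 * v1.data, rtol=1e-12)

    def test_rejects_suv_input(self):
        with pytest.raises(ValueError, match="Bq/mL"):
            activity_to_suv(make_volume(np.ones((2, 2, 2))), ScanMeta(469, 130, 75))

    @pytest.mark.parametrize("kwargs", [
        dict(injected_activity_mbq=0, injection_to_scan_min=130, body_weight_kg=75),
        dict(injected_activity_mbq=469, injection_to_scan_min=-1, body_weight_kg=75),
        dict(injected_activity_mbq=469, injection_to_scan_min=130, body_weight_kg=0),
    ])
    def test_meta_validation(self, kwargs):
        with pytest.raises(ValueError):
            ScanMeta(**kwargs)


class TestPropagate:
    def test_identity_on_same_grid(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[3:6, 3:6, 3:6] = True
        m = RoiMask(data=data, role=Role.TUMOR, spacing=(2, 2, 2), affine=np.diag([2, 2, 2, 1]))
        target = make_volume(np.zeros((8, 8, 8)), spacing=(2, 2, 2))
        out = propagate_mask(m, target)
        np.testing.assert_array_equal(out.data, m.data)

    def test_cube_volume_preserved_across_resolution(self):
        # 20 mm cube on an MR-like 0.625 mm grid, resampled to a 2.8 mm PET grid
        n = 64
        data = np.zeros((n, n, n), dtype=bool)
        data[10:42, 10:42, 10:42] = True  # 32 voxels * 0.625 mm = 20 mm
        sp = (0.625, 0.625, 0.625)
        m = RoiMask(data=data, role=Role.TUMOR, spacing=sp, affine=np.diag([*sp, 1]))
        target = make_volume(np.zeros((20, 20, 20)), spacing=(2.8, 2.8, 2.8))
        out = propagate_mask(m, target)
        vol = out.n_voxels * out.voxel_volume_mm3
        shell = 6 * 20.0 ** 2 * 2.8  # one voxel-thick surface shell of the cube
        assert abs(vol - 20.0 ** 3) <= shell

    def test_mask_outside_fov_is_error(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[0, 0, 0] = True
        affine = np.diag([1.0, 1, 1, 1])
        affine[:3, 3] = 500.0  # mask lives 500 mm away
        m = RoiMask(data=data, role=Role.BP, spacing=(1, 1, 1), affine=affine)
        target = make_volume(np.zeros((8, 8, 8)))
        with pytest.raises(EmptyMaskError):
            propagate_mask(m, target)
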