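"""Preprocessing contracts: windowing, resizing, splitting, overlays,
augmentation, and DICOM-series conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdaunet import (
    ConfigurationError,
    FormatError,
    InputError,
    ShapeError,
    WindowSpec,
    augment,
    dicom_series_to_nifti,
    overlay_contour,
    resize_to_grid,
    split_dataset,
    window_hu,
)
from rdaunet.preprocessing import boundary_pixels

WINDOW = WindowSpec(-100.0, 400.0)


class TestWindowHU:
    @pytest.mark.parametrize(
        "hu,expected", [(-200.0, 0.0), (400.0, 1.0), (150.0, 0.5), (-100.0, 0.0), (900.0, 1.0)]
    )
    def test_clamp_and_rescale(self, hu, expected):
        assert window_hu(np.array([[hu]]), WINDOW)[0, 0] == pytest.approx(expected)

    def test_invalid_window_rejected(self):
        with pytest.raises(ConfigurationError):
            WindowSpec(10.0, 10.0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(InputError):
            window_hu(np.array([[np.nan]]), WINDOW)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-2000, 2000), min_size=1, max_size=40))
    def test_output_in_unit_interval(self, values):
        out = window_hu(np.array(values), WINDOW)
        assert np.all((out >= 0.0) & (out <= 1.0))

    def test_idempotence(self, rng):
        """Clamping is idempotent, so windowing pre-clamped HU data changes
        nothing, and re-windowing [0,1] output with the unit window is the
        identity."""
        img = rng.uniform(-1500, 1500, size=(32, 32))
        once = window_hu(img, WINDOW)
        clamped = np.clip(img, WINDOW.hu_min, WINDOW.hu_max)
        np.testing.assert_allclose(window_hu(clamped, WINDOW), once)
        np.testing.assert_allclose(window_hu(once, WindowSpec(0.0, 1.0)), once)


class TestResize:
    def test_constant_image_stays_constant(self):
        out = resize_to_grid(np.full((512, 512), 0.3), 224)
        np.testing.assert_allclose(out, 0.3, atol=1e-6)
        assert out.shape == (224, 224)

    def test_mask_resize_preserves_binarity(self, rng):
        mask = (rng.random((512, 512)) < 0.3).astype(np.uint8)
        out = resize_to_grid(mask, 224, is_mask=True)
        assert set(np.unique(out)) <= {0, 1}

    def test_all_ones_mask(self):
        out = resize_to_grid(np.ones((512, 512), dtype=np.uint8), 224, is_mask=True)
        np.testing.assert_array_equal(out, 1)

    def test_non_square_rejected(self):
        with pytest.raises(ShapeError):
            resize_to_grid(np.zeros((64, 32)), 16)


class TestSplit:
    def test_eight_two_on_ten(self):
        split = split_dataset(list(range(10)), ratio=0.8, seed=0)
        assert len(split.train_ids) == 8 and len(split.val_ids) == 2

    def test_deterministic(self):
        a = split_dataset(list(range(30)), 0.8, seed=5)
        b = split_dataset(list(range(30)), 0.8, seed=5)
        assert a.train_ids == b.train_ids and a.val_ids == b.val_ids

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(2, 200),
        ratio=st.floats(0.05, 0.95),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_partition_property(self, n, ratio, seed):
        if not 1 <= round(ratio * n) <= n - 1:
            return
        ids = [f"s{i}" for i in range(n)]
        split = split_dataset(ids, ratio, seed)
        assert len(split.train_ids) == round(ratio * n)
        assert set(split.train_ids) | set(split.val_ids) == set(ids)
        assert not set(split.train_ids) & set(split.val_ids)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            split_dataset([], 0.8, 0)


class TestOverlay:
    def test_empty_mask_is_channel_replication(self, rng):
        img = rng.random((8, 8))
        out = overlay_contour(img, np.zeros((8, 8), dtype=np.uint8))
        np.testing.assert_array_equal(out, np.stack([img] * 3, axis=-1))

    def test_single_pixel_mask_colors_exactly_that_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 3] = 1
        out = overlay_contour(np.zeros((5, 5)), mask, color=(0.0, 1.0, 0.0))
        colored = np.argwhere((out != 0).any(axis=-1))
        np.testing.assert_array_equal(colored, [[2, 3]])

    def test_solid_square_colors_its_ring(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        out = overlay_contour(np.zeros((5, 5)), mask, color=(1.0, 0.0, 0.0))
        assert (out[..., 0] == 1.0).sum() == 8  # 3x3 square minus its center
        assert out[2, 2, 0] == 0.0

    def test_only_boundary_pixels_change(self, rng):
        img = rng.random((32, 32))
        mask = (rng.random((32, 32)) < 0.4).astype(np.uint8)
        out = overlay_contour(img, mask, color=(-1.0, -1.0, -1.0))
        changed = (out != np.stack([img] * 3, axis=-1)).any(axis=-1)
        np.testing.assert_array_equal(changed, boundary_pixels(mask))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            overlay_contour(np.zeros((4, 4)), np.zeros((5, 5)))


class TestAugment:
    def test_double_hflip_is_identity(self, phantom_sample):
        s = phantom_sample
        img, masks = augment(s.image, [s.liver_mask, s.lesion_mask], ["hflip"])
        img2, masks2 = augment(img, masks, ["hflip"])
        np.testing.assert_array_equal(img2, s.image)
        np.testing.assert_array_equal(masks2[0], s.liver_mask)

    def test_nesting_preserved_under_random_ops(self, phantom_sample):
        s = phantom_sample
        for seed in range(10):
            _, (liver, lesion) = augment(
                s.image, [s.liver_mask, s.lesion_mask], ["hflip", "vflip", "rot90"], seed=seed
            )
            assert not np.any(lesion & ~liver)
            assert set(np.unique(liver)) <= {0, 1}

    def test_rot90_matches_coordinate_remap_oracle(self):
        a = np.arange(12, dtype=float).reshape(3, 4)
        img, _ = augment(a, [], ["rot90:1"])
        h, w = a.shape
        expected = np.empty((w, h))
        for i in range(h):  # rot90: (i, j) -> (w-1-j, i)
            for j in range(w):
                expected[w - 1 - j, i] = a[i, j]
        np.testing.assert_array_equal(img, expected)

    def test_unknown_op_rejected(self):
        with pytest.raises(ConfigurationError):
            augment(np.zeros((4, 4)), [], ["sharpen"])


# ------------------------------------------------------------------- DICOM
def _write_series(dirpath, n_slices=3, shuffle=True, uid="1.2.3.4", with_position=True):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    rng = np.random.default_rng(0)
    order = [2, 0, 1] if shuffle else list(range(n_slices))
    arrays = []
    for k, z in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = uid
        ds.Modality = "CT"
        ds.Rows = ds.Columns = 8
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelSpacing = [0.7, 0.7]
        ds.SliceThickness = 2.5
        if with_position:
            ds.ImagePositionPatient = [0.0, 0.0, float(z) * 2.5]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        arr = rng.integers(0, 3000, size=(8, 8), dtype=np.uint16)
        if z == 0:
            arr[0, 0] = 1024  # stored 1024 with intercept -1024 -> 0 HU
        ds.PixelData = arr.tobytes()
        ds.save_as(str(dirpath / f"slice_{k}.dcm"), enforce_file_format=True)
        arrays.append((z, arr))
    return dict(arrays)


class TestDicom:
    def test_hu_rescale_and_slice_ordering(self, tmp_path):
        planes = _write_series(tmp_path, shuffle=True)
        vol = dicom_series_to_nifti(tmp_path)
        assert vol.voxels.shape == (3, 8, 8)
        # slices sorted by position regardless of file order
        for z in range(3):
            np.testing.assert_allclose(vol.voxels[z], planes[z].astype(float) - 1024.0)
        assert vol.voxels[0, 0, 0] == 0.0  # stored 1024, intercept -1024
        assert vol.spacing == (2.5, 0.7, 0.7)

    def test_nifti_roundtrip(self, tmp_path):
        import nibabel as nib

        _write_series(tmp_path)
        out = tmp_path / "vol.nii.gz"
        vol = dicom_series_to_nifti(tmp_path, out_path=out)
        img = nib.load(str(out))
        back = np.asarray(img.dataobj).transpose(2, 1, 0)
        np.testing.assert_allclose(back, vol.voxels)
        np.testing.assert_allclose(img.header.get_zooms(), (0.7, 0.7, 2.5))

    def test_mixed_series_rejected(self, tmp_path):
        _write_series(tmp_path, uid="1.1")
        (tmp_path / "extra").mkdir()
        _write_series(tmp_path / "extra", n_slices=1, uid="9.9", shuffle=False)
        (tmp_path / "extra" / "slice_0.dcm").rename(tmp_path / "slice_zz.dcm")
        with pytest.raises(FormatError, match="series"):
            dicom_series_to_nifti(tmp_path)

    def test_missing_position_identifies_file(self, tmp_path):
        _write_series(tmp_path, with_position=False)
        with pytest.raises(FormatError, match="slice_0"):
            dicom_series_to_nifti(tmp_path)
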