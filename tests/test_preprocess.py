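"""Volume I/O, plane extraction, canvas padding, and slice selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import patchunet as pu
from patchunet.errors import FormatError, ValidationError


def _slice(h, w, seed=0, labels=False):
    rng = np.random.default_rng(seed)
    return pu.SliceImage(
        pixels=rng.normal(size=(h, w)),
        labels=rng.integers(0, 4, size=(h, w)) if labels else None,
    )


class TestPadToCanvas:
    @pytest.mark.parametrize(
        "h,w,expected",
        [
            (208, 176, (24, 24, 40, 40)),  # OASIS axial geometry
            (128, 256, (64, 64, 0, 0)),  # IBSR axial geometry
            (256, 256, (0, 0, 0, 0)),
            (255, 254, (0, 1, 1, 1)),  # odd remainders go bottom/right
        ],
    )
    def test_pad_record(self, h, w, expected):
        padded = pu.pad_to_canvas(_slice(h, w), 256)
        assert padded.pad_record == expected
        assert padded.shape == (256, 256)

    def test_added_pixels_are_zero_and_center_preserved(self):
        s = _slice(208, 176, labels=True)
        padded = pu.pad_to_canvas(s, 256)
        assert np.array_equal(padded.pixels[24:232, 40:216], s.pixels)
        assert np.array_equal(padded.labels[24:232, 40:216], s.labels)
        assert padded.pixels.sum() == pytest.approx(s.pixels.sum())
        assert padded.labels.sum() == s.labels.sum()  # padding is background

    def test_oversized_slice_refused(self):
        with pytest.raises(ValidationError, match="exceeds canvas"):
            pu.pad_to_canvas(_slice(300, 100), 256)

    def test_unpad_requires_record(self):
        with pytest.raises(ValidationError, match="pad_record"):
            pu.unpad(_slice(16, 16))

    @given(
        h=st.integers(1, 64),
        w=st.integers(1, 64),
        seed=st.integers(0, 10_000),
    )
    def test_pad_unpad_round_trip(self, h, w, seed):
        s = _slice(h, w, seed=seed, labels=True)
        back = pu.unpad(pu.pad_to_canvas(s, 64))
        assert np.array_equal(back.pixels, s.pixels)
        assert np.array_equal(back.labels, s.labels)


class TestSliceSelection:
    def test_published_protocol_48_of_176_interval_3(self):
        idx = pu.select_training_slices(176, 48, 3)
        assert len(idx) == 48
        assert np.all(np.diff(idx) == 3)
        # centered window: start = floor((176 - 1 - 47*3) / 2)
        assert idx[0] == 17
        assert idx[-1] == 158

    def test_single_slice_is_the_middle(self):
        assert pu.select_training_slices(176, 1, 3) == [87]
        assert pu.select_training_slices(9, 1, 1) == [4]

    def test_exact_fit(self):
        assert pu.select_training_slices(10, 4, 3) == [0, 3, 6, 9]

    def test_infeasible_count_reports_feasible(self):
        with pytest.raises(ValidationError, match="at most"):
            pu.select_training_slices(10, 5, 3)

    @given(
        n=st.integers(2, 300),
        count=st.integers(1, 60),
        interval=st.integers(1, 5),
    )
    def test_length_and_span_invariants(self, n, count, interval):
        if (count - 1) * interval >= n:
            return
        idx = pu.select_training_slices(n, count, interval)
        assert len(idx) == count
        assert max(idx) - min(idx) == (count - 1) * interval
        assert 0 <= min(idx) and max(idx) < n


class TestPlaneExtraction:
    def test_toy_volume_axis_convention(self):
        vol = pu.Volume(
            intensities=np.arange(10 * 12 * 14, dtype=float).reshape(10, 12, 14),
            axis_names=("axial", "coronal", "sagittal"),
        )
        assert len(pu.extract_slices(vol, "axial")) == 10
        assert len(pu.extract_slices(vol, "coronal")) == 12
        assert len(pu.extract_slices(vol, "sagittal")) == 14
        assert pu.extract_slices(vol, "coronal")[3].shape == (10, 14)

    def test_restack_is_lossless(self, small_phantom_volume):
        for plane in ("axial", "coronal", "sagittal"):
            slices = pu.extract_slices(small_phantom_volume, plane)
            back = pu.restack_slices(slices, small_phantom_volume)
            assert np.array_equal(back.intensities, small_phantom_volume.intensities)
            assert np.array_equal(back.labels, small_phantom_volume.labels)

    def test_unknown_plane_rejected(self, small_phantom_volume):
        with pytest.raises(ValidationError, match="unknown plane"):
            pu.extract_slices(small_phantom_volume, "oblique")


class TestNormalization:
    def test_minmax_definition(self):
        vol = pu.Volume(intensities=np.array([[[10.0, 20.0], [15.0, 10.0]]]))
        out = pu.normalize_intensity(vol, "minmax")
        assert np.allclose(out.intensities, (vol.intensities - 10) / 10)

    def test_constant_volume_maps_to_zero(self):
        vol = pu.Volume(intensities=np.full((2, 3, 4), 7.0))
        for mode in ("minmax", "zscore"):
            assert np.all(pu.normalize_intensity(vol, mode).intensities == 0)

    def test_zscore_moments(self, small_phantom_volume):
        out = pu.normalize_intensity(small_phantom_volume, "zscore")
        assert abs(out.intensities.mean()) < 1e-6
        assert abs(out.intensities.std() - 1) < 1e-6

    def test_labels_untouched(self, small_phantom_volume):
        out = pu.normalize_intensity(small_phantom_volume, "minmax")
        assert np.array_equal(out.labels, small_phantom_volume.labels)


class TestVolumeIO:
    def test_save_load_round_trip(self, tmp_path, small_phantom_volume):
        img = tmp_path / "vol.nii.gz"
        lab = tmp_path / "vol_labels.nii.gz"
        pu.save_volume(small_phantom_volume, img, lab)
        loaded = pu.load_volume(img, lab)
        assert np.allclose(
            loaded.intensities, small_phantom_volume.intensities, atol=1e-6
        )
        assert np.array_equal(loaded.labels, small_phantom_volume.labels)
        assert set(np.unique(loaded.labels)) <= {0, 1, 2, 3}

    def test_oasis_geometry_axial_slicing(self, tmp_path):
        import nibabel as nib

        arr = np.random.default_rng(0).normal(size=(208, 176, 176)).astype(np.float32)
        path = tmp_path / "oasis_like.nii.gz"
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
        vol = pu.load_volume(path, axis_names=("coronal", "sagittal", "axial"))
        slices = pu.extract_slices(vol, "axial")
        assert len(slices) == 176
        assert slices[0].shape == (208, 176)

    def test_png_export_windows_intensity_range(self, tmp_path):
        import imageio.v3 as iio

        s = pu.SliceImage(pixels=np.linspace(-1, 1, 64).reshape(8, 8))
        path = tmp_path / "slice.png"
        pu.save_slice_png(s, path)
        img = iio.imread(path)
        assert img.shape == (8, 8)
        assert img.min() == 0 and img.max() == 255

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            pu.load_volume(tmp_path / "nope.nii.gz")

    def test_label_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="does not match"):
            pu.Volume(
                intensities=np.zeros((4, 4, 4)), labels=np.zeros((4, 4, 5), dtype=int)
            )

    def test_label_value_out_of_range_named(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[0, 0, 0] = 9
        with pytest.raises(ValidationError, match="9"):
            pu.Volume(intensities=np.zeros((2, 2, 2)), labels=labels)
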