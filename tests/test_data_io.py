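"""NIfTI handling, slicing, resizing, splitting, augmentation and noise."""

import numpy as np
import pytest

from feccnet.data_io import (
    AugmentConfig,
    SliceRecord,
    SplitConfig,
    add_gaussian_noise,
    augment,
    elastic_pair,
    extract_axial_slices,
    load_volume,
    manifest_checksum,
    read_slices,
    resize_record,
    rotate_pair,
    split_dataset,
    write_slices,
)
from feccnet.errors import ConfigurationError, DataFormatError, InputError


def _write_nifti(path, data):
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4)), str(path))


def _record(image, mask, case="c", idx=0):
    from feccnet.metrics import stratify_by_lesion_size

    return SliceRecord(image=np.asarray(image, float), mask=np.asarray(mask, np.uint8),
                       case_id=case, slice_index=idx,
                       stratum=stratify_by_lesion_size(mask))


class TestLoadVolume:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        data = rng.uniform(0, 100, (8, 8, 4))
        _write_nifti(tmp_path / "vol.nii", data)
        vol = load_volume(tmp_path / "vol.nii")
        np.testing.assert_array_equal(vol.data, data)
        assert vol.spacing == (1.0, 1.0, 1.0)

    def test_gzip_and_plain_load_identically(self, tmp_path, rng):
        data = rng.uniform(0, 100, (8, 8, 4))
        _write_nifti(tmp_path / "a.nii", data)
        _write_nifti(tmp_path / "b.nii.gz", data)
        np.testing.assert_array_equal(
            load_volume(tmp_path / "a.nii").data, load_volume(tmp_path / "b.nii.gz").data
        )

    def test_wrong_magic_bytes_raise_format_error(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"definitely not a nifti header")
        with pytest.raises(DataFormatError):
            load_volume(bad)


class TestExtractAxialSlices:
    def test_slice_count_equals_axial_extent(self, rng):
        from feccnet.data_io import Volume

        vol = Volume(rng.uniform(0, 1, (8, 8, 4)), (1, 1, 1), np.eye(4))
        msk = Volume((rng.uniform(size=(8, 8, 4)) > 0.8).astype(float), (1, 1, 1), np.eye(4))
        records = extract_axial_slices(vol, msk)
        assert len(records) == 4
        for rec in records:
            assert set(np.unique(rec.mask)).issubset({0, 1})
            assert rec.image.min() >= 0 and rec.image.max() <= 255

    def test_values_conserved_up_to_affine_rescale(self, rng):
        from feccnet.data_io import Volume

        data = rng.uniform(10, 20, (6, 6, 3))
        vol = Volume(data, (1, 1, 1), np.eye(4))
        msk = Volume(np.zeros_like(data), (1, 1, 1), np.eye(4))
        records = extract_axial_slices(vol, msk)
        lo, hi = data.min(), data.max()
        expected = (data[:, :, 1] - lo) * 255.0 / (hi - lo)
        np.testing.assert_allclose(records[1].image, expected)

    def test_shape_mismatch_rejected(self, rng):
        from feccnet.data_io import Volume

        vol = Volume(np.zeros((4, 4, 2)), (1, 1, 1), np.eye(4))
        msk = Volume(np.zeros((4, 4, 3)), (1, 1, 1), np.eye(4))
        with pytest.raises(InputError):
            extract_axial_slices(vol, msk)


class TestResize:
    def test_same_size_is_identity(self, rng):
        rec = _record(rng.uniform(0, 255, (16, 16)), rng.uniform(size=(16, 16)) > 0.8)
        out = resize_record(rec, 16)
        np.testing.assert_array_equal(out.mask, rec.mask)

    def test_mask_stays_binary_under_any_resize(self, rng):
        rec = _record(rng.uniform(0, 255, (20, 20)), rng.uniform(size=(20, 20)) > 0.7)
        for size in (13, 32, 64):
            out = resize_record(rec, size)
            assert set(np.unique(out.mask)).issubset({0, 1})
            assert out.image.shape == (size, size)

    def test_square_mask_upscales_exactly_under_nearest_neighbour(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[27:37, 27:37] = 1  # 10x10 = 100 px
        rec = _record(np.zeros((64, 64)), mask)
        out = resize_record(rec, 128)
        assert int(out.mask.sum()) == 400

    def test_invalid_size_rejected(self, rng):
        rec = _record(np.zeros((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ConfigurationError):
            resize_record(rec, 0)


class TestSplit:
    def _records(self, n_cases, slices_per_case=3):
        out = []
        for c in range(n_cases):
            for s in range(slices_per_case):
                out.append(_record(np.zeros((4, 4)), np.zeros((4, 4)),
                                   case=f"case{c}", idx=s))
        return out

    def test_ten_cases_split_8_1_1(self):
        tr, va, te = split_dataset(self._records(10), SplitConfig(seed=0))
        assert len({r.case_id for r in tr}) == 8
        assert len({r.case_id for r in va}) == 1
        assert len({r.case_id for r in te}) == 1

    def test_partition_is_disjoint_and_exhaustive(self):
        records = self._records(7)
        tr, va, te = split_dataset(records, SplitConfig(seed=3))
        ids = lambda part: {(r.case_id, r.slice_index) for r in part}
        assert ids(tr) | ids(va) | ids(te) == ids(records)
        assert not (ids(tr) & ids(va)) and not (ids(tr) & ids(te)) and not (ids(va) & ids(te))

    def test_case_unit_keeps_patients_together(self):
        tr, va, te = split_dataset(self._records(10), SplitConfig(seed=1))
        for part in (tr, va, te):
            for case in {r.case_id for r in part}:
                assert sum(r.case_id == case for r in part) == 3

    def test_same_seed_same_split_different_seed_differs(self):
        records = self._records(20)
        a = split_dataset(records, SplitConfig(seed=5))
        b = split_dataset(records, SplitConfig(seed=5))
        c = split_dataset(records, SplitConfig(seed=6))
        key = lambda parts: [sorted((r.case_id, r.slice_index) for r in p) for p in parts]
        assert key(a) == key(b)
        assert key(a) != key(c)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitConfig(ratios=(0.8, 0.1, 0.2))
        with pytest.raises(InputError):
            split_dataset([], SplitConfig())


class TestAugment:
    def test_zero_rotation_is_identity(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        msk = (rng.uniform(size=(32, 32)) > 0.8).astype(np.uint8)
        out_img, out_msk = rotate_pair(img, msk, 0.0)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_msk, msk)

    def test_elastic_applies_same_field_to_image_and_mask(self):
        rng_a = np.random.default_rng(9)
        mask = np.zeros((48, 48), dtype=np.uint8)
        mask[16:32, 16:32] = 1
        # feed the mask through the image path; identical field -> identical warp
        img_out, msk_out = elastic_pair(mask.astype(float), mask, rng_a)
        np.testing.assert_array_equal((img_out > 0.5).astype(np.uint8), msk_out)

    def test_elastic_roughly_preserves_blob_area(self):
        # ~1000 px disc; the default deformation changes area by < 20%
        ii, jj = np.mgrid[0:64, 0:64]
        mask = ((ii - 32) ** 2 + (jj - 32) ** 2 <= 18**2).astype(np.uint8)
        assert 950 < mask.sum() < 1050
        for seed in range(5):
            _, warped = elastic_pair(mask.astype(float), mask, np.random.default_rng(seed))
            assert abs(int(warped.sum()) - int(mask.sum())) < 0.2 * mask.sum()

    def test_augment_keeps_mask_binary_and_shapes(self, rng):
        rec = _record(rng.uniform(0, 255, (32, 32)), rng.uniform(size=(32, 32)) > 0.8)
        out = augment(rec, np.random.default_rng(4), AugmentConfig(p_each=1.0))
        assert out.image.shape == rec.image.shape
        assert set(np.unique(out.mask)).issubset({0, 1})


class TestGaussianNoise:
    def test_sigma_zero_is_identity(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        np.testing.assert_array_equal(add_gaussian_noise(img, 0.0, rng), img)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            add_gaussian_noise(np.zeros((4, 4)), -1.0, rng)

    def test_empirical_sd_matches_sigma_at_midgray(self, rng):
        img = np.full((512, 512), 128.0)
        noisy = add_gaussian_noise(img, 40.0, rng)
        sd = (noisy - img).std()
        assert abs(sd - 40.0) / 40.0 < 0.05

    def test_output_bounded(self, rng):
        noisy = add_gaussian_noise(np.full((64, 64), 250.0), 40.0, rng)
        assert noisy.min() >= 0.0 and noisy.max() <= 255.0


class TestPngLayout:
    def test_write_read_round_trip(self, tmp_path, rng):
        records = [
            _record(rng.uniform(0, 255, (16, 16)), rng.uniform(size=(16, 16)) > 0.8,
                    case=f"c{i}", idx=i)
            for i in range(3)
        ]
        write_slices(records, tmp_path)
        back = read_slices(tmp_path)
        assert len(back) == 3
        for orig, rt in zip(records, back):
            np.testing.assert_array_equal(rt.mask, orig.mask)
            assert np.abs(rt.image - orig.image).max() <= 0.5  # uint8 quantisation

    def test_manifest_checksum_stable(self, tmp_path, rng):
        records = [_record(rng.uniform(0, 255, (8, 8)), np.zeros((8, 8)))]
        write_slices(records, tmp_path / "a")
        write_slices(records, tmp_path / "b")
        assert manifest_checksum(tmp_path / "a" / "manifest.csv") == manifest_checksum(
            tmp_path / "b" / "manifest.csv"
        )
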