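"""Preprocessing: foreground cropping, percentile normalisation, slicing,
patching and patient-level cohort splits."""

import numpy as np
import pytest

from spixseg.data import (
    MultimodalVolume,
    center_patch,
    clip_and_normalize,
    crop_to_foreground,
    load_slices,
    random_patch,
    read_nifti_volume,
    save_slices,
    split_cohorts,
    volume_to_slices,
)


def _volume(channels, mask=None):
    return MultimodalVolume(channels=channels, reference_mask=mask, patient_id="p0")


class TestCropToForeground:
    def test_already_tight_is_identity(self, rng):
        ch = (rng.random((4, 5, 6, 7)) + 0.1).astype(np.float32)  # all positive
        out = crop_to_foreground(_volume(ch))
        np.testing.assert_array_equal(out.channels, ch)

    def test_block_crop_matches_enumerated_bbox(self):
        ch = np.zeros((4, 10, 10, 10))
        ch[:, 2:5, 3:6, 4:7] = 1.0
        out = crop_to_foreground(_volume(ch))
        assert out.channels.shape == (4, 3, 3, 3)

    def test_union_over_channels(self):
        ch = np.zeros((4, 10, 10, 10))
        ch[2, 1:9, 2:4, 5:6] = 1.0  # only channel 2 non-zero
        out = crop_to_foreground(_volume(ch))
        assert out.channels.shape == (4, 8, 2, 1)

    def test_mask_cropped_identically(self):
        ch = np.zeros((4, 8, 8, 8))
        ch[:, 2:6, 2:6, 2:6] = 1.0
        mask = np.zeros((8, 8, 8))
        mask[3, 3, 3] = 1
        out = crop_to_foreground(_volume(ch, mask))
        assert out.reference_mask.shape == (4, 4, 4)
        assert out.reference_mask[1, 1, 1] == 1

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="no foreground"):
            crop_to_foreground(_volume(np.zeros((4, 3, 3, 3))))


class TestClipAndNormalize:
    def test_uniform_levels_map_to_unit_range(self):
        # non-zeros uniform on {1..100}: p1/p99 computed on non-zeros, then
        # the whole channel min-max scales to [0, 1]
        ch = np.zeros((4, 10, 10, 2))
        vals = np.arange(1, 101, dtype=float)
        for c in range(4):
            ch[c, :, :, 0] = vals.reshape(10, 10)
        out = clip_and_normalize(_volume(ch)).channels
        lo, hi = np.percentile(vals, [1, 99])
        expect = (np.clip(vals, lo, hi) - 0) / np.clip(vals, lo, hi).max()
        np.testing.assert_allclose(
            np.sort(np.unique(out[0, :, :, 0])), np.sort(np.unique(expect)),
            atol=1e-6,
        )
        assert out[0, :, :, 1].max() == 0  # background stays zero

    def test_channel_in_unit_range_nearly_unchanged(self, rng):
        ch = np.zeros((4, 8, 8, 4))
        body = rng.uniform(0.01, 1.0, size=(8, 8, 4))
        ch[:] = body
        out = clip_and_normalize(_volume(ch)).channels
        # inner 98% of mass only rescaled by the clipped extremes
        assert np.corrcoef(out[0].ravel(), ch[0].ravel())[0, 1] > 0.999

    def test_all_zero_channel_warns_and_stays_zero(self):
        ch = np.zeros((4, 6, 6, 3))
        ch[:3] = 1.0 + np.arange(324).reshape(3, 6, 6, 3) % 7
        with pytest.warns(UserWarning, match="channel 3"):
            out = clip_and_normalize(_volume(ch)).channels
        assert out[3].max() == 0

    def test_idempotence(self, rng):
        ch = np.zeros((4, 8, 8, 4))
        ch[:, 1:7, 1:7, :] = rng.uniform(10, 200, size=(4, 6, 6, 4))
        once = clip_and_normalize(_volume(ch))
        twice = clip_and_normalize(once)
        np.testing.assert_allclose(twice.channels, once.channels, atol=0.05)


class TestVolumeToSlices:
    def test_drop_rule_counts(self):
        ch = np.random.default_rng(0).random((4, 6, 6, 100))
        slices = volume_to_slices(_volume(ch), drop_slices=30)
        assert len(slices) == 40
        assert slices[0].slice_index == 30

    def test_empty_mask_gives_label_zero(self):
        ch = np.random.default_rng(0).random((4, 6, 6, 10))
        mask = np.zeros((6, 6, 10))
        mask[2:4, 2:4, 7] = 1
        slices = volume_to_slices(_volume(ch, mask), drop_slices=2)
        labels = {s.slice_index: s.label for s in slices}
        assert labels[7] == 1
        assert all(v == 0 for z, v in labels.items() if z != 7)

    def test_drop_zero_returns_all(self):
        ch = np.random.default_rng(0).random((4, 6, 6, 5))
        assert len(volume_to_slices(_volume(ch), drop_slices=0)) == 5

    def test_too_shallow_errors(self):
        ch = np.ones((4, 6, 6, 60))
        with pytest.raises(ValueError, match="60"):
            volume_to_slices(_volume(ch), drop_slices=30)


class TestPatching:
    def test_identity_at_target_size(self, tiny_phantom_train):
        s = tiny_phantom_train[0]
        out = random_patch(s, size=16, rng_seed=0)
        np.testing.assert_array_equal(out.pixels, s.pixels)

    def test_deterministic_window(self, rng):
        from spixseg.data import MultimodalSlice

        s = MultimodalSlice(pixels=rng.random((4, 24, 24)), label=1)
        a = random_patch(s, size=16, rng_seed=5)
        b = random_patch(s, size=16, rng_seed=5)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_mask_shares_offsets_with_pixels(self, rng):
        from spixseg.data import MultimodalSlice

        pix = rng.random((4, 24, 24))
        mask = np.zeros((24, 24))
        mask[10, 12] = 1
        pix[0, 10, 12] = 7.0  # marker pixel
        s = MultimodalSlice(pixels=pix, label=1, reference_mask=mask)
        out = random_patch(s, size=16, rng_seed=2)
        my, mx = np.argwhere(out.reference_mask)[0]
        assert out.pixels[0, my, mx] == 7.0

    def test_small_input_zero_padded(self, rng):
        from spixseg.data import MultimodalSlice

        s = MultimodalSlice(pixels=rng.random((4, 10, 10)), label=0)
        out = center_patch(s, size=16)
        assert out.shape == (16, 16)
        assert out.pixels[:, 0, 0].max() == 0


class TestSplitCohorts:
    def test_reference_cohort_sizes(self):
        train, val, test = split_cohorts([f"p{i}" for i in range(369)])
        assert (len(train), len(val), len(test)) == (295, 37, 37)

    def test_ten_patients_floor_rule(self):
        train, val, test = split_cohorts([f"p{i}" for i in range(10)])
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_disjoint_cover_and_determinism(self):
        ids = [f"p{i}" for i in range(37)]
        a = split_cohorts(ids, rng_seed=4)
        b = split_cohorts(ids, rng_seed=4)
        assert a == b
        combined = sum(map(list, a), [])
        assert sorted(combined) == sorted(ids)
        assert not (set(a[0]) & set(a[1])) and not (set(a[0]) & set(a[2]))

    def test_bad_fractions_error(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_cohorts(["a", "b"], fractions=(0.5, 0.2, 0.2))


def test_slice_dataset_roundtrip(tmp_path, tiny_phantom_train):
    save_slices(tiny_phantom_train, tmp_path / "ds")
    loaded = load_slices(tmp_path / "ds")
    assert len(loaded) == len(tiny_phantom_train)
    np.testing.assert_array_equal(loaded[3].pixels, tiny_phantom_train[3].pixels)
    assert loaded[3].label == tiny_phantom_train[3].label


def test_nifti_reader_roundtrip(tmp_path, rng):
    import nibabel as nib

    paths = {}
    arrays = {}
    for key in ("t1", "t1ce", "t2", "flair"):
        arr = rng.random((5, 6, 7)).astype(np.float32)
        p = tmp_path / f"{key}.nii.gz"
        nib.save(nib.Nifti1Image(arr, np.eye(4)), p)
        paths[key], arrays[key] = p, arr
    vol = read_nifti_volume(paths, patient_id="p1")
    assert vol.channels.shape == (4, 5, 6, 7)
    np.testing.assert_allclose(vol.channels[3], arrays["flair"], atol=1e-6)
    with pytest.raises(KeyError, match="t2"):
        read_nifti_volume({k: v for k, v in paths.items() if k != "t2"})
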