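import numpy as np
import pytest

from mrinorm import Volume3D
from mrinorm.radiomics import (ExtractionConfig, discretize, extract_features,
                               CLASS_COUNTS, TEXTURE_CLASSES, INTENSITY_CLASSES)
from mrinorm.texture import (cooccurrence_matrix, merged_cooccurrence,
                             glcm_features, run_length_matrix, size_zone_matrix,
                             dependence_matrix, gray_tone_difference,
                             ngtdm_features, DIRECTIONS_3D)
from mrinorm.dist_stats import masked_moments


def vol3(arr):
    return Volume3D(np.asarray(arr, dtype=np.float64))


class TestDiscretize:
    def test_two_bin_rule(self):
        v = vol3(np.linspace(0, 1, 8).reshape(2, 2, 2))
        mask = np.ones((2, 2, 2), dtype=np.uint8)
        lv = discretize(v, mask, 2)
        expected = np.where(v.data < 0.5, 1, 2)
        np.testing.assert_array_equal(lv, expected)
        assert lv.max() == 2

    def test_single_bin(self, rng):
        v = vol3(rng.random((3, 3, 3)))
        lv = discretize(v, np.ones((3, 3, 3), np.uint8), 1)
        assert np.all(lv == 1)

    def test_histogram_matches_brute_force(self, rng):
        v = vol3(rng.random((6, 6, 6)) * 40)
        mask = (rng.random((6, 6, 6)) > 0.3).astype(np.uint8)
        n_bins = 7
        lv = discretize(v, mask, n_bins)
        vals = v.data[mask > 0]
        lo, hi = vals.min(), vals.max()
        brute = np.zeros(n_bins, dtype=int)
        for x in vals:
            b = min(int(n_bins * (x - lo) / (hi - lo)), n_bins - 1)
            brute[b] += 1
        got = np.bincount(lv[mask > 0], minlength=n_bins + 1)[1:]
        np.testing.assert_array_equal(got, brute)
        assert lv[v.data == lo].min() == 1 and lv[v.data == hi].max() == n_bins

    def test_constant_region_errors(self):
        v = vol3(np.full((3, 3, 3), 2.0))
        with pytest.raises(ValueError, match="constant"):
            discretize(v, np.ones((3, 3, 3), np.uint8), 4)


class TestCooccurrence:
    def test_2x2_slice_worked_example(self):
        levels = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        P = cooccurrence_matrix(levels, 2, (0, 1, 0), symmetric=True)
        np.testing.assert_allclose(P, [[0.5, 0.25], [0.25, 0.0]])
        f = glcm_features(P)
        assert f["contrast"] == pytest.approx(0.5)

    def test_single_level_image(self):
        levels = np.ones((3, 3, 1), dtype=np.int64)
        P = cooccurrence_matrix(levels, 1, (1, 0, 0))
        assert P[0, 0] == 1.0
        f = glcm_features(P)
        assert f["angular_second_moment"] == 1.0
        assert f["contrast"] == 0.0
        assert np.isnan(f["correlation"])

    def test_probabilities_sum_to_one(self, rng):
        levels = rng.integers(1, 5, size=(5, 5, 5))
        for off in [(1, 0, 0), (0, 1, 1), (1, -1, 1)]:
            P = cooccurrence_matrix(levels, 4, off)
            assert P.sum() == pytest.approx(1.0)

    def test_exhaustive_pair_enumeration_oracle(self, rng):
        """Count ordered pairs voxel-by-voxel on small arrays and compare."""
        for trial in range(5):
            shape = (4, 4, 4)
            levels = rng.integers(0, 4, size=shape)  # 0 = outside mask
            off = tuple(rng.choice([-1, 0, 1], size=3))
            if off == (0, 0, 0):
                off = (1, 0, 0)
            counts = np.zeros((3, 3))
            for x in range(4):
                for y in range(4):
                    for z in range(4):
                        xx, yy, zz = x + off[0], y + off[1], z + off[2]
                        if not (0 <= xx < 4 and 0 <= yy < 4 and 0 <= zz < 4):
                            continue
                        a, b = levels[x, y, z], levels[xx, yy, zz]
                        if a > 0 and b > 0:
                            counts[a - 1, b - 1] += 1
            counts = counts + counts.T
            if counts.sum() == 0:
                continue
            P = cooccurrence_matrix(levels, 3, off, symmetric=True)
            np.testing.assert_allclose(P, counts / counts.sum(), atol=1e-14)

    def test_no_valid_pairs_errors(self):
        levels = np.zeros((3, 3, 3), dtype=np.int64)
        levels[0, 0, 0] = 1
        with pytest.raises(ValueError, match="no valid"):
            cooccurrence_matrix(levels, 1, (1, 0, 0))


class TestRunAndZoneMatrices:
    def test_1d_run_example(self):
        levels = np.array([1, 1, 1, 2]).reshape(4, 1, 1)
        M = run_length_matrix(levels, 2, [(1, 0, 0)])
        # one run of level 1 length 3, one run of level 2 length 1
        assert M[0, 2] == 1 and M[1, 0] == 1
        assert M.sum() == 2

    def test_runs_broken_by_mask_gaps(self):
        levels = np.array([1, 1, 0, 1]).reshape(4, 1, 1)
        M = run_length_matrix(levels, 1, [(1, 0, 0)])
        assert M[0, 1] == 1 and M[0, 0] == 1

    def test_single_zone_of_7_voxels(self):
        levels = np.zeros((5, 5, 5), dtype=np.int64)
        # 26-connected blob of 7 voxels at level 3
        for p in [(1, 1, 1), (1, 1, 2), (2, 2, 2), (2, 1, 1), (3, 3, 3),
                  (1, 2, 1), (2, 2, 1)]:
            levels[p] = 3
        from scipy import ndimage
        lab, n = ndimage.label(levels == 3, structure=np.ones((3, 3, 3)))
        assert n == 1  # oracle: connected-component labeling finds one zone
        M = size_zone_matrix(levels, 3)
        assert M[2, 6] == 1.0
        assert M.sum() == 1.0

    def test_dependence_counts_constant_block(self):
        levels = np.zeros((4, 4, 4), dtype=np.int64)
        levels[1:3, 1:3, 1:3] = 2
        S = dependence_matrix(levels, 2)
        # every voxel of a 2x2x2 constant block has 7 same-level neighbours
        assert S[1, 7] == 8
        assert S.sum() == 8

    def test_ngtdm_constant_region_undefined(self):
        levels = np.zeros((4, 4, 4), dtype=np.int64)
        levels[1:3, 1:3, 1:3] = 1
        s, n = gray_tone_difference(levels, 1)
        assert s.sum() == 0.0
        f = ngtdm_features(s, n)
        assert np.isnan(f["coarseness"])


@pytest.fixture(scope="module")
def random_case():
    rng = np.random.default_rng(3)
    vol = Volume3D(rng.random((12, 12, 12)) * 50)
    mask = np.zeros((12, 12, 12), dtype=np.uint8)
    mask[3:10, 2:10, 3:9] = 1
    return vol, mask


class TestExtractFeatures:
    def test_count_conservation(self, random_case):
        vol, mask = random_case
        fv = extract_features(vol, mask, ExtractionConfig(n_bins=8))
        assert len(fv.features) == 197
        assert fv.class_counts() == CLASS_COUNTS
        assert fv.n_texture() == 136
        assert fv.n_intensity() == 61

    def test_constant_region_preserves_count_with_flags(self):
        vol = Volume3D(np.full((8, 8, 8), 4.0))
        mask = np.zeros((8, 8, 8), dtype=np.uint8)
        mask[2:6, 2:6, 2:6] = 1
        fv = extract_features(vol, mask)
        assert len(fv.features) == 197
        assert fv.features["stat_variance"] == 0.0
        assert fv.features["glcm_3D_angular_second_moment"] == pytest.approx(1.0)
        assert "ngtdm_coarseness" in fv.undefined
        assert all(not np.isfinite(fv.features[k]) for k in fv.undefined)

    def test_shift_invariance_of_texture_features(self, random_case):
        """Fixed-bin-number discretization makes matrix features invariant to
        adding a constant to the volume."""
        vol, mask = random_case
        cfg = ExtractionConfig(n_bins=8)
        f0 = extract_features(vol, mask, cfg)
        f1 = extract_features(vol.with_data(vol.data + 123.0), mask, cfg)
        for name, v in f0.features.items():
            cls = f0.class_of[name]
            if cls in TEXTURE_CLASSES or cls == "IntensityHistogram":
                assert f1.features[name] == pytest.approx(v, rel=1e-9), name

    def test_intensity_stats_agree_with_dist_stats(self, random_case):
        vol, mask = random_case
        fv = extract_features(vol, mask, ExtractionConfig(n_bins=8))
        s = masked_moments(vol, mask)
        assert fv.features["stat_mean"] == pytest.approx(s.mean, rel=1e-12)
        assert fv.features["stat_variance"] == pytest.approx(s.variance, rel=1e-12)
        assert fv.features["stat_skewness"] == pytest.approx(s.skewness, rel=1e-12)
        assert fv.features["stat_kurtosis"] == pytest.approx(s.kurtosis, rel=1e-12)

    def test_closed_form_intensity_oracles(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 8.0, 8.0, 10.0])
        vol = Volume3D(vals.reshape(2, 2, 2))
        mask = np.ones((2, 2, 2), dtype=np.uint8)
        fv = extract_features(vol, mask, ExtractionConfig(n_bins=4))
        f = fv.features
        assert f["stat_mean"] == pytest.approx(vals.mean(), abs=1e-8)
        assert f["stat_minimum"] == 1.0 and f["stat_maximum"] == 10.0
        assert f["stat_range"] == 9.0
        assert f["stat_energy"] == pytest.approx(np.sum(vals ** 2), abs=1e-8)
        assert f["stat_root_mean_square"] == pytest.approx(
            np.sqrt(np.mean(vals ** 2)), abs=1e-8)
        assert f["stat_median"] == pytest.approx(np.median(vals), abs=1e-8)
        assert f["stat_mean_absolute_deviation"] == pytest.approx(
            np.mean(np.abs(vals - vals.mean())), abs=1e-8)
        assert f["stat_interquartile_range"] == pytest.approx(
            np.percentile(vals, 75) - np.percentile(vals, 25), abs=1e-8)
        assert f["stat_coefficient_of_variation"] == pytest.approx(
            vals.std(ddof=1) / vals.mean(), abs=1e-8)
        # IVH: half the voxels are >= the median-ish threshold
        assert f["ivh_intensity_at_volume_50"] == pytest.approx(
            np.percentile(vals, 50), abs=1e-8)
        assert 0.0 <= f["ivh_volume_fraction_at_intensity_90"] <= 1.0

    def test_rotation_invariance_of_3d_merged_glcm(self, random_case):
        vol, mask = random_case
        cfg = ExtractionConfig(n_bins=6)
        lv = discretize(vol, mask, 6)
        P0 = merged_cooccurrence(lv, 6, DIRECTIONS_3D)
        lv_rot = np.rot90(lv, k=1, axes=(0, 1))
        P1 = merged_cooccurrence(lv_rot, 6, DIRECTIONS_3D)
        f0, f1 = glcm_features(P0), glcm_features(P1)
        for k, v in f0.items():
            if np.isfinite(v):
                assert f1[k] == pytest.approx(v, rel=1e-10), k

    def test_local_intensity_peak_on_known_hotspot(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 100.0
        vol = Volume3D(data, spacing_mm=(2.0, 2.0, 2.0))
        mask = np.ones((15, 15, 15), dtype=np.uint8)
        fv = extract_features(vol, mask, ExtractionConfig(n_bins=4))
        # sphere of radius 6.2 mm at 2 mm spacing: mean = 100 / n_kernel_voxels
        from mrinorm.radiomics import _sphere_kernel
        nk = _sphere_kernel(6.2035, (2.0, 2.0, 2.0)).sum()
        assert fv.features["li_local_intensity_peak"] == pytest.approx(100.0 / nk, rel=1e-6)
        assert fv.features["li_global_intensity_peak"] == pytest.approx(100.0 / nk, rel=1e-6)

    def test_empty_mask_errors(self, random_case):
        vol, _ = random_case
        with pytest.raises(ValueError, match="empty"):
            extract_features(vol, np.zeros(vol.shape, dtype=np.uint8))
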