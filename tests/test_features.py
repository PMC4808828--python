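import numpy as np
import pandas as pd
import pytest

from nodulecad import features as feat
from nodulecad.candidate_segmentation import Candidate, blob_scores
from nodulecad.volume_io import CTVolume


def make_candidate(voxels, spacing=(1.0, 1.0, 1.0)):
    voxels = np.asarray(voxels)
    sphericity, width = blob_scores(voxels, spacing)
    extent = voxels.max(axis=0) - voxels.min(axis=0)
    edges = tuple((extent + 1) * np.asarray(spacing, dtype=float))
    centroid = tuple(voxels.mean(axis=0) * np.asarray(spacing, dtype=float))
    return Candidate(0, voxels, edges, centroid, sphericity, width,
                     len(voxels) * float(np.prod(spacing)))


def lattice_disk(radius, z=0):
    pts = [(z, y, x) for y in range(-radius - 1, radius + 2)
           for x in range(-radius - 1, radius + 2)
           if y * y + x * x <= radius * radius]
    arr = np.asarray(pts)
    return arr - arr.min(axis=0)


class TestArea:
    def test_single_voxel(self):
        assert feat.area_d1(make_candidate([[0, 0, 0]])) == 1

    def test_lattice_disk_radius_10(self):
        disk = lattice_disk(10)
        assert len(disk) == 317  # Gauss circle count for r=10
        assert feat.area_d1(make_candidate(disk)) == 317

    def test_square(self):
        sq = [(0, y, x) for y in range(5) for x in range(5)]
        assert feat.area_d1(make_candidate(sq)) == 25

    def test_uses_largest_cross_section(self):
        voxels = [(0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 0)]
        assert feat.area_d1(make_candidate(voxels)) == 3


class TestCircularity:
    def test_single_pixel(self):
        assert feat.circularity_d2(make_candidate([[0, 0, 0]])) \
            == pytest.approx(1 / np.pi)

    def test_lattice_disk_radius_10(self):
        d2 = feat.circularity_d2(make_candidate(lattice_disk(10)))
        assert d2 == pytest.approx(317 / (np.pi * 21 ** 2), abs=1e-9)

    def test_pixel_line(self):
        line = [(0, 0, x) for x in range(25)]
        d2 = feat.circularity_d2(make_candidate(line))
        assert d2 == pytest.approx(25 / (np.pi * 625), abs=1e-9)


class TestIntensityStats:
    def volume_with(self, values):
        data = np.zeros((1, 1, len(values)))
        data[0, 0] = values
        return CTVolume(data, (1, 1, 1), intensity_scale="normalized8bit")

    def test_three_voxel_example(self):
        v = self.volume_with([10.0, 20.0, 30.0])
        c = make_candidate([(0, 0, 0), (0, 0, 1), (0, 0, 2)])
        d3, d4, d8 = feat.intensity_stats(c, v)
        assert (d3, d8) == (20.0, 60.0)
        assert d4 == pytest.approx(200 / 3)

    def test_constant_region_zero_variance(self):
        v = self.volume_with([7.0, 7.0, 7.0])
        c = make_candidate([(0, 0, 0), (0, 0, 1), (0, 0, 2)])
        assert feat.intensity_stats(c, v)[1] == 0.0

    def test_out_of_bounds_rejected(self):
        v = self.volume_with([1.0, 2.0])
        with pytest.raises(feat.FeatureError, match="bounds"):
            feat.intensity_stats(make_candidate([(0, 0, 5)]), v)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 255, size=40)
        v = self.volume_with(values)
        c = make_candidate([(0, 0, i) for i in range(40)])
        d3, d4, d8 = feat.intensity_stats(c, v)
        assert d3 == pytest.approx(sum(values) / 40, abs=1e-9)
        assert d8 == pytest.approx(sum(values), abs=1e-9)
        assert d4 == pytest.approx(
            sum((x - sum(values) / 40) ** 2 for x in values) / 40, abs=1e-9)


class TestMomentRatios:
    def test_symmetric_sample_zero_skewness(self):
        assert feat.skewness_d5([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_worked_sample(self):
        sample = [1, 2, 3, 4, 10]
        assert feat.skewness_d5(sample) == pytest.approx(36 / 10 ** 1.5, abs=1e-9)
        assert feat.kurtosis_d6(sample) == pytest.approx(2.788, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(feat.FeatureError, match="moment ratio"):
            feat.kurtosis_d6([5, 5, 5])

    def test_normal_sample_kurtosis_three(self):
        rng = np.random.default_rng(0)
        assert feat.kurtosis_d6(rng.standard_normal(10 ** 6)) \
            == pytest.approx(3.0, abs=0.05)

    def test_uniform_sample_kurtosis_nine_fifths(self):
        rng = np.random.default_rng(0)
        assert feat.kurtosis_d6(rng.uniform(size=10 ** 6)) \
            == pytest.approx(1.8, abs=0.02)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 255, size=200)
        for op in (feat.skewness_d5, feat.kurtosis_d6):
            assert op(3.2 * x + 17) == pytest.approx(op(x), abs=1e-9)


class TestVolumeBox:
    def test_single_voxel(self):
        c = make_candidate([[0, 0, 0]], spacing=(2.5, 0.7, 0.7))
        assert feat.volume_box_d7(c) == pytest.approx(2.5 * 0.7 * 0.7)

    def test_isotropic_cube(self):
        cube = [(z, y, x) for z in range(3) for y in range(3) for x in range(3)]
        assert feat.volume_box_d7(make_candidate(cube)) == pytest.approx(27.0)

    def test_digitized_sphere_matches_extent_product(self):
        spacing = np.array([2.5, 0.7, 0.7])
        zz, yy, xx = np.indices((9, 21, 21))
        mm = (np.stack([zz, yy, xx], axis=-1) - [4, 10, 10]) * spacing
        voxels = np.argwhere((mm ** 2).sum(axis=-1) <= 9.0)
        c = make_candidate(voxels, spacing=tuple(spacing))
        extent = voxels.max(axis=0) - voxels.min(axis=0)
        assert feat.volume_box_d7(c) == pytest.approx(
            float(np.prod((extent + 1) * spacing)))


class TestFeatureMatrix:
    def test_empty_candidates(self):
        v = CTVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        m = feat.feature_matrix([], v)
        assert m.shape == (0, 8)
        assert list(m.columns) == feat.FEATURE_NAMES

    def test_rows_match_individual_ops(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 255, size=(8, 12, 12))
        v = CTVolume(data, (1, 1, 1), intensity_scale="normalized8bit")
        zz, yy, xx = np.indices((8, 12, 12))
        voxels = np.argwhere((zz - 4) ** 2 + (yy - 6) ** 2 + (xx - 6) ** 2 <= 9)
        c = make_candidate(voxels)
        m = feat.feature_matrix([c, c], v)
        assert m.shape == (2, 8) and not m.isna().any().any()
        assert m.iloc[0]["d1_area"] == feat.area_d1(c)
        assert m.iloc[0]["d2_circularity"] == feat.circularity_d2(c)
        assert m.iloc[0]["d7_volume_box"] == feat.volume_box_d7(c)

    def test_voxel_order_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(0, 255, size=(6, 10, 10))
        v = CTVolume(data, (1, 1, 1), intensity_scale="normalized8bit")
        voxels = np.argwhere(rng.random((6, 10, 10)) < 0.2)
        shuffled = voxels[rng.permutation(len(voxels))]
        m1 = feat.feature_matrix([make_candidate(voxels)], v)
        m2 = feat.feature_matrix([make_candidate(shuffled)], v)
        pd.testing.assert_frame_equal(m1, m2)

    def test_intensity_scaling_behaviour(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(10, 200, size=(6, 10, 10))
        voxels = np.argwhere(rng.random((6, 10, 10)) < 0.3)
        c = make_candidate(voxels)
        v1 = CTVolume(data, (1, 1, 1), intensity_scale="normalized8bit")
        v2 = CTVolume(2.0 * data, (1, 1, 1), intensity_scale="normalized8bit")
        m1, m2 = feat.feature_matrix([c], v1), feat.feature_matrix([c], v2)
        for geom in ("d1_area", "d2_circularity", "d7_volume_box"):
            assert m1.iloc[0][geom] == m2.iloc[0][geom]
        for linear in ("d3_mean_intensity", "d8_sum_intensity"):
            assert m2.iloc[0][linear] == pytest.approx(2 * m1.iloc[0][linear])
        for invariant in ("d5_skewness", "d6_kurtosis"):
            assert m2.iloc[0][invariant] == pytest.approx(
                m1.iloc[0][invariant], abs=1e-9)


class TestCorrelationSelection:
    def random_matrix(self, seed=0, n=50):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, 5)),
                            columns=list("abcde"))

    def test_duplicate_column_reduced_to_one(self):
        m = self.random_matrix()
        m["dup"] = m["a"]
        kept = feat.select_features_by_correlation(m, r_max=0.95)
        assert ("a" in kept) != ("dup" in kept)

    def test_independent_columns_all_survive(self):
        m = self.random_matrix(seed=11, n=200)
        r = np.abs(np.corrcoef(m.to_numpy(), rowvar=False))
        np.fill_diagonal(r, 0)
        assert r.max() < 0.95  # premise of the example
        assert feat.select_features_by_correlation(m, 0.95) == list("abcde")

    def test_r_max_zero_keeps_single_feature(self):
        assert len(feat.select_features_by_correlation(self.random_matrix(), 0.0)) == 1

    def test_constant_column_dropped_with_warning(self):
        m = self.random_matrix()
        m["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            kept = feat.select_features_by_correlation(m, 0.95)
        assert "flat" not in kept
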