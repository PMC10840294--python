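import numpy as np
import pytest

from ricemap.composite import StageFeatureImage
from ricemap.grid import RasterGrid
from ricemap.ssv import (
    CalibrationError,
    build_standard_curve,
    cosine_similarity,
    euclidean_distance,
    normalize_distance,
    scale_features,
    ssv_image,
    ssv_naive,
    StandardCurve,
)
from ricemap.types import SamplePointSet, SchemaError


def _image(values, stage="sowing", names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[0])]
    grid = RasterGrid(width=values.shape[2], height=values.shape[1])
    return StageFeatureImage(stage, names, values, grid)


class TestVectorPrimitives:
    def test_euclidean_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == 5.0

    def test_euclidean_identity_and_hand_value(self):
        assert euclidean_distance([1, 2], [1, 2]) == 0.0
        assert euclidean_distance([1, 2, 3], [4, 6, 3]) == pytest.approx(5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            euclidean_distance([1, 2], [1, 2, 3])
        with pytest.raises(SchemaError):
            cosine_similarity([1, 2], [1, 2, 3])

    def test_cosine_identity_orthogonality_scale_invariance(self):
        assert cosine_similarity([2, 4], [2, 4]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([2, 4], [1, 2]) == pytest.approx(1.0)

    def test_cosine_zero_norm_is_nodata(self):
        assert np.isnan(cosine_similarity([0, 0], [1, 2]))


class TestNormalizeDistance:
    def test_min_maps_to_zero_max_to_one(self):
        d_norm, d_min, d_max = normalize_distance(np.array([[0.0, 5.0, 10.0]]))
        np.testing.assert_allclose(d_norm, [[0.0, 0.5, 1.0]])
        assert (d_min, d_max) == (0.0, 10.0)

    def test_constant_image_degenerates_to_zero(self):
        d_norm, _, _ = normalize_distance(np.full((2, 2), 3.0))
        np.testing.assert_array_equal(d_norm, 0.0)

    def test_all_nodata_is_an_error(self):
        with pytest.raises(CalibrationError):
            normalize_distance(np.full((2, 2), np.nan))


class TestScaleFeatures:
    def test_minmax_maps_band_to_unit_interval(self):
        img = _image(np.array([[[-20.0, -15.0, -10.0]]]))
        scaled, record = scale_features(img, "minmax")
        np.testing.assert_allclose(scaled.values[0], [[0.0, 0.5, 1.0]])
        np.testing.assert_allclose(record.apply_vector(np.array([-15.0])), [0.5])

    def test_constant_band_flagged_degenerate_and_zeroed(self):
        img = _image(np.full((1, 1, 3), 7.0))
        scaled, record = scale_features(img, "minmax")
        np.testing.assert_array_equal(scaled.values, 0.0)
        assert record.degenerate.all()

    def test_none_mode_is_identity(self, rng):
        img = _image(rng.random((3, 2, 2)))
        scaled, record = scale_features(img, "none")
        np.testing.assert_array_equal(scaled.values, img.values)
        np.testing.assert_array_equal(record.apply_vector(np.array([1.0, 2.0, 3.0])),
                                      [1.0, 2.0, 3.0])


class TestStandardCurve:
    def _points(self, grid, pixels, label="rice"):
        return SamplePointSet([(*grid.xy_of(r, c), label) for r, c in pixels])

    def test_single_point_curve_equals_pixel_vector(self, rng):
        img = _image(rng.random((4, 3, 3)))
        curve = build_standard_curve(img, self._points(img.grid, [(1, 2)]))
        np.testing.assert_array_equal(curve.values, img.values[:, 1, 2])

    def test_two_point_mean(self):
        vals = np.zeros((2, 1, 2))
        vals[:, 0, 0] = [1.0, 3.0]
        vals[:, 0, 1] = [3.0, 5.0]
        curve = build_standard_curve(_image(vals), self._points(RasterGrid(2, 1), [(0, 0), (0, 1)]))
        np.testing.assert_array_equal(curve.values, [2.0, 4.0])

    def test_point_on_invalid_pixel_excluded(self, rng):
        vals = rng.random((2, 2, 2))
        vals[0, 0, 0] = np.nan
        img = _image(vals)
        curve = build_standard_curve(img, self._points(img.grid, [(0, 0), (1, 1)]))
        assert curve.sample_count == 1
        np.testing.assert_array_equal(curve.values, vals[:, 1, 1])

    def test_no_usable_rice_points_is_calibration_error(self, rng):
        img = _image(np.full((2, 2, 2), np.nan))
        with pytest.raises(CalibrationError):
            build_standard_curve(img, self._points(img.grid, [(0, 0)]))


class TestSSVImage:
    def test_three_pixel_toy_example_matches_hand_computation(self):
        # pixels (1,0), (0.6,0.8), (1,1) against curve (1,0), no scaling:
        #   d  = (0, sqrt(0.16+0.64), 1) = (0, sqrt(0.8), 1);  d_max = 1
        #   cs = (1, 0.6, 1/sqrt(2))
        #   ssv = cs - d/1 = (1, 0.6 - sqrt(0.8), 1/sqrt(2) - 1)
        vals = np.zeros((2, 1, 3))
        vals[:, 0, 0] = [1.0, 0.0]
        vals[:, 0, 1] = [0.6, 0.8]
        vals[:, 0, 2] = [1.0, 1.0]
        img = _image(vals)
        curve = StandardCurve("sowing", img.feature_names, np.array([1.0, 0.0]))
        out = ssv_image(img, curve, scaling="none")
        np.testing.assert_allclose(out.d[0], [0.0, np.sqrt(0.8), 1.0], atol=1e-9)
        np.testing.assert_allclose(out.d_norm[0], [0.0, np.sqrt(0.8), 1.0], atol=1e-9)
        np.testing.assert_allclose(out.cs[0], [1.0, 0.6, 1 / np.sqrt(2)], atol=1e-9)
        np.testing.assert_allclose(
            out.ssv[0], [1.0, 0.6 - np.sqrt(0.8), 1 / np.sqrt(2) - 1.0], atol=1e-9
        )
        assert out.d_min == 0.0 and out.d_max == 1.0

    def test_pixel_identical_to_curve_attaining_min_distance_scores_one(self, rng):
        vals = rng.random((3, 4, 4)) + 0.5
        y = vals[:, 2, 2].copy()
        img = _image(vals)
        curve = StandardCurve("sowing", img.feature_names, y)
        out = ssv_image(img, curve, scaling="none")
        if out.d[2, 2] == out.d.min():
            assert out.ssv[2, 2] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("scaling", ["minmax", "none"])
    def test_oracle_equivalence_on_random_scene(self, scaling, rng):
        vals = rng.random((20, 32, 32))
        vals[:, 0, 0] = np.nan  # one invalid pixel exercises nodata paths
        img = _image(vals)
        curve = StandardCurve("sowing", img.feature_names,
                              rng.random(20) * 0.5 + 0.25)
        fast = ssv_image(img, curve, scaling=scaling)
        slow = ssv_naive(img, curve, scaling=scaling)
        np.testing.assert_allclose(fast.ssv, slow, atol=1e-12, equal_nan=True)

    def test_ssv_identity_cs_minus_dnorm_everywhere(self, rng):
        img = _image(rng.random((5, 8, 8)))
        curve = StandardCurve("sowing", img.feature_names, rng.random(5))
        out = ssv_image(img, curve)
        np.testing.assert_allclose(out.ssv, out.cs - out.d_norm, atol=0)

    def test_bounds_under_minmax_scaling(self, rng):
        img = _image(rng.random((6, 10, 10)) * 10 - 5)
        curve = StandardCurve("sowing", img.feature_names, img.values[:, 3, 3].copy())
        out = ssv_image(img, curve, scaling="minmax")
        valid = np.isfinite(out.ssv)
        assert np.all(out.ssv[valid] <= 1.0 + 1e-12)
        assert np.all(out.ssv[valid] >= -1.0 - 1e-12)

    def test_rank_property_equal_cs_decreasing_in_distance(self):
        # colinear pixels all have cs = 1; ssv must then strictly
        # decrease with distance to the curve
        y = np.array([1.0, 2.0])
        alphas = np.array([1.0, 1.5, 2.5, 4.0])
        vals = (alphas[None, :] * y[:, None]).reshape(2, 1, 4)
        img = _image(vals)
        out = ssv_image(img, StandardCurve("sowing", img.feature_names, y), scaling="none")
        d = out.d[0]
        order = np.argsort(d)
        assert np.all(np.diff(out.ssv[0][order]) < 0)

    def test_curve_feature_mismatch_rejected(self, rng):
        img = _image(rng.random((3, 2, 2)))
        with pytest.raises(SchemaError):
            ssv_image(img, StandardCurve("sowing", ["a", "b", "c"], np.ones(3)))
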