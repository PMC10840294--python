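import numpy as np
import pytest

from ricemap.evaluation import (
    ConfusionMatrix,
    EvaluationError,
    confusion,
    metrics,
    patch_recognition_by_size,
    recognition_by_slope,
)
from ricemap.grid import RasterGrid
from ricemap.thresholds import RiceMap
from ricemap.types import SamplePointSet

# validation counts published for the two hilly study counties
DIANJIANG = np.array([[61, 3], [4, 118]])
ZHONGXIAN = np.array([[34, 3], [6, 37]])


def _rice_map(values, valid=None, grid=None):
    values = np.asarray(values, dtype=np.uint8)
    grid = grid or RasterGrid(width=values.shape[1], height=values.shape[0])
    valid = np.ones_like(values, dtype=bool) if valid is None else valid
    return RiceMap(values=values, valid=valid, grid=grid)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts, ua, pa, oa, kappa",
        [
            (DIANJIANG, 0.95, 0.94, 0.96, 0.92),
            # Zhongxian OA is exactly 71/80 = 0.8875, which rounds to 0.89
            # at two decimals under any nearest rule (the published table's
            # 0.88 is a truncation of 0.8875); kappa is exactly 31/40 =
            # 0.775 -> 0.78 half-up, as published.
            (ZHONGXIAN, 0.92, 0.85, 0.89, 0.78),
        ],
    )
    def test_published_county_tables_reproduce_at_two_decimals(
        self, counts, ua, pa, oa, kappa
    ):
        rep = metrics(ConfusionMatrix(counts)).rounded()
        assert rep["ua_rice"] == ua
        assert rep["pa_rice"] == pa
        assert rep["oa"] == oa
        assert rep["kappa"] == kappa

    def test_kappa_matches_independent_implementation(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        for counts in (DIANJIANG, ZHONGXIAN):
            pred, ref = [], []
            for i in range(2):
                for j in range(2):
                    pred += [i] * counts[i, j]
                    ref += [j] * counts[i, j]
            expected = sklearn.cohen_kappa_score(pred, ref)
            assert metrics(ConfusionMatrix(counts)).kappa == pytest.approx(expected, abs=1e-12)

    def test_perfect_prediction_gives_unit_oa_and_kappa(self):
        rep = metrics(ConfusionMatrix([[7, 0], [0, 11]]))
        assert rep.oa == 1.0 and rep.kappa == 1.0

    def test_kappa_zero_when_rows_proportional_to_column_marginals(self):
        rep = metrics(ConfusionMatrix([[10, 10], [40, 40]]))
        assert rep.kappa == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_reported_not_applicable(self):
        rep = metrics(ConfusionMatrix([[5, 5], [0, 0]]))
        assert np.isnan(rep.ua_nonrice)
        assert rep.oa == pytest.approx(0.5)


class TestConfusion:
    def _points(self, grid, labelled_pixels):
        return SamplePointSet(
            [(*grid.xy_of(r, c), label) for (r, c), label in labelled_pixels],
            role="validation",
        )

    def test_perfect_prediction_is_diagonal(self):
        pred = _rice_map([[1, 1], [0, 0]])
        pts = self._points(pred.grid, [((0, 0), "rice"), ((0, 1), "rice"),
                                       ((1, 0), "water"), ((1, 1), "dry-land")])
        cm = confusion(pred, pts)
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 2]])

    def test_all_rice_prediction_fills_top_row(self):
        pred = _rice_map(np.ones((2, 5)))
        pts = self._points(pred.grid, [((0, c), "rice") for c in range(5)]
                           + [((1, c), "water") for c in range(5)])
        cm = confusion(pred, pts)
        np.testing.assert_array_equal(cm.counts, [[5, 5], [0, 0]])

    def test_sample_on_nodata_pixel_dropped_and_counted(self):
        valid = np.ones((2, 2), dtype=bool)
        valid[0, 0] = False
        pred = _rice_map([[1, 1], [0, 0]], valid=valid)
        pts = self._points(pred.grid, [((0, 0), "rice"), ((0, 1), "rice")])
        cm = confusion(pred, pts)
        assert cm.total == 1 and cm.dropped == 1

    def test_zero_usable_points_is_an_error(self):
        pred = _rice_map([[1]], valid=np.zeros((1, 1), dtype=bool))
        with pytest.raises(EvaluationError):
            confusion(pred, self._points(pred.grid, [((0, 0), "rice")]))


class TestPatchRecognition:
    def test_perfect_prediction_recognizes_every_bin(self, rng):
        truth = rng.random((20, 20)) > 0.8
        truth[0:3, 0:3] = True
        pred = _rice_map(truth.astype(np.uint8))
        out = patch_recognition_by_size(truth, pred)
        assert out and all(v["proportion"] == 1.0 for v in out.values())

    def test_empty_prediction_recognizes_nothing(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[2:5, 2:5] = True
        pred = _rice_map(np.zeros((10, 10)))
        out = patch_recognition_by_size(truth, pred)
        assert all(v["proportion"] == 0.0 for v in out.values())

    def test_three_by_three_patch_with_one_missed_pixel(self):
        # a single 3x3 patch is 900 m2 at 10 m resolution -> the >= 800 bin;
        # 8 of its 9 pixels predicted gives proportion 8/9
        truth = np.zeros((10, 10), dtype=bool)
        truth[2:5, 2:5] = True
        pred_vals = truth.copy()
        pred_vals[3, 3] = False
        out = patch_recognition_by_size(truth, _rice_map(pred_vals.astype(np.uint8)))
        assert list(out) == [">= 800 m2"]
        assert out[">= 800 m2"]["proportion"] == pytest.approx(8 / 9)

    def test_diagonal_pixels_form_one_patch_under_8_connectivity(self):
        truth = np.zeros((6, 6), dtype=bool)
        truth[1, 1] = truth[2, 2] = truth[3, 3] = True   # 300 m2 if 8-connected
        pred = _rice_map(truth.astype(np.uint8))
        out8 = patch_recognition_by_size(truth, pred, connectivity=2)
        out4 = patch_recognition_by_size(truth, pred, connectivity=1)
        assert out8["[0, 400) m2"]["patches"] == 1
        assert out4["[0, 400) m2"]["patches"] == 3

    def test_no_truth_rice_is_an_error(self):
        with pytest.raises(EvaluationError):
            patch_recognition_by_size(np.zeros((4, 4), dtype=bool),
                                      _rice_map(np.zeros((4, 4))))

    def test_matches_direct_count_oracle_on_random_scene(self, rng):
        from skimage import measure

        truth = rng.random((30, 30)) > 0.85
        pred_vals = truth & (rng.random((30, 30)) > 0.3)
        pred = _rice_map(pred_vals.astype(np.uint8))
        out = patch_recognition_by_size(truth, pred, bin_edges_m2=[400.0, 800.0])
        labels = measure.label(truth, connectivity=2)
        for key, stats in out.items():
            rec = tot = 0
            for lab in range(1, labels.max() + 1):
                patch = labels == lab
                area = patch.sum() * 100.0
                lo, hi = {"[0, 400) m2": (0, 400), "[400, 800) m2": (400, 800),
                          ">= 800 m2": (800, np.inf)}[key]
                if lo <= area < hi:
                    tot += patch.sum()
                    rec += (patch & pred_vals).sum()
            assert stats["proportion"] == pytest.approx(rec / tot)


class TestRecognitionBySlope:
    def test_flat_scene_perfect_prediction(self):
        truth = np.zeros((5, 5), dtype=bool)
        truth[1:3, 1:3] = True
        out = recognition_by_slope(truth, _rice_map(truth.astype(np.uint8)),
                                   np.zeros((5, 5)))
        assert out["[0, 2) deg"]["ratio"] == 1.0

    def test_bins_without_rice_are_not_applicable(self):
        truth = np.zeros((5, 5), dtype=bool)
        truth[1, 1] = True
        out = recognition_by_slope(truth, _rice_map(truth.astype(np.uint8)),
                                   np.zeros((5, 5)))
        assert np.isnan(out[">= 10 deg"]["ratio"])

    def test_matches_direct_count_oracle_on_hillside(self, rng):
        truth = rng.random((20, 20)) > 0.7
        pred_vals = truth & (rng.random((20, 20)) > 0.4)
        slope = rng.random((20, 20)) * 15
        out = recognition_by_slope(truth, _rice_map(pred_vals.astype(np.uint8)),
                                   slope, bin_edges_deg=[2.0, 6.0, 10.0])
        edges = [(0, 2), (2, 6), (6, 10), (10, np.inf)]
        for (lo, hi), stats in zip(edges, out.values()):
            sel = truth & (slope >= lo) & (slope < hi)
            if sel.sum():
                assert stats["ratio"] == pytest.approx((sel & pred_vals).sum() / sel.sum())
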