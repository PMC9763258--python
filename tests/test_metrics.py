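import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from gevrisk.metrics import (
    clopper_pearson,
    diagnostic_report,
    mcnemar_test,
    pixel_metrics,
    segmentation_report,
    table3_deltas,
)
from gevrisk.segmentation import RasterMask


def _mask(arr):
    return RasterMask.from_bool(np.asarray(arr, bool))


def _row_mask(tp, fp, fn, width=40):
    """1-D masks with prescribed overlap counts."""
    pred = np.zeros((1, width), bool)
    gt = np.zeros((1, width), bool)
    pred[0, : tp + fp] = True
    gt[0, : tp] = True
    gt[0, tp + fp: tp + fp + fn] = True
    return _mask(pred), _mask(gt)


class TestPixelMetrics:
    def test_identity(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        ov = pixel_metrics(_mask(m), _mask(m))
        assert (ov.precision, ov.recall, ov.iou) == (1.0, 1.0, 1.0)

    def test_disjoint(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = b[4, 4] = True
        ov = pixel_metrics(_mask(a), _mask(b))
        assert (ov.precision, ov.recall, ov.iou) == (0.0, 0.0, 0.0)

    def test_hand_counted_overlap(self):
        # two 2x2 squares sharing one 2-pixel column: tp=2, fp=2, fn=2
        pred = np.zeros((4, 4), bool)
        gt = np.zeros((4, 4), bool)
        pred[1:3, 0:2] = True
        gt[1:3, 1:3] = True
        ov = pixel_metrics(_mask(pred), _mask(gt))
        assert (ov.tp_area, ov.fp_area, ov.fn_area) == (2, 2, 2)
        assert ov.precision == 0.5 and ov.recall == 0.5
        assert ov.iou == pytest.approx(1 / 3)

    def test_empty_vs_empty_is_perfect_and_flagged(self):
        ov = pixel_metrics(_mask(np.zeros((3, 3))), _mask(np.zeros((3, 3))))
        assert ov.iou == 1.0 and ov.degenerate

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_metrics(_mask(np.zeros((3, 3))), _mask(np.zeros((4, 4))))

    @pytest.mark.parametrize("seed", range(8))
    def test_iou_bounded_by_precision_and_recall(self, seed):
        rng = np.random.default_rng(seed)
        pred = _mask(rng.random((20, 20)) < 0.4)
        gt = _mask(rng.random((20, 20)) < 0.4)
        ov = pixel_metrics(pred, gt)
        assert ov.iou <= min(ov.precision, ov.recall) + 1e-12

    def test_invariant_under_joint_transposition(self):
        rng = np.random.default_rng(5)
        p = rng.random((15, 20)) < 0.3
        g = rng.random((15, 20)) < 0.3
        a = pixel_metrics(_mask(p), _mask(g))
        b = pixel_metrics(_mask(p.T), _mask(g.T))
        assert (a.precision, a.recall, a.iou) == (b.precision, b.recall, b.iou)

    def test_bounding_box_mode(self):
        pred = np.zeros((10, 10), bool)
        gt = np.zeros((10, 10), bool)
        pred[0, 0] = pred[4, 4] = True  # bbox 5x5
        gt[0, 0] = gt[4, 4] = True
        assert pixel_metrics(_mask(pred), _mask(gt), boxes=True).iou == 1.0


class TestSegmentationReport:
    def test_perfect_pairs(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        rep = segmentation_report([(_mask(m), _mask(m))] * 3)
        assert rep.miou == 1.0
        assert rep.frac_iou_gt_05 == 1.0
        assert rep.sens_per_varix == 1.0 and rep.sens_per_image == 1.0

    def test_forty_percent_coverage_not_detected(self):
        gt = np.zeros((1, 10), bool)
        gt[0, :10] = True
        pred = np.zeros((1, 10), bool)
        pred[0, :4] = True  # covers 40% of the instance
        rep = segmentation_report([(_mask(pred), _mask(gt))])
        assert rep.sens_per_varix == 0.0 and rep.sens_per_image == 0.0

    def test_coverage_threshold_monotonicity(self):
        gt = np.zeros((1, 10), bool)
        gt[0, :10] = True
        pred = np.zeros((1, 10), bool)
        pred[0, :4] = True
        pairs = [(_mask(pred), _mask(gt))]
        sens = [
            segmentation_report(pairs, coverage_threshold=t).sens_per_varix
            for t in (0.9, 0.5, 0.4, 0.1)
        ]
        assert sens == sorted(sens)  # non-decreasing as threshold drops

    def test_miou_and_threshold_fractions(self):
        p1, g1 = _row_mask(11, 4, 5)  # IoU 11/20 = 0.55
        p2, g2 = _row_mask(13, 3, 4)  # IoU 13/20 = 0.65
        rep = segmentation_report([(p1, g1), (p2, g2)])
        assert rep.miou == pytest.approx(0.60)
        assert rep.frac_iou_gt_05 == 1.0
        assert rep.frac_iou_gt_06 == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            segmentation_report([])


class TestClopperPearson:
    @pytest.mark.parametrize("n", range(1, 16))
    def test_matches_exhaustive_binomial_enumeration(self, n):
        # oracle: invert the exact binomial tails by bisection on p
        def oracle(k, n, alpha=0.05):
            def tail_ge(p):  # P(X >= k)
                return sum(stats.binom.pmf(i, n, p) for i in range(k, n + 1))

            def tail_le(p):  # P(X <= k)
                return sum(stats.binom.pmf(i, n, p) for i in range(0, k + 1))

            def bisect(f, target, lo=0.0, hi=1.0):
                for _ in range(200):
                    mid = (lo + hi) / 2
                    if f(mid) < target:
                        lo = mid
                    else:
                        hi = mid
                return (lo + hi) / 2

            lo = 0.0 if k == 0 else bisect(tail_ge, alpha / 2)
            hi = 1.0 if k == n else 1.0 - bisect(lambda p: tail_le(1 - p), alpha / 2)
            return lo, hi

        for k in range(n + 1):
            got = clopper_pearson(k, n)
            want = oracle(k, n)
            assert got[0] == pytest.approx(want[0], abs=1e-6)
            assert got[1] == pytest.approx(want[1], abs=1e-6)

    def test_contains_point_estimate(self):
        for k, n in [(0, 7), (3, 9), (12, 12), (127, 130)]:
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi


class TestDiagnosticReport:
    def test_risk_table_accuracy(self):
        rep = diagnostic_report([[110, 1], [2, 17]])
        assert rep.accuracy * 100 == pytest.approx(97.69, abs=0.005)
        lo, hi = rep.accuracy_ci
        assert (round(lo * 100, 2), round(hi * 100, 2)) == (93.14, 99.51)

    def test_reader_table_accuracy(self):
        rep = diagnostic_report([[104, 7], [12, 7]])
        assert rep.accuracy * 100 == pytest.approx(85.38, abs=0.005)
        lo, hi = rep.accuracy_ci
        assert (round(lo * 100, 2), round(hi * 100, 2)) == (78.22, 90.52)

    def test_perfect_diagonal(self):
        rep = diagnostic_report([[20, 0], [0, 10]])
        assert rep.accuracy == 1.0 and rep.accuracy_ci[1] == 1.0

    def test_two_by_two_rates(self):
        rep = diagnostic_report([[8, 2], [1, 9]])
        assert rep.sensitivity == 0.8
        assert rep.specificity == 0.9
        assert rep.ppv == pytest.approx(8 / 9)
        assert rep.npv == pytest.approx(9 / 11)

    def test_accuracy_invariant_under_category_permutation(self):
        m = np.array([[5, 1, 0], [2, 7, 1], [0, 3, 9]])
        perm = [2, 0, 1]
        a = diagnostic_report(m).accuracy
        b = diagnostic_report(m[np.ix_(perm, perm)]).accuracy
        assert a == b

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_report([[0, 0], [0, 0]])


class TestMcNemar:
    def test_perfect_symmetry(self):
        assert mcnemar_test(5, 5)["p"] == 1.0

    def test_exact_one_sided_tail(self):
        out = mcnemar_test(10, 0)
        assert out["method"] == "exact"
        assert out["p"] == pytest.approx(2 * 0.5**10)

    def test_chi_square_with_continuity_correction(self):
        out = mcnemar_test(40, 10)
        assert out["method"] == "chi2-cc"
        assert out["statistic"] == pytest.approx((abs(40 - 10) - 1) ** 2 / 50)

    @pytest.mark.parametrize("b,c", [(3, 8), (0, 12), (30, 14), (25, 25)])
    def test_matches_statsmodels(self, b, c):
        ours = mcnemar_test(b, c)
        exact = b + c < 25
        ref = sm_mcnemar([[0, b], [c, 0]], exact=exact, correction=True)
        assert ours["p"] == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(-1, 3)


class TestTable3Deltas:
    SYSTEM = [[110, 1], [2, 17]]
    READERS = [[104, 7], [12, 7]]

    def test_more_correct_interventions(self):
        out = table3_deltas(self.SYSTEM, self.READERS)
        assert out["delta_correct"] == 16
        assert out["delta_correct_pct"] == pytest.approx(100 * 16 / 130)

    def test_more_low_risk_patients_spared(self):
        out = table3_deltas(self.SYSTEM, self.READERS)
        assert out["delta_lowrisk"] == 10
        assert out["delta_lowrisk_pct"] == pytest.approx(100 * 10 / 19)

    def test_identical_tables_give_zero(self):
        out = table3_deltas(self.SYSTEM, self.SYSTEM)
        assert out["delta_correct_pct"] == 0.0 and out["delta_lowrisk_pct"] == 0.0

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError):
            table3_deltas(self.SYSTEM, [[1, 0], [0, 0]])
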