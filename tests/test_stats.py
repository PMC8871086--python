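import math

import numpy as np
import pytest

from histoscar import (
    compare_regions,
    one_way_anova,
    student_t,
    summarize_roi,
)
from histoscar.errors import DegenerateVarianceError, ParameterError
from histoscar.fibers import VarianceMap
from histoscar.segmentation import SegmentationResult
from histoscar.stats import RoiMetrics, metrics_to_frame


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t and two-sided p (closed form)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def make_seg(fs, cas):
    fs, cas = np.asarray(fs, bool), np.asarray(cas, bool)
    return SegmentationResult(cas=cas, fs=fs, bs=~(fs | cas))


def make_variance(v, valid):
    v = np.asarray(v, float)
    valid = np.asarray(valid, bool)
    m = valid.astype(float)
    return VarianceMap(v=v, r=(1 - v) * m, m=m, valid=valid)


class TestSummarizeRoi:
    def test_all_collagen_constant_orientation(self):
        shape = (10, 10)
        seg = make_seg(np.zeros(shape), np.ones(shape))
        density = np.ones(shape)
        var = make_variance(np.zeros(shape), np.ones(shape))
        m = summarize_roi(seg, density, var)
        assert (m.cas_pct, m.cdm_pct, m.dv_pct) == (100.0, 100.0, 0.0)
        assert m.fs_pct == 0.0 and m.n_valid_dv == 100

    def test_pixel_counting_arithmetic(self, rng):
        fs = np.zeros(100, bool)
        fs[rng.choice(100, 37, replace=False)] = True
        fs = fs.reshape(10, 10)
        seg = make_seg(fs, np.zeros((10, 10)))
        m = summarize_roi(seg, np.zeros((10, 10)), make_variance(np.zeros((10, 10)), np.zeros((10, 10))))
        assert m.fs_pct == 37.0
        # independent recount from the masks themselves
        assert m.fs_pct == 100.0 * fs.sum() / fs.size
        assert m.cas_pct == 0.0

    def test_undefined_dv_is_nan_not_zero(self):
        seg = make_seg(np.zeros((4, 4)), np.zeros((4, 4)))
        m = summarize_roi(seg, np.zeros((4, 4)), make_variance(np.zeros((4, 4)), np.zeros((4, 4))))
        assert math.isnan(m.dv_pct) and m.n_valid_dv == 0

    def test_percentages_bounded_and_partition_consistent(self, rng):
        fs = rng.random((12, 12)) < 0.3
        cas = ~fs & (rng.random((12, 12)) < 0.5)
        seg = make_seg(fs, cas)
        m = summarize_roi(seg, rng.random((12, 12)), make_variance(rng.random((12, 12)), cas))
        assert 0 <= m.fs_pct <= 100 and 0 <= m.cas_pct <= 100
        assert m.fs_pct + m.cas_pct <= 100


class TestStudentT:
    def test_identical_groups(self):
        out = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.statistic == 0.0 and out.p_value == 1.0

    def test_large_shift_is_significant(self):
        out = student_t([1, 2, 3], [11, 12, 13])
        assert out.p_value < 0.001

    def test_matches_closed_form_oracle(self):
        a = [2.1, 2.5, 2.3, 2.0]
        b = [3.0, 3.4, 3.1]
        out = student_t(a, b)
        t_exp, p_exp = pooled_t_oracle(a, b)
        assert out.statistic == pytest.approx(t_exp, abs=1e-6)
        assert out.p_value == pytest.approx(p_exp, abs=1e-6)
        assert out.means == pytest.approx([np.mean(a), np.mean(b)])
        assert out.sds == pytest.approx([np.std(a, ddof=1), np.std(b, ddof=1)])

    def test_zero_variance_conventions(self):
        out = student_t([5.0, 5.0], [5.0, 5.0])
        assert out.p_value == 1.0
        with pytest.raises(DegenerateVarianceError):
            student_t([5.0, 5.0], [6.0, 6.0])

    def test_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        base = student_t(a, b)
        scaled = student_t(1234.5 * a, 1234.5 * b)
        assert scaled.statistic == pytest.approx(base.statistic, abs=1e-12)
        assert scaled.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_group_size_validation(self):
        with pytest.raises(ParameterError):
            student_t([1.0], [2.0, 3.0])

    def test_welch_flag_reported(self, rng):
        out = student_t(rng.normal(0, 1, 6), rng.normal(0, 3, 6), welch=True)
        assert out.test == "welch_t"


class TestOneWayAnova:
    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 9)
        t_out = student_t(a, b)
        f_out = one_way_anova([a, b])
        assert f_out.statistic == pytest.approx(t_out.statistic**2, abs=1e-10)
        assert f_out.p_value == pytest.approx(t_out.p_value, abs=1e-10)

    def test_three_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        out = one_way_anova([g, g, g])
        assert out.statistic == 0.0 and out.p_value == 1.0

    def test_hand_worked_three_by_four_table(self):
        # groups with hand-computed sums of squares:
        groups = [[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0], [4.0, 5.0, 6.0, 7.0]]
        # grand mean = 46/12; SS_between = 4*((2.5-gm)^2+(3.5-gm)^2+(5.5-gm)^2)
        gm = 46.0 / 12.0
        ss_b = 4 * ((2.5 - gm) ** 2 + (3.5 - gm) ** 2 + (5.5 - gm) ** 2)
        ss_w = 3 * (5.0 / 3.0) * 3  # each group's SS is 5; ddof-1 var * (n-1) = 5
        f_exp = (ss_b / 2) / (15.0 / 9)
        assert ss_w == pytest.approx(15.0)
        out = one_way_anova(groups)
        assert out.statistic == pytest.approx(f_exp, abs=1e-9)

    def test_scale_invariance(self, rng):
        gs = [rng.normal(i, 1, 6) for i in range(3)]
        base = one_way_anova(gs)
        scaled = one_way_anova([7.7 * g for g in gs])
        assert scaled.statistic == pytest.approx(base.statistic, abs=1e-12)

    def test_degenerate_variance(self):
        assert one_way_anova([[2.0, 2.0], [2.0, 2.0]]).p_value == 1.0
        with pytest.raises(DegenerateVarianceError):
            one_way_anova([[2.0, 2.0], [3.0, 3.0]])


def _metric(value, group):
    return RoiMetrics(fs_pct=1.0, cas_pct=2.0, cdm_pct=value, dv_pct=3.0,
                      n_pixels=100, n_valid_dv=50, group=group)


class TestCompareRegions:
    def test_two_identical_groups_p_one(self):
        groups = {
            "a": [_metric(5.0, "a"), _metric(6.0, "a")],
            "b": [_metric(5.0, "b"), _metric(6.0, "b")],
        }
        out = compare_regions(groups, "cdm_pct")
        assert out.p_value == 1.0 and out.test == "student_t"

    def test_three_groups_dispatch_to_anova(self, rng):
        groups = {
            name: [_metric(v, name) for v in rng.normal(mu, 1, 5)]
            for name, mu in (("normal", 40.0), ("mixed", 60.0), ("scar", 90.0))
        }
        out = compare_regions(groups, "cdm_pct")
        assert out.test == "one_way_anova" and out.statistic > 0

    def test_unknown_metric_lists_valid_names(self):
        groups = {"a": [_metric(1, "a")] * 2, "b": [_metric(2, "b")] * 2}
        with pytest.raises(ParameterError, match="cdm_pct"):
            compare_regions(groups, "bogus")

    def test_nan_dv_excluded(self):
        ms = [_metric(1.0, "a"), _metric(2.0, "a")]
        ms[0].dv_pct = math.nan
        groups = {"a": ms + [_metric(3.0, "a")],
                  "b": [_metric(v, "b") for v in (1.0, 2.0, 3.0)]}
        out = compare_regions(groups, "dv_pct")
        assert math.isfinite(out.p_value)

    def test_metrics_frame_column_order(self):
        frame = metrics_to_frame([_metric(1.0, "g")])
        assert list(frame.columns) == [
            "roi_id", "group", "fs_pct", "cas_pct", "cdm_pct", "dv_pct", "n_pixels", "n_valid_dv",
        ]


class TestCalibration:
    def test_type_i_error_rate_near_alpha(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a, b = rng.standard_normal(8), rng.standard_normal(8)
            if student_t(a, b).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065
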