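"""Evaluation: reserve reference, performance errors, rolling CV, zone agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crmon.detect import DetectionEvent
from crmon.engine import CRMSeries
from crmon.errors import EvaluationError
from crmon.evaluate import (GroundTruthSeries, PerformanceErrorSeries, cohort_summary,
                            detection_time_stats, evaluate_subject, ground_truth,
                            mdpe_mdape, performance_error, rolling_cv, zone_confusion)
from crmon.protocol import LBNPProtocol

# endpoint in the 60 mmHg stage -> reference pressure 60
PROTO = LBNPProtocol(endpoint_time=300.0 + 3 * 300.0 + 150.0)


def _series(times, values):
    v = np.asarray(values, dtype=float)
    return CRMSeries(times=np.asarray(times, float), raw=v, smoothed=v.copy())


class TestGroundTruth:
    def test_reference_points(self):
        t = np.array([100.0,                 # baseline -> 1
                      300.0 + 300.0 + 10.0,  # 30 mmHg stage, ref 60 -> 0.5
                      PROTO.endpoint_time])  # endpoint stage -> 0
        gt = ground_truth(PROTO, t)
        assert gt.crm_gt[0] == 1.0
        assert gt.crm_gt[1] == pytest.approx(0.5)
        assert gt.crm_gt[2] == 0.0

    def test_values_bounded(self):
        t = np.arange(0.0, PROTO.total_duration, 1.0)
        gt = ground_truth(PROTO, t)
        assert gt.crm_gt.min() >= 0.0 and gt.crm_gt.max() <= 1.0


class TestPerformanceError:
    def test_perfect_prediction_gives_zero(self):
        t = np.arange(5.0, 900.0)
        gt = ground_truth(PROTO, t)
        pred = _series(t, 100.0 * gt.crm_gt)
        pe = performance_error(pred, gt)
        assert np.all(pe.pe == 0.0)

    def test_under_prediction_sign(self):
        t = np.array([10.0, 11.0])
        gt = GroundTruthSeries(times=t, crm_gt=np.array([1.0, 1.0]))
        pe = performance_error(_series(t, [50.0, 50.0]), gt)
        assert np.allclose(pe.pe, -0.5)

    def test_zero_reference_ticks_discarded(self):
        t = np.arange(5.0, PROTO.total_duration - 300.0)
        gt = ground_truth(PROTO, t)
        pred = _series(t, np.full(len(t), 50.0))
        pe = performance_error(pred, gt)
        assert len(pe.pe) == np.count_nonzero(gt.crm_gt > 0)
        assert len(pe.pe) < len(t)

    def test_disjoint_axes_rejected(self):
        gt = GroundTruthSeries(times=np.array([1000.0]), crm_gt=np.array([1.0]))
        with pytest.raises(EvaluationError):
            performance_error(_series([5.0], [50.0]), gt)


class TestMdpeMdape:
    @pytest.mark.parametrize("pe,expect", [
        ([-0.1, 0.0, 0.1], (0.0, 10.0)),
        ([0.2, 0.2, 0.2], (20.0, 20.0)),
    ])
    def test_examples(self, pe, expect):
        series = PerformanceErrorSeries(times=np.arange(len(pe), dtype=float),
                                        pe=np.asarray(pe))
        assert mdpe_mdape(series) == pytest.approx(expect)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_sorting_oracle(self, seed):
        pe = np.random.default_rng(seed).normal(0, 0.3, 41)
        series = PerformanceErrorSeries(times=np.arange(41.0), pe=pe)
        mdpe, mdape = mdpe_mdape(series)
        assert mdpe == pytest.approx(100.0 * np.sort(pe)[20])
        assert mdape == pytest.approx(100.0 * np.sort(np.abs(pe))[20])

    @given(st.integers(0, 2 ** 32 - 1))
    def test_unsigned_error_dominates_signed(self, seed):
        pe = np.random.default_rng(seed).normal(0.05, 0.4, 60)
        series = PerformanceErrorSeries(times=np.arange(60.0), pe=pe)
        mdpe, mdape = mdpe_mdape(series)
        assert mdape >= abs(mdpe)


class TestRollingCV:
    def test_constant_series_zero(self):
        assert rolling_cv(np.full(100, 55.0)) == 0.0

    def test_alternating_pattern_matches_bruteforce(self):
        values = np.tile([40.0, 60.0], 50)
        expect = np.std(values[:30], ddof=1) / np.mean(values[:30]) * 100.0
        assert rolling_cv(values) == pytest.approx(expect)

    def test_near_zero_mean_windows_excluded(self):
        values = np.concatenate([np.full(60, 50.0), np.full(60, 0.0), np.full(60, 50.0)])
        assert rolling_cv(values) == 0.0  # zero-mean windows cannot dominate

    def test_no_valid_window_rejected(self):
        with pytest.raises(EvaluationError):
            rolling_cv(np.zeros(100))


class TestZoneConfusion:
    def test_identity_for_perfect_predictions(self):
        t = np.arange(5.0, PROTO.total_duration, 1.0)
        gt = ground_truth(PROTO, t)
        norm, counts, metrics = zone_confusion(_series(t, 100.0 * gt.crm_gt), gt)
        assert np.allclose(norm, np.eye(3))
        assert np.allclose(metrics.to_numpy(dtype=float), 1.0)

    def test_all_yellow_predictions(self):
        t = np.arange(5.0, PROTO.total_duration, 1.0)
        gt = ground_truth(PROTO, t)
        norm, counts, metrics = zone_confusion(_series(t, np.full(len(t), 55.0)), gt)
        assert metrics.loc["green", "recall"] == 0.0
        assert metrics.loc["red", "recall"] == 0.0
        assert metrics.loc["yellow", "recall"] == 1.0

    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(200.0)
        gt = GroundTruthSeries(times=t, crm_gt=rng.uniform(0, 1, 200))
        pred = _series(t, rng.uniform(0, 100, 200))
        norm, counts, metrics = zone_confusion(pred, gt)

        def zone(v):
            return 0 if v > 70 else (2 if v < 40 else 1)

        expect = np.zeros((3, 3))
        for g, p in zip(gt.crm_gt, pred.raw):
            expect[zone(100 * g), zone(p)] += 1
        assert np.array_equal(counts, expect)
        rows = expect.sum(axis=1)
        for z in range(3):
            if rows[z]:
                assert np.allclose(norm[z], expect[z] / rows[z])
                tp = expect[z, z]
                fp = expect[:, z].sum() - tp
                fn = rows[z] - tp
                tn = expect.sum() - tp - fp - fn
                assert metrics.iloc[z]["recall"] == pytest.approx(tp / (tp + fn))
                assert metrics.iloc[z]["specificity"] == pytest.approx(tn / (tn + fp))

    def test_unsupported_zone_marked_unavailable(self):
        t = np.arange(50.0)
        gt = GroundTruthSeries(times=t, crm_gt=np.full(50, 1.0))  # green only
        norm, counts, metrics = zone_confusion(_series(t, np.full(50, 80.0)), gt)
        assert np.all(np.isnan(norm[1])) and np.all(np.isnan(norm[2]))
        assert np.isnan(metrics.loc["yellow", "recall"])

    def test_rows_sum_to_one_where_supported(self):
        t = np.arange(5.0, PROTO.total_duration, 1.0)
        gt = ground_truth(PROTO, t)
        rng = np.random.default_rng(0)
        norm, _, _ = zone_confusion(_series(t, rng.uniform(0, 100, len(t))), gt)
        sums = np.nansum(norm, axis=1)
        assert np.allclose(sums[~np.isnan(norm).all(axis=1)], 1.0)


class TestCohort:
    def _report(self, sid, early):
        t = np.arange(5.0, PROTO.total_duration, 1.0)
        gt = ground_truth(PROTO, t)
        pred = _series(t, 100.0 * gt.crm_gt)
        events = [DetectionEvent("trend_crm", True, PROTO.endpoint_time - early * 60, early)]
        return evaluate_subject(sid, pred, PROTO, detection_events=events)

    def test_single_subject_equals_cohort(self):
        report = self._report("s0", 10.0)
        cohort = cohort_summary([report])
        assert cohort["metrics"].loc["mdpe_pct", "median"] == report.mdpe
        assert cohort["metrics"].loc["mdape_pct", "mean"] == report.mdape

    def test_detection_aggregation(self):
        cohort = cohort_summary([self._report("a", 10.0), self._report("b", 20.0)])
        det = cohort["detections"].loc["trend_crm"]
        assert det["early_min_mean"] == pytest.approx(15.0)
        assert det["early_min_sd"] == pytest.approx(np.std([10.0, 20.0], ddof=1))
        assert det["n_not_flagged"] == 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(EvaluationError):
            cohort_summary([])


def test_detection_time_stats_smoke():
    rng = np.random.default_rng(0)
    early = {"red_gate": rng.normal(6, 2, 12), "yellow_gate": rng.normal(14, 3, 12),
             "trend_crm": rng.normal(18, 3, 12)}
    table = detection_time_stats(early)
    assert {"friedman"} <= set(table["test"])
    assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()
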