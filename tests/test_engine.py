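"""Engine: normalization, surrogate/oracle predictors, causal smoothing, pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crmon.engine import (CRMSeries, SurrogatePredictor, minmax_normalize,
                          run_pipeline, smooth_causal, stream_pipeline)
from crmon.errors import ContractError
from crmon.ingest import WaveformRecord
from crmon.simulate import synth_ppg_segment


class TestMinMaxNormalize:
    def test_ramp_midpoint(self):
        window = np.linspace(0.0, 10.0, 500)
        out = minmax_normalize(window, end_time=5.0)
        assert out.valid
        idx = np.argmin(np.abs(window - 5.0))
        assert out.values[idx] == pytest.approx(0.5, abs=5e-3)

    def test_constant_window_invalid(self):
        out = minmax_normalize(np.full(500, 3.3), end_time=5.0)
        assert not out.valid

    @given(st.integers(0, 2 ** 32 - 1))
    def test_exactly_one_zero_and_one_one(self, seed):
        window = np.random.default_rng(seed).normal(size=500)
        out = minmax_normalize(window, end_time=5.0)
        assert out.valid
        assert np.count_nonzero(out.values == 0.0) == 1
        assert np.count_nonzero(out.values == 1.0) == 1
        assert out.values.min() == 0.0 and out.values.max() == 1.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ContractError):
            minmax_normalize(np.zeros(499), end_time=5.0)


class TestSmoothing:
    def test_constant_input(self):
        out = smooth_causal(np.full(30, 42.0))
        assert np.all(np.isnan(out[:19]))
        assert np.allclose(out[19:], 42.0)

    def test_warmup_at_twentieth_value(self):
        out = smooth_causal(np.arange(25, dtype=float))
        assert np.all(np.isnan(out[:19])) and np.isfinite(out[19])

    def test_impulse_response_spreads_over_twenty_ticks(self):
        raw = np.zeros(80)
        raw[30] = 1.0
        out = smooth_causal(raw)
        hit = np.flatnonzero(np.isclose(out, 1.0 / 20.0))
        assert np.array_equal(hit, np.arange(30, 50))
        assert np.all(out[50:] == 0.0)

    def test_missing_ticks_do_not_count_toward_warmup(self):
        raw = np.full(50, np.nan)
        raw[::2] = 7.0  # 25 valid values at even indices
        out = smooth_causal(raw)
        # 20th valid value sits at index 38
        assert np.all(np.isnan(out[:38]))
        assert out[38] == pytest.approx(7.0)
        assert np.all(np.isnan(out[39::2]))

    @given(st.integers(0, 2 ** 32 - 1), st.integers(5, 120))
    def test_matches_bruteforce_trailing_mean(self, seed, n):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0, 100, n)
        raw[rng.random(n) < 0.2] = np.nan
        out = smooth_causal(raw)
        finite_idx = [i for i in range(n) if np.isfinite(raw[i])]
        for rank, i in enumerate(finite_idx):
            if rank + 1 >= 20:
                expect = np.mean([raw[j] for j in finite_idx[rank - 19:rank + 1]])
                assert out[i] == pytest.approx(expect)
            else:
                assert np.isnan(out[i])


class TestSurrogate:
    def test_baseline_morphology_maps_high(self):
        """Windows at the simulator's baseline amplitude and rate predict >= 90."""
        predictor = SurrogatePredictor()
        for seed in range(6):
            rec = synth_ppg_segment(65.0, 1.0, 40.0, 31.25, noise_sd=0.02,
                                    rng=np.random.default_rng(seed))
            series = run_pipeline(rec, predictor)
            assert np.nanmin(series.raw) >= 90.0

    def test_endpoint_morphology_maps_low(self):
        predictor = SurrogatePredictor()
        rec = synth_ppg_segment(100.0, 0.2, 40.0, 31.25, noise_sd=0.02,
                                rng=np.random.default_rng(0))
        series = run_pipeline(rec, predictor)
        assert np.nanmax(series.raw) <= 10.0

    def test_monotone_decline_after_smoothing(self):
        """Stepwise falling amplitude with rising rate yields a (near-)
        monotone falling smoothed prediction stream."""
        segs = []
        for k, (amp, hr) in enumerate(zip(np.linspace(1.0, 0.2, 6),
                                          np.linspace(65.0, 100.0, 6))):
            segs.append(synth_ppg_segment(hr, amp, 60.0, 100.0).samples)
        rec = WaveformRecord(np.concatenate(segs), 100.0)
        series = run_pipeline(rec, SurrogatePredictor())
        s = series.smoothed[np.isfinite(series.smoothed)]
        assert np.all(np.diff(s) <= 0.2)  # tolerance for beat quantization wobble
        assert s[0] - s[-1] > 80.0

    def test_flat_signal_gives_no_predictions(self):
        rec = WaveformRecord(np.full(3000, 5.0), 100.0)
        series = run_pipeline(rec, SurrogatePredictor())
        assert len(series) == 0  # all windows invalid -> empty series


class TestPipeline:
    def test_raw_estimate_count_oracle(self):
        rec = synth_ppg_segment(65.0, 1.0, 120.0, 100.0)
        series = run_pipeline(rec, SurrogatePredictor())
        assert len(series) == 116  # floor((120-5)/1)+1
        assert np.all(np.isnan(series.smoothed[:19]))
        assert np.isfinite(series.smoothed[19])

    def test_one_hertz_output_axis(self):
        rec = synth_ppg_segment(65.0, 1.0, 30.0, 100.0)
        series = run_pipeline(rec, SurrogatePredictor())
        assert np.allclose(np.diff(series.times), 1.0)

    def test_oracle_identity_reproduces_staircase(self, subject, oracle_series):
        expect = 100.0 * subject.reserve_at(oracle_series.times)
        assert np.array_equal(oracle_series.raw, expect)

    def test_streaming_and_batch_bit_identical(self):
        rec = synth_ppg_segment(70.0, 0.8, 45.0, 31.25, noise_sd=0.02,
                                rng=np.random.default_rng(11))
        predictor = SurrogatePredictor()
        batch = run_pipeline(rec, predictor)
        ticks = list(stream_pipeline(rec, predictor))
        assert np.array_equal(batch.times, [t for t, _, _ in ticks])
        assert np.array_equal(batch.raw, [r for _, r, _ in ticks], equal_nan=True)
        assert np.array_equal(batch.smoothed, [s for _, _, s in ticks], equal_nan=True)

    def test_causality_by_truncation_through_pipeline(self):
        rec = synth_ppg_segment(65.0, 1.0, 60.0, 31.25, noise_sd=0.02,
                                rng=np.random.default_rng(4))
        predictor = SurrogatePredictor()
        full = run_pipeline(rec, predictor)
        cut = WaveformRecord(rec.samples[:int(30 * 31.25) + 1], 31.25)
        part = run_pipeline(cut, predictor)
        n = len(part)
        assert np.array_equal(part.times, full.times[:n])
        assert np.array_equal(part.raw, full.raw[:n], equal_nan=True)
        assert np.array_equal(part.smoothed, full.smoothed[:n], equal_nan=True)

    def test_estimates_within_percent_range(self, oracle_series):
        for arr in (oracle_series.raw, oracle_series.smoothed):
            finite = arr[np.isfinite(arr)]
            assert finite.min() >= 0.0 and finite.max() <= 100.0

    def test_out_of_range_series_rejected(self):
        with pytest.raises(ContractError):
            CRMSeries(times=np.array([5.0]), raw=np.array([120.0]),
                      smoothed=np.array([np.nan]))
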