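import math

import numpy as np
import pytest

from oscillaquant import synth, traces
from oscillaquant.stack import TimeLapseStack
from oscillaquant.traces import (
    NOT_PROMINENT,
    IntensityTrace,
    adjust_to_initial_intensity,
    autocorrelation,
    autocorrelation_period,
    correct_photobleaching,
    cycle_mean_intensity,
    detect_peaks,
    extract_trace,
    peak_interval_period_estimate,
    peak_interval_periods,
    summarize_cells,
)


def corrected(realization):
    """Mark a generator trace as bleach-corrected (for noise/jitter cases
    generated without bleaching)."""
    tr = realization.trace
    return tr.with_values(tr.values, provenance="bleach_corrected")


class TestExtractTrace:
    def test_uniform_frames_minus_background(self):
        data = np.full((5, 10, 10), 100.0)
        data[:, 7:, 7:] = 20.0
        stack = TimeLapseStack(data, frame_interval=30)
        cell = np.zeros((10, 10), bool)
        cell[2:5, 2:5] = True
        bg = np.zeros((10, 10), bool)
        bg[8:, 8:] = True
        tr = extract_trace(stack, cell, bg)
        assert np.allclose(tr.values, 80.0)
        assert tr.provenance == "raw"

    def test_matches_generator_recorded_means(self, regular_trace):
        # paint the per-frame trace value uniformly into a small movie
        vals = regular_trace.trace.values
        data = np.tile(vals[:, None, None], (1, 8, 8))
        stack = TimeLapseStack(data, frame_interval=30)
        cell = np.zeros((8, 8), bool)
        cell[2:6, 2:6] = True
        tr = extract_trace(stack, cell)
        assert np.allclose(tr.values, vals)

    def test_single_pixel_mask_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 100, (6, 5, 5))
        stack = TimeLapseStack(data, frame_interval=30)
        cell = np.zeros((5, 5), bool)
        cell[3, 1] = True
        tr = extract_trace(stack, cell)
        assert np.array_equal(tr.values, data[:, 3, 1])

    def test_empty_mask_and_overlap_rejected(self):
        stack = TimeLapseStack(np.ones((4, 5, 5)), frame_interval=30)
        empty = np.zeros((5, 5), bool)
        cell = np.zeros((5, 5), bool)
        cell[1, 1] = True
        with pytest.raises(ValueError, match="empty"):
            extract_trace(stack, empty)
        with pytest.raises(ValueError, match="overlap"):
            extract_trace(stack, cell, cell)


class TestPhotobleachCorrection:
    def test_recovers_unbleached_truth_within_3pct_rms(self):
        truth = synth.TraceGroundTruth(
            true_period=180, amplitude=300, baseline=600,
            bleach_time_constant=600.0, seed=0,
        )
        real = synth.make_oscillatory_trace(truth, 1800, 30)
        corr = correct_photobleaching(real.trace)
        rms = np.sqrt(np.mean((corr.values - real.unbleached) ** 2))
        assert rms / real.unbleached.mean() < 0.03
        assert corr.provenance == "bleach_corrected"

    def test_constant_trace_returned_unchanged(self):
        tr = IntensityTrace(np.arange(20) * 30.0, np.full(20, 50.0), 30.0)
        corr = correct_photobleaching(tr)
        assert np.allclose(corr.values, 50.0)

    def test_no_decay_input_unchanged_within_1pct(self, regular_trace):
        corr = correct_photobleaching(regular_trace.trace)
        assert np.allclose(corr.values, regular_trace.trace.values, rtol=0.01)

    def test_idempotent_within_1pct_rms(self):
        truth = synth.TraceGroundTruth(
            true_period=180, amplitude=300, baseline=600,
            bleach_time_constant=600.0, seed=1,
        )
        real = synth.make_oscillatory_trace(truth, 1800, 30)
        once = correct_photobleaching(real.trace)
        twice = correct_photobleaching(once)
        rms = np.sqrt(np.mean((twice.values - once.values) ** 2))
        assert rms / once.values.mean() < 0.01

    def test_mostly_nonpositive_trace_rejected(self):
        vals = np.zeros(20)
        vals[:5] = 10.0
        tr = IntensityTrace(np.arange(20) * 30.0, vals, 30.0)
        with pytest.raises(ValueError, match="non-positive"):
            correct_photobleaching(tr)


class TestAdjustToInitialIntensity:
    def test_decaying_frame_means_equalized(self):
        data = np.stack([np.full((4, 4), v) for v in (100.0, 80.0, 64.0)])
        stack = TimeLapseStack(data, frame_interval=30)
        out = adjust_to_initial_intensity(stack)
        assert np.allclose(out.data.mean(axis=(1, 2)), 100.0)
        assert np.array_equal(out.data[0], data[0])

    def test_constant_stack_unchanged(self):
        stack = TimeLapseStack(np.full((4, 5, 5), 9.0), frame_interval=30)
        out = adjust_to_initial_intensity(stack)
        assert np.allclose(out.data, 9.0)

    def test_bleached_synthetic_movie_flat_after_adjustment(self):
        decay = np.exp(-np.arange(10) * 30 / 600.0)
        rng = np.random.default_rng(2)
        base = rng.uniform(50, 150, (8, 8))
        data = np.stack([base * d for d in decay])
        out = adjust_to_initial_intensity(TimeLapseStack(data, frame_interval=30))
        means = out.data.mean(axis=(1, 2))
        assert np.allclose(means, means[0], rtol=0.005)

    def test_zero_mean_frame_rejected(self):
        data = np.ones((3, 4, 4))
        data[1] = 0.0
        with pytest.raises(ValueError, match="frame 1"):
            adjust_to_initial_intensity(TimeLapseStack(data, frame_interval=30))


class TestPeakDetection:
    def test_noiseless_raised_cosine_peaks_180s_apart(self, regular_trace):
        peaks = detect_peaks(corrected(regular_trace))
        assert 8 <= len(peaks) <= 10
        assert np.allclose(np.diff(peaks), 180.0)

    def test_monotone_ramp_and_constant_have_no_peaks(self):
        t = np.arange(20) * 30.0
        ramp = IntensityTrace(t, np.linspace(0, 10, 20), 30.0,
                              provenance="bleach_corrected")
        const = IntensityTrace(t, np.full(20, 3.0), 30.0,
                               provenance="bleach_corrected")
        assert len(detect_peaks(ramp)) == 0
        assert len(detect_peaks(const)) == 0


class TestPeakIntervals:
    def test_explicit_peaks(self):
        res = peak_interval_periods([60.0, 240.0, 420.0])
        assert np.allclose(res.intervals, [180, 180])
        assert res.mean_period == 180.0

    def test_single_peak_not_prominent(self):
        res = peak_interval_periods([60.0])
        assert res.mean_period is NOT_PROMINENT

    def test_jittered_interval_cv_matches_truth(self):
        truth = synth.TraceGroundTruth(
            true_period=180, amplitude=4, baseline=10,
            period_jitter_cv=0.2, seed=13,
        )
        real = synth.make_oscillatory_trace(truth, 60 * 180.0, 30.0)
        peaks = detect_peaks(corrected(real))
        res = peak_interval_periods(peaks)
        cv = res.intervals.std() / res.intervals.mean()
        assert cv == pytest.approx(0.2, abs=0.05)


class TestAutocorrelationPeriod:
    def test_noiseless_trace_period_and_score(self, regular_trace):
        est = autocorrelation_period(corrected(regular_trace))
        assert est.period == 180.0
        assert est.detectability_score > 0.9
        assert est.method == "autocorrelation"

    def test_lag_zero_autocorrelation_is_one(self, regular_trace):
        acf = autocorrelation(corrected(regular_trace))
        assert acf[0] == 1.0

    def test_white_noise_not_prominent(self):
        rng = np.random.default_rng(42)
        n_np = 0
        for _ in range(50):
            tr = IntensityTrace(
                np.arange(60) * 30.0, rng.normal(10, 1, 60), 30.0,
                provenance="bleach_corrected",
            )
            est = autocorrelation_period(tr, min_detectability=0.2)
            n_np += not est.is_prominent
        assert n_np >= 47  # >= 95% of pure-noise traces rejected

    def test_constant_trace_not_prominent_score_zero(self):
        tr = IntensityTrace(np.arange(20) * 30.0, np.full(20, 4.0), 30.0,
                            provenance="bleach_corrected")
        est = autocorrelation_period(tr)
        assert est.period is NOT_PROMINENT
        assert est.detectability_score == 0.0

    def test_max_lag_beyond_half_duration_rejected(self, regular_trace):
        with pytest.raises(ValueError, match="half"):
            autocorrelation_period(corrected(regular_trace), max_lag=1000.0)

    def test_agrees_with_peak_intervals_on_clean_traces(self, regular_trace):
        tr = corrected(regular_trace)
        ac = autocorrelation_period(tr)
        pk = peak_interval_period_estimate(tr)
        assert abs(float(ac.period) - float(pk.period)) <= tr.dt

    @pytest.mark.parametrize("gain,offset", [(3.0, 0.0), (1.0, 50.0), (0.5, -2.0)])
    def test_invariant_to_affine_transforms(self, regular_trace, gain, offset):
        truth = synth.TraceGroundTruth(
            true_period=180, amplitude=4, baseline=10, noise_sd=0.5, seed=21
        )
        real = synth.make_oscillatory_trace(truth, 1800, 30)
        tr = corrected(real)
        tr2 = tr.with_values(gain * tr.values + offset)
        a = autocorrelation_period(tr)
        b = autocorrelation_period(tr2)
        assert a.period == b.period
        assert a.detectability_score == pytest.approx(b.detectability_score)


class TestCycleMeans:
    def test_constant_trace_with_external_period(self):
        tr = IntensityTrace(np.arange(30) * 30.0, np.full(30, 5.0), 30.0,
                            provenance="bleach_corrected")
        means = cycle_mean_intensity(tr, 180.0)
        assert len(means) > 0
        assert np.allclose(means, 5.0)

    def test_raised_cosine_cycle_mean_is_baseline_plus_half_amplitude(
        self, regular_trace
    ):
        means = cycle_mean_intensity(corrected(regular_trace), 180.0)
        assert len(means) >= 8
        assert np.allclose(means, 12.0, atol=0.35)  # 10 + 4/2, discretized

    def test_trace_shorter_than_period_gives_empty(self):
        tr = IntensityTrace(np.arange(5) * 30.0, np.full(5, 2.0), 30.0,
                            provenance="bleach_corrected")
        assert len(cycle_mean_intensity(tr, 600.0)) == 0

    def test_not_prominent_period_rejected(self):
        tr = IntensityTrace(np.arange(10) * 30.0, np.full(10, 2.0), 30.0,
                            provenance="bleach_corrected")
        est = traces.PeriodEstimate(NOT_PROMINENT, "autocorrelation", 0.0, 0)
        with pytest.raises(ValueError, match="NOT_PROMINENT"):
            cycle_mean_intensity(tr, est)


class TestSummaries:
    def test_identical_periods(self):
        ests = [traces.PeriodEstimate(180.0, "autocorrelation", 0.9, 9)] * 3
        s = summarize_cells(ests)
        assert s.mean_period == 180.0
        assert s.sd_period == 0.0

    def test_mixed_detectable_and_not_prominent(self):
        ests = [
            traces.PeriodEstimate(180.0, "autocorrelation", 0.9, 9),
            traces.PeriodEstimate(NOT_PROMINENT, "autocorrelation", 0.1, 0),
        ]
        s = summarize_cells(ests)
        assert s.mean_period == 180.0
        assert s.fraction_not_prominent == 0.5

    def test_all_not_prominent_flagged(self):
        ests = [traces.PeriodEstimate(NOT_PROMINENT, "autocorrelation", 0.0, 0)]
        s = summarize_cells(ests)
        assert s.mean_period is NOT_PROMINENT

    def test_population_recovery_within_one_frame(self):
        ests = []
        for i in range(60):
            truth = synth.TraceGroundTruth(
                true_period=180, amplitude=300, baseline=600,
                noise_sd=90, seed=300 + i,
            )
            real = synth.make_oscillatory_trace(truth, 1800, 30)
            ests.append(autocorrelation_period(corrected(real)))
        s = summarize_cells(ests)
        assert s.mean_period == pytest.approx(180.0, abs=30.0)


class TestRobustnessOrdering:
    def test_autocorrelation_tighter_than_interval_distribution(self):
        """On small-amplitude jittered traces the per-cell autocorrelation
        periods disperse less than the raw adjacent-peak intervals."""
        ac, intervals = [], []
        for i in range(60):
            truth = synth.TraceGroundTruth(
                true_period=180, amplitude=60, baseline=600,
                noise_sd=18, period_jitter_cv=0.3, seed=1000 + i,
            )
            real = synth.make_oscillatory_trace(truth, 1800, 30)
            tr = corrected(real)
            est = autocorrelation_period(tr)
            if est.is_prominent:
                ac.append(float(est.period))
            intervals.extend(peak_interval_periods(detect_peaks(tr)).intervals)
        assert len(ac) >= 10
        assert np.std(ac) <= np.std(intervals)
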