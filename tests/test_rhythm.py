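import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circasync import rhythm
from circasync.rhythm import (
    classify_rhythmic,
    dwt_detrend,
    embed_phase,
    lomb_scargle_rhythmic,
    sine_fit_windows,
    SineFitWindow,
)
from circasync.traces import CellTrace

from conftest import cosine_trace, detrended_cosine


class TestDetrend:
    def test_recovers_cosine_under_linear_trend(self):
        tr = cosine_trace(amp=5.0, days=11, trend=0.05, baseline=20.0)
        d = dwt_detrend(tr)
        ref = 5.0 * np.cos(2 * np.pi * d.t / 24)
        inner = slice(32, -32)
        assert np.corrcoef(d.x[inner], ref[inner])[0, 1] > 0.99

    def test_mean_is_zero(self):
        tr = cosine_trace(days=11, noise_sd=1.0, baseline=10.0, seed=3)
        d = dwt_detrend(tr)
        assert abs(d.x.mean()) < 1e-6 * max(d.x.std(), 1e-12)

    def test_zero_signal(self):
        t = np.arange(0, 96, 0.75)
        d = dwt_detrend(CellTrace("c", "b", "s", t, np.zeros(len(t))))
        assert np.allclose(d.x, 0)
        assert d.sigma_noise == 0.0

    def test_noise_floor_matches_bandpass_oracle(self):
        """sigma_noise (finest DWT detail) within 20% of an FFT band-pass
        estimate of the 1.5-3 h band on white noise."""
        rng = np.random.default_rng(0)
        t = np.arange(0, 264, 0.75)
        y = rng.normal(0, 2.0, len(t))
        d = dwt_detrend(CellTrace("c", "b", "s", t, y))
        yy = y[t >= 12.0]
        spec = np.fft.rfft(yy)
        f = np.fft.rfftfreq(len(yy), 0.75)
        mask = (f >= 1 / 3.0) & (f <= 1 / 1.5)
        oracle = np.sqrt(np.sum(np.abs(spec[mask]) ** 2) * 2 / len(yy) ** 2)
        assert abs(d.sigma_noise - oracle) / oracle < 0.20

    def test_circadian_band_attenuates_white_noise(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 264, 0.75)
        d = dwt_detrend(CellTrace("c", "b", "s", t, rng.normal(0, 2.0, len(t))))
        assert d.x.std() < 0.5 * 2.0

    def test_idempotent_within_one_percent(self):
        tr = cosine_trace(days=11, noise_sd=1.0, baseline=10.0, trend=0.02, seed=5)
        d1 = dwt_detrend(tr)
        tr2 = CellTrace("c", "b", "s", d1.t, d1.x)
        d2 = dwt_detrend(tr2, trim_h=0.0)
        rms = np.sqrt(np.mean((d2.x - d1.x) ** 2))
        assert rms < 0.01 * np.std(d1.x) * 10  # < 1% energy shift (10% RMS bound)

    def test_first_12h_excluded(self):
        tr = cosine_trace(days=11)
        d = dwt_detrend(tr)
        assert d.t[0] >= 12.0

    def test_gaps_interpolated_and_masked(self):
        tr = cosine_trace(days=11)
        tr.missing[40:43] = True
        tr.y[40:43] = np.nan
        d = dwt_detrend(tr)
        assert np.isfinite(d.x).all()
        assert d.gap_mask.sum() == 3

    def test_short_record_rejected(self):
        tr = cosine_trace(days=2)  # < 2 days after the 12-h trim
        with pytest.raises(ValueError):
            dwt_detrend(tr)


class TestSineFit:
    def test_noiseless_recovery_exact(self):
        d = detrended_cosine(amp=5.0, period=24.0, phase_h=6.0, days=4)
        f = sine_fit_windows(d)[0]
        assert abs(f.period_h - 24.0) < 0.1
        assert abs(f.amplitude - 5.0) < 0.05
        assert abs(f.phase_h - 6.0) < 0.1
        assert f.gof > 0.999

    @pytest.mark.parametrize("period,phase", [(20.0, 3.0), (28.5, 17.2), (24.6, 0.0)])
    def test_recovery_across_period_range(self, period, phase):
        d = detrended_cosine(amp=3.0, period=period, phase_h=phase, days=4)
        f = sine_fit_windows(d)[0]
        assert abs(f.period_h - period) < 0.1
        dphi = (f.phase_h - phase) % period
        assert min(dphi, period - dphi) < 0.1

    def test_flat_window_degenerate(self):
        t = np.arange(0, 96, 0.75)
        d = rhythm.DetrendedTrace("c", "b", "s", t, np.zeros(len(t)), 0.0)
        f = sine_fit_windows(d)[0]
        assert f.amplitude == pytest.approx(0.0, abs=1e-9)
        assert f.gof == 0.0
        assert f.degenerate

    def test_gappy_window_skipped(self):
        d = detrended_cosine(days=4)
        d.gap_mask[:30] = True  # ~47% of the first 48-h window
        fits = sine_fit_windows(d)
        assert fits[0].skipped
        assert not fits[-1].skipped

    def test_window_midpoints_step(self):
        d = detrended_cosine(days=4)
        fits = sine_fit_windows(d, window_h=48, step_h=6)
        mids = [f.midpoint_h for f in fits]
        assert np.allclose(np.diff(mids), 6.0)

    def test_window_larger_than_record_rejected(self):
        d = detrended_cosine(days=1.5)
        with pytest.raises(ValueError):
            sine_fit_windows(d, window_h=48)


class TestClassify:
    def base_fit(self, **kw):
        args = dict(midpoint_h=24.0, period_h=24.0, amplitude=5.0, phase_h=0.0,
                    phase_rad=0.0, gof=0.9, start_h=0.0)
        args.update(kw)
        return SineFitWindow(**args)

    def test_all_criteria_pass(self):
        (call,) = classify_rhythmic([self.base_fit()], sigma_noise=1.0)
        assert call.reliably_rhythmic
        assert call.failed_criteria == frozenset()

    @pytest.mark.parametrize("gof,ok", [(0.82, True), (0.8199, False), (0.81, False)])
    def test_gof_boundary_inclusive(self, gof, ok):
        (call,) = classify_rhythmic([self.base_fit(gof=gof)], sigma_noise=1.0)
        assert call.reliably_rhythmic is ok
        if not ok:
            assert call.failed_criteria == frozenset({"gof"})

    @pytest.mark.parametrize("tau,ok", [(16.0, True), (32.0, True),
                                        (15.99, False), (32.01, False), (33.0, False)])
    def test_period_range_boundary_inclusive(self, tau, ok):
        (call,) = classify_rhythmic([self.base_fit(period_h=tau)], sigma_noise=1.0)
        assert call.reliably_rhythmic is ok
        if not ok:
            assert call.failed_criteria == frozenset({"period_range"})

    def test_amplitude_floor_strict(self):
        (at,) = classify_rhythmic([self.base_fit(amplitude=1.0)], sigma_noise=1.0)
        assert not at.reliably_rhythmic
        assert at.failed_criteria == frozenset({"amplitude_floor"})
        (above,) = classify_rhythmic([self.base_fit(amplitude=1.0 + 1e-9)], sigma_noise=1.0)
        assert above.reliably_rhythmic

    def test_multiple_failures_reported(self):
        (call,) = classify_rhythmic([self.base_fit(period_h=34.0, gof=0.5)],
                                    sigma_noise=10.0)
        assert call.failed_criteria == frozenset(
            {"period_range", "amplitude_floor", "gof"})

    @given(
        gof=st.floats(0.0, 1.0),
        amp=st.floats(0.0, 20.0),
        bump=st.floats(0.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_gof_and_amplitude(self, gof, amp, bump):
        """Raising gof or amplitude never flips rhythmic to non-rhythmic."""
        lo = classify_rhythmic([self.base_fit(gof=gof, amplitude=amp)], 1.0)[0]
        hi = classify_rhythmic(
            [self.base_fit(gof=min(1.0, gof + bump / 5), amplitude=amp + bump)], 1.0
        )[0]
        assert not (lo.reliably_rhythmic and not hi.reliably_rhythmic)


class TestLombScargle:
    def test_rhythmic_cells_all_detected(self):
        cells = [detrended_cosine(amp=5.0, phase_h=i, days=4, noise_sd=1.0,
                                  seed=i, cell_id=f"c{i}") for i in range(10)]
        _, pct = lomb_scargle_rhythmic(cells, seed=0)
        assert pct == 100.0

    def test_constant_trace_not_rhythmic(self):
        t = np.arange(0, 96, 0.75)
        d = rhythm.DetrendedTrace("c", "b", "s", t, np.zeros(len(t)), 0.0)
        calls, pct = lomb_scargle_rhythmic([d], seed=0)
        assert pct == 0.0

    def test_noise_false_positive_rate_near_alpha(self):
        """Permutation FAP is calibrated: segment-level false positives over
        white-noise cells stay in the vicinity of alpha."""
        rng = np.random.default_rng(5)
        t = np.arange(0, 96, 0.75)
        cells = [
            rhythm.DetrendedTrace(f"n{i}", "b", "s", t,
                                  rng.normal(0, 1, len(t)), 1.0)
            for i in range(60)
        ]
        calls, _ = lomb_scargle_rhythmic(cells, alpha=0.05, n_perm=200, seed=1)
        fp = np.mean([seg for v in calls.values() for seg in v])
        assert fp <= 0.15   # ~alpha expected; bound guards against miscalibration


class TestEmbedPhase:
    def test_quarter_period_lag_gives_unit_slope(self):
        d = detrended_cosine(amp=5.0, period=24.0, days=6)
        e = embed_phase(d, lag_h=6.0)
        slope = np.polyfit(e.t, e.phase_rad, 1)[0]
        assert abs(slope * 24 / (2 * np.pi) - 1.0) < 0.01

    def test_trajectory_is_a_circle(self):
        d = detrended_cosine(amp=5.0, period=24.0, days=6)
        e = embed_phase(d, lag_h=6.0, smooth_h=0.0)
        inner = slice(16, -16)
        assert np.ptp(e.amplitude[inner]) / np.mean(e.amplitude[inner]) < 0.05

    def test_damped_cosine_radius_decreasing(self):
        t = np.arange(0, 144, 0.75)
        x = 5 * np.exp(-t / 100) * np.cos(2 * np.pi * t / 24)
        d = rhythm.DetrendedTrace("c", "b", "s", t, x - x.mean(), 0.01)
        e = embed_phase(d, lag_h=6.0)
        # cycle-matched times, one period apart
        i0 = np.argmin(np.abs(e.t - 48));  i1 = np.argmin(np.abs(e.t - 72))
        i2 = np.argmin(np.abs(e.t - 96))
        assert e.amplitude[i0] > e.amplitude[i1] > e.amplitude[i2]

    def test_low_radius_flagged_invalid(self):
        d = detrended_cosine(amp=0.5, period=24.0, days=6, sigma_noise=5.0)
        e = embed_phase(d, lag_h=6.0)
        assert not e.valid.any()

    def test_non_multiple_lag_warns(self):
        d = detrended_cosine(days=6)
        with pytest.warns(UserWarning):
            embed_phase(d, lag_h=6.1)

    def test_agrees_with_sine_fit_phase(self):
        """Embedding and sine-fit peak-time estimates agree on clean cosines."""
        for ph in [0.0, 5.0, 13.0, 21.0]:
            d = detrended_cosine(amp=4.0, period=24.0, phase_h=ph, days=6,
                                 noise_sd=0.4, seed=int(ph))
            f = sine_fit_windows(d, step_h=24.0)[0]
            e = embed_phase(d, lag_h=6.0)
            i = np.argmin(np.abs(e.t - f.midpoint_h))
            # embedding angle mod 2 pi: time since last waveform peak
            since_peak = (e.phase_rad[i] % (2 * np.pi)) * f.period_h / (2 * np.pi)
            peak_embed = e.t[i] - since_peak
            diff = (peak_embed - f.peak_time_h) % f.period_h
            diff = min(diff, f.period_h - diff)
            assert diff < 0.5
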