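"""fEPSP measurement, time courses, I/O curves and train analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import slicephys as sp
from slicephys.core import Sweep, SweepSet
from slicephys.synth import fepsp_waveform, io_response_mv

FS = 20000.0


def vee_sweep(peak_mv=-1.0, artifact_ms=5.0, ramp_ms=10.0, fs=FS):
    """Artifact window of zeros, then an exact V: line to peak and back."""
    n_ramp = int(ramp_ms * 1e-3 * fs)
    down = np.linspace(0.0, peak_mv, n_ramp + 1)
    up = np.linspace(peak_mv, 0.0, n_ramp + 1)[1:]
    pre = np.zeros(int(artifact_ms * 1e-3 * fs))
    v = np.concatenate([pre, down, up, np.zeros(n_ramp)])
    return Sweep(v, fs, 0.0, 35.0, "baseline")


def series(amps, block="baseline", t0=0.0, dt=30.0, noise=0.0, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    sweeps = []
    for i, a in enumerate(amps):
        v = fepsp_waveform(50.0, fs, 5.0, 1.5, 8.0, a)
        if noise:
            v = v + rng.normal(0, noise, v.size)
        sweeps.append(Sweep(v, fs, t0 + i * dt, 35.0, block))
    return sweeps


class TestMeasureFEPSP:
    def test_linear_descending_phase_slope(self):
        cfg = sp.RunConfig(fepsp_smooth_ms=0.0)
        m = sp.measure_fepsp(vee_sweep(), cfg)
        assert m.valid
        assert m.peak_amplitude_mv == pytest.approx(-1.0, rel=0.01)
        assert m.slope_10_90_mv_per_ms == pytest.approx(0.1, rel=0.01)

    def test_scaling_sweep_scales_peak_and_slope(self, cfg):
        s1 = vee_sweep()
        s2 = Sweep(2.0 * s1.voltage_mv, FS, 0.0, 35.0, "baseline")
        m1, m2 = sp.measure_fepsp(s1, cfg), sp.measure_fepsp(s2, cfg)
        assert m2.peak_amplitude_mv == pytest.approx(2 * m1.peak_amplitude_mv, rel=1e-9)
        assert m2.slope_10_90_mv_per_ms == pytest.approx(2 * m1.slope_10_90_mv_per_ms, rel=1e-9)

    def test_flat_sweep_invalid(self, cfg):
        m = sp.measure_fepsp(Sweep(np.zeros(2000), FS, 0.0, 35.0, "baseline"), cfg)
        assert not m.valid

    def test_subthreshold_peak_invalid(self, cfg):
        v = fepsp_waveform(50.0, FS, 5.0, 1.5, 8.0, -0.005)  # below noise floor
        assert not sp.measure_fepsp(Sweep(v, FS, 0.0, 35.0, "baseline"), cfg).valid

    def test_noiseless_waveform_slope_matches_dense_oracle(self):
        cfg = sp.RunConfig(fepsp_smooth_ms=0.0)
        fs = 200000.0  # fine grid so crossing-sample discretisation is negligible
        peak_mv, rise, decay, art = -0.4, 1.5, 8.0, 5.0
        v = fepsp_waveform(50.0, fs, art, rise, decay, peak_mv)
        m = sp.measure_fepsp(Sweep(v, fs, 0.0, 35.0, "baseline"), cfg)
        # oracle: closed-form waveform evaluated on a 1 MHz grid, same
        # 10-90 definition computed independently
        t = np.arange(0, 45.0, 1e-3)  # ms after artifact window
        shape = np.exp(-t / decay) - np.exp(-t / rise)
        w = peak_mv * shape / shape.max()
        peak = w.min()
        i10 = np.flatnonzero(w <= 0.1 * peak)[0]
        i90 = np.flatnonzero(w <= 0.9 * peak)[0]
        sel = slice(i10, i90 + 1)
        slope = abs(np.polyfit(t[sel], w[sel], 1)[0])
        assert m.slope_10_90_mv_per_ms == pytest.approx(slope, rel=0.02)


class TestPairAverage:
    def test_non_overlapping_pairs(self):
        vals, odd = sp.pair_average(np.array([100.0, 110.0, 120.0, 130.0]))
        assert np.allclose(vals, [105.0, 125.0])
        assert not odd

    def test_single_element_flagged(self):
        vals, odd = sp.pair_average(np.array([100.0]))
        assert np.allclose(vals, [100.0]) and odd

    @given(st.integers(1, 8))
    def test_double_pairing_equals_blocks_of_four(self, k):
        series_ = np.arange(4.0 * k)
        once, _ = sp.pair_average(series_)
        twice, _ = sp.pair_average(once)
        blocks = series_.reshape(-1, 4).mean(axis=1)
        assert np.allclose(twice, blocks)


class TestTimecourse:
    def test_identical_sweeps_normalize_to_100(self, cfg):
        sweeps = SweepSet(
            series([-0.4] * 8, "baseline")
            + series([-0.4] * 10, "post", t0=8 * 30.0 + 60.0)
        )
        tc = sp.build_timecourse(sweeps, cfg)
        assert np.allclose(tc.normalized_percent, 100.0, rtol=1e-9)
        assert tc.magnitude_percent == pytest.approx(100.0, rel=1e-9)
        assert tc.direction == "none"

    def test_baseline_normalization_identity(self, cfg):
        p = sp.EvokedSimParams(n_pulses=0, plasticity_factor=1.3, seed=0)
        tc = sp.build_timecourse(sp.simulate_evoked_series(p), cfg)
        baseline_norm = tc.normalized_percent[tc.times_min <= 0]
        # the 3-min normalization window is the last 6 sweeps of baseline
        assert np.mean(baseline_norm[-6:]) == pytest.approx(100.0, rel=1e-9)

    def test_programmed_factor_1454_reports_145_4(self, cfg):
        p = sp.EvokedSimParams(n_pulses=0, plasticity_factor=1.454, seed=0)
        tc = sp.build_timecourse(sp.simulate_evoked_series(p), cfg)
        assert tc.magnitude_percent == pytest.approx(145.4, rel=1e-9)
        assert tc.direction == "LTP"

    def test_depression_factor_recovered_under_noise(self):
        cfg = sp.RunConfig()
        mags = []
        for seed in range(6):
            p = sp.EvokedSimParams(
                n_pulses=0, plasticity_factor=0.6, noise_sd_mv=0.04, seed=seed
            )
            mags.append(sp.build_timecourse(sp.simulate_evoked_series(p), cfg).magnitude_percent)
        assert np.mean(mags) == pytest.approx(60.0, abs=5.0)

    def test_scale_invariance_of_normalized_quantities(self, cfg):
        p = sp.EvokedSimParams(n_pulses=0, plasticity_factor=1.2, noise_sd_mv=0.0, seed=0)
        sweeps = sp.simulate_evoked_series(p)
        scaled = SweepSet(
            [
                Sweep(3.7 * s.voltage_mv, s.sampling_rate_hz, s.stimulus_time_s,
                      s.stimulus_current_ua, s.block)
                for s in sweeps
            ]
        )
        tc1, tc2 = sp.build_timecourse(sweeps, cfg), sp.build_timecourse(scaled, cfg)
        assert np.allclose(tc1.normalized_percent, tc2.normalized_percent, rtol=1e-9)
        assert tc1.magnitude_percent == pytest.approx(tc2.magnitude_percent, rel=1e-9)

    def test_no_baseline_sweeps_rejected(self, cfg):
        sweeps = SweepSet(series([-0.4] * 10, "post"))
        with pytest.raises(ValueError):
            sp.build_timecourse(sweeps, cfg)


class TestIOCurve:
    def test_threshold_is_35_percent_of_max_response_stimulus(self, cfg):
        p = sp.IOSimParams(noise_sd_mv=0.0)
        curve = sp.build_io_curve(sp.simulate_io(p), cfg)
        assert curve.stimulus_levels_ua[-1] == 100.0
        assert curve.threshold_stimulus_ua == pytest.approx(35.0)

    def test_tied_amplitudes_use_largest_stimulus(self, cfg):
        sweeps = []
        for lv in (10.0, 20.0, 40.0):
            for s in series([-0.4] * 2):
                sweeps.append(Sweep(s.voltage_mv, FS, len(sweeps) * 10.0, lv, "io_pre"))
        curve = sp.build_io_curve(SweepSet(sweeps), cfg)
        assert curve.threshold_stimulus_ua == pytest.approx(0.35 * 40.0)

    def test_noiseless_means_match_closed_form(self):
        cfg = sp.RunConfig(fepsp_smooth_ms=0.0)
        p = sp.IOSimParams(noise_sd_mv=0.0, stimulus_levels_ua=np.array([10.0, 30.0, 60.0, 100.0]))
        curve = sp.build_io_curve(sp.simulate_io(p), cfg)
        expected = io_response_mv(p, curve.stimulus_levels_ua)
        assert np.allclose(curve.mean_amplitude_mv, expected, rtol=0.005)

    def test_noiseless_monotone_model_gives_monotone_means(self, cfg):
        p = sp.IOSimParams(noise_sd_mv=0.0)
        curve = sp.build_io_curve(sp.simulate_io(p), cfg)
        assert np.all(np.diff(curve.mean_amplitude_mv) > 0)

    def test_single_level_rejected(self, cfg):
        sweeps = SweepSet(
            [Sweep(fepsp_waveform(50.0, FS, 5.0, 1.5, 8.0, -0.4), FS, 0.0, 20.0, "io_pre")]
        )
        with pytest.raises(ValueError):
            sp.build_io_curve(sweeps, cfg)


class TestAnalyzeTrain:
    def test_constant_train_ratio_one(self, cfg):
        sweeps = SweepSet(series([-0.4] * 20, "induction", dt=1.0))
        tr = sp.analyze_train(sweeps, cfg)
        assert np.allclose(tr.normalized, 1.0, rtol=1e-9)
        assert tr.last5_first5_ratio == pytest.approx(1.0, rel=1e-9)

    def test_linear_growth_ratio_from_arithmetic(self, cfg):
        amps = [-0.05 * i for i in range(1, 601)]
        sweeps = SweepSet(series(amps, "induction", dt=1.0))
        tr = sp.analyze_train(sweeps, cfg)
        assert tr.last5_first5_ratio == pytest.approx(598.0 / 3.0, rel=1e-6)

    def test_geometric_growth_matches_closed_form(self, cfg):
        g = 1.002
        p = sp.EvokedSimParams(
            n_baseline_sweeps=2, n_post_sweeps=2, n_pulses=600, train_growth=g, seed=0
        )
        tr = sp.analyze_train(sp.simulate_evoked_series(p), cfg)
        amps = g ** np.arange(600)
        expected = amps[595:600].mean() / amps[:5].mean()  # = g**595
        assert tr.last5_first5_ratio == pytest.approx(expected, rel=1e-6)
        assert tr.tail_mean_last_100 == pytest.approx(amps[-100:].mean(), rel=1e-6)

    def test_short_train_rejected(self, cfg):
        sweeps = SweepSet(series([-0.4] * 5, "induction", dt=1.0))
        with pytest.raises(ValueError):
            sp.analyze_train(sweeps, cfg)
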