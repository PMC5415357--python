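"""CAP pipeline: peak detection, window definition, area, normalization."""

from dataclasses import replace

import numpy as np
import pytest

from axatp.cap import (
    CapSweep,
    CapWindow,
    build_cap_series,
    cap_area,
    define_window,
    detect_peaks,
    mean_sweep,
)
from axatp.capsim import render_sweep, simulate_caps
from axatp.params import CapShapeParams, StimProtocol
from axatp.workflows import cap_series


def make_sweep(v, t_ms=None, rate=20_000, stim_time=0.0):
    if t_ms is None:
        step = 1000.0 / rate
        t_ms = (np.arange(len(v)) - 20) * step
    return CapSweep(stim_time_s=stim_time, t_ms=t_ms, v_mV=np.asarray(v, float),
                    sample_rate=rate)


def synthetic_baseline_sweep(noise=0.0, rng=None, rate=20_000):
    shape = replace(CapShapeParams(), noise_sd=noise, sample_rate=rate)
    step = 1000.0 / rate
    n_pre, n_post = int(1.0 / step), int(5.0 / step)
    t_ms = (np.arange(n_pre + n_post + 1) - n_pre) * step
    v = render_sweep(t_ms, shape)
    if noise and rng is not None:
        v = v + rng.normal(0, noise, v.shape)
    return make_sweep(v, t_ms=t_ms, rate=rate), shape


class TestDetectPeaks:
    def test_noiseless_three_peak_sweep_recovers_latencies(self):
        sweep, shape = synthetic_baseline_sweep()
        peaks = detect_peaks(sweep)
        assert len(peaks["latencies_ms"]) == 3
        np.testing.assert_allclose(peaks["latencies_ms"], shape.latencies_ms,
                                   atol=1000.0 / sweep.sample_rate)

    def test_flat_sweep_suggests_manual_window(self):
        with pytest.raises(ValueError, match="manual window"):
            detect_peaks(make_sweep(np.zeros(120)))

    def test_two_peak_sweep_is_sufficient(self):
        t_ms = (np.arange(120) - 20) * 0.05
        v = (np.exp(-0.5 * ((t_ms - 0.6) / 0.1) ** 2)
             + 0.8 * np.exp(-0.5 * ((t_ms - 1.2) / 0.15) ** 2))
        peaks = detect_peaks(make_sweep(v, t_ms=t_ms))
        assert len(peaks["latencies_ms"]) == 2

    def test_short_sweep_rejected(self):
        with pytest.raises(ValueError, match="3 ms"):
            detect_peaks(make_sweep(np.zeros(40)))


class TestDefineWindow:
    def test_auto_window_spans_first_two_peaks_only(self):
        sweep, shape = synthetic_baseline_sweep()
        win = define_window([sweep])
        assert 0.15 <= win.start_ms <= 0.45
        assert shape.latencies_ms[1] < win.end_ms < shape.latencies_ms[2]
        assert win.provenance == "auto"

    def test_manual_bounds_returned_verbatim(self):
        win = define_window([], start_ms=0.25, end_ms=1.6)
        assert (win.start_ms, win.end_ms, win.provenance) == (0.25, 1.6, "manual")

    def test_span_far_from_nominal_warns(self):
        with pytest.warns(UserWarning, match="deviates"):
            CapWindow(0.2, 5.0)


class TestCapArea:
    def test_zero_sweep_has_zero_area(self):
        area = cap_area(make_sweep(np.zeros(120)), CapWindow(0.2, 1.7))
        assert area == 0.0

    def test_linearity_in_voltage(self):
        sweep, _ = synthetic_baseline_sweep()
        win = CapWindow(0.2, 1.7)
        a1 = cap_area(sweep, win)
        a3 = cap_area(make_sweep(3.0 * sweep.v_mV, t_ms=sweep.t_ms), win)
        assert a3 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_gaussian_peak_matches_closed_form_within_0p1_percent(self):
        """A single unit Gaussian fully inside the window integrates to
        amp * sigma * sqrt(2*pi)."""
        rate = 100_000
        step = 1000.0 / rate
        t_ms = (np.arange(int(6.0 / step)) - int(1.0 / step)) * step
        amp, mu, sigma = 1.0, 2.0, 0.15
        v = amp * np.exp(-0.5 * ((t_ms - mu) / sigma) ** 2)
        area = cap_area(make_sweep(v, t_ms=t_ms, rate=rate), CapWindow(0.8, 3.2))
        assert area == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=1e-3)

    def test_window_outside_sweep_rejected(self):
        with pytest.raises(ValueError, match="outside sweep"):
            cap_area(make_sweep(np.zeros(120)), CapWindow(0.2, 50.0))

    def test_rectification_excludes_negative_lobes(self):
        t_ms = (np.arange(120) - 20) * 0.05
        v = np.exp(-0.5 * ((t_ms - 0.8) / 0.1) ** 2) \
            - 0.5 * np.exp(-0.5 * ((t_ms - 1.4) / 0.1) ** 2)
        sweep = make_sweep(v, t_ms=t_ms)
        win = CapWindow(0.2, 1.8)
        assert cap_area(sweep, win, rectify=True) > cap_area(sweep, win, rectify=False)


class TestBuildCapSeries:
    def test_identical_sweeps_normalize_to_one(self):
        sweep, _ = synthetic_baseline_sweep()
        sweeps = [replace(sweep, stim_time_s=10.0 * k, sweep_id=k) for k in range(30)]
        series = build_cap_series(sweeps, CapWindow(0.2, 1.7), baseline_period_s=100.0)
        np.testing.assert_allclose(series.value, 1.0, rtol=1e-12)

    def test_normalization_invariant_to_amplifier_gain(self):
        sweep, _ = synthetic_baseline_sweep()
        sweeps = [replace(sweep, stim_time_s=10.0 * k, sweep_id=k,
                          v_mV=sweep.v_mV * (1 + 0.01 * k)) for k in range(20)]
        scaled = [replace(s, v_mV=s.v_mV * 500.0) for s in sweeps]
        win = CapWindow(0.2, 1.7)
        s1 = build_cap_series(sweeps, win, baseline_period_s=50.0)
        s2 = build_cap_series(scaled, win, baseline_period_s=50.0)
        np.testing.assert_allclose(s1.value, s2.value, rtol=1e-12)

    def test_no_baseline_sweeps_rejected(self):
        sweep, _ = synthetic_baseline_sweep()
        sweeps = [replace(sweep, stim_time_s=1000.0 + k, sweep_id=k) for k in range(3)]
        with pytest.raises(ValueError, match="baseline period"):
            build_cap_series(sweeps, CapWindow(0.2, 1.7), baseline_period_s=100.0)

    def test_full_depletion_abolishes_the_cap(self, mbgd_noiseless):
        """At the end of the MB+GD treatment no CAP is evoked: the
        normalized series falls to ~0."""
        series = cap_series(mbgd_noiseless)
        t1 = mbgd_noiseless.config.treatment_window[1]
        end = series.window_mask((t1 - 30.0, t1))
        assert series.value[end].max() < 0.02


class TestClosedLoop:
    def test_noiseless_cap_series_equals_fatigue_times_phi(self, hfs100_noiseless):
        """On noiseless generator output the normalized CAP reproduces
        psi_fatigue * phi(A) at the sweep times."""
        from axatp.capsim import fatigue_trace, phi_conduction

        sim = hfs100_noiseless
        series = cap_series(sim)
        prot, shape = sim.preset.protocol, sim.preset.cap_shape
        t, psi = fatigue_trace(prot, shape, sim.config.total_duration_s)
        psi_at = np.interp(series.time_s, t, psi)
        phi_at = phi_conduction(sim.energy.at(series.time_s),
                                sim.preset.energy.A_safe, shape.phi_exponent)
        np.testing.assert_allclose(series.value, psi_at * phi_at, atol=0.02)
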