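"""Kinetic metrics: slopes, onsets, HFS statistics, pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axatp.kinetics import (
    detect_onset,
    drop_ratio,
    hfs_metrics,
    max_decay_rate,
    pair_series,
    recovery_metrics,
    sliding_slope,
)

from conftest import make_series


def piecewise_decay(break_s=300.0, rate=0.01, dt=10.4, total=600.0):
    t = np.arange(0, total, dt)
    v = np.where(t < break_s, 1.0, 1.0 - rate * (t - break_s))
    return make_series(t, np.clip(v, 0.0, None))


class TestSlidingSlope:
    def test_linear_series_gives_its_slope_everywhere(self):
        t = np.arange(50) * 10.0
        s = make_series(t, 0.02 * t + 1.0)
        np.testing.assert_allclose(sliding_slope(s), 0.02, rtol=1e-10)

    def test_constant_series_gives_zero(self):
        s = make_series(np.arange(30) * 10.0, np.ones(30))
        np.testing.assert_allclose(sliding_slope(s), 0.0, atol=1e-14)

    def test_quadratic_matches_analytic_derivative_at_centres(self):
        """A centred least-squares line on a symmetric window of a
        quadratic recovers the exact derivative at the centre."""
        t = np.arange(60) * 5.0
        s = make_series(t, 1e-4 * t ** 2)
        slopes = sliding_slope(s, window_frames=5)
        interior = slice(2, -2)
        np.testing.assert_allclose(slopes[interior], 2e-4 * t[interior], rtol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_slope(make_series([0, 1, 2], [1, 1, 1]), window_frames=5)


class TestMaxDecayRate:
    def test_piecewise_linear_drop_recovers_rate(self):
        s = piecewise_decay(rate=0.01)
        assert max_decay_rate(s, (200, 500)) == pytest.approx(0.01, rel=1e-6)

    def test_monotone_rise_reports_nonpositive(self):
        t = np.arange(40) * 10.0
        s = make_series(t, 0.001 * t)
        assert max_decay_rate(s, (0, 390)) <= 0


class TestDetectOnset:
    def test_noiseless_break_found_within_one_frame(self):
        """A decay starting on a frame boundary is detected causally,
        within one frame of the break."""
        s = piecewise_decay(break_s=312.0, rate=0.02)
        onset = detect_onset(s, (0, 200), direction="down", search_start_s=200.0)
        assert 312.0 <= onset <= 312.0 + 10.4 + 1e-9

    def test_pure_noise_yields_no_onset(self):
        rng = np.random.default_rng(11)
        t = np.arange(100) * 10.4
        s = make_series(t, 1.0 + 0.01 * rng.standard_normal(100))
        onset = detect_onset(s, (0, 400), direction="down", search_start_s=400.0)
        assert np.isnan(onset)

    @given(shift=st.floats(-200.0, 200.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_time_shift_equivariance(self, shift):
        """Shifting the whole series by delta shifts the onset by exactly
        delta."""
        s = piecewise_decay()
        shifted = make_series(s.time_s + shift, s.value)
        o1 = detect_onset(s, (0, 200), direction="down", search_start_s=250.0)
        o2 = detect_onset(shifted, (shift, 200 + shift), direction="down",
                          search_start_s=250.0 + shift)
        assert o2 - o1 == pytest.approx(shift, abs=1e-9)

    @given(alpha=st.floats(0.2, 5.0), beta=st.floats(-1.0, 1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_onset_invariant_rates_scale_under_affine_rescaling(self, alpha, beta):
        s = piecewise_decay()
        scaled = make_series(s.time_s, alpha * s.value + beta)
        o1 = detect_onset(s, (0, 200), direction="down", search_start_s=250.0)
        o2 = detect_onset(scaled, (0, 200), direction="down", search_start_s=250.0)
        assert o1 == o2
        r1 = max_decay_rate(s, (250, 550))
        r2 = max_decay_rate(scaled, (250, 550))
        assert r2 == pytest.approx(alpha * r1, rel=1e-9)

    def test_k_sd_must_be_positive(self):
        with pytest.raises(ValueError, match="k_sd"):
            detect_onset(piecewise_decay(), (0, 200), k_sd=0.0)


class TestRecoveryMetrics:
    def test_series_already_recovered(self):
        t = np.arange(60) * 10.0
        s = make_series(t, np.ones(60), baseline_window=(0, 100))
        onset, rate, overall = recovery_metrics(s, 300.0)
        assert rate == pytest.approx(0.0, abs=1e-12)
        assert overall == pytest.approx(1.0)

    def test_linear_ramp_rate(self):
        t = np.arange(0, 600, 10.0)
        v = np.clip((t - 300.0) / 100.0, 0.0, 1.0)
        s = make_series(t, v, baseline_window=(0, 200))
        onset, rate, overall = recovery_metrics(s, 290.0)
        assert rate == pytest.approx(0.01, rel=0.05)
        assert overall == pytest.approx(1.0)

    def test_reperfusion_outside_series_rejected(self):
        s = piecewise_decay()
        with pytest.raises(ValueError, match="outside"):
            recovery_metrics(s, 10_000.0)


class TestHfsMetrics:
    def test_constant_series_gives_identity(self):
        t = np.arange(0, 700, 10.0)
        s = make_series(t, np.ones(t.size))
        amp, dec, rec = hfs_metrics(s, 300.0, 450.0)
        assert (amp, dec, rec) == (pytest.approx(1.0), pytest.approx(0.0),
                                   pytest.approx(0.0))

    def test_drop_then_plateau_amplitude(self):
        t = np.arange(0, 700, 10.0)
        v = np.interp(t, [0, 300, 360, 700], [1, 1, 0.8, 0.8])
        s = make_series(t, v)
        amp, dec, rec = hfs_metrics(s, 300.0, 450.0)
        assert amp == pytest.approx(0.8, abs=1e-9)
        assert dec < 0

    def test_windows_beyond_series_rejected(self):
        t = np.arange(0, 500, 10.0)
        s = make_series(t, np.ones(t.size))
        with pytest.raises(ValueError, match="beyond"):
            hfs_metrics(s, 300.0, 480.0)
        with pytest.raises(ValueError, match="60 s"):
            hfs_metrics(s, 300.0, 330.0)


class TestDropRatio:
    def test_arithmetic(self):
        assert drop_ratio(0.3, 0.6) == pytest.approx(0.5)
        assert drop_ratio(0.5, 0.5) == pytest.approx(1.0)

    def test_decrement_convention(self):
        assert drop_ratio(0.7, 0.4, decrement=True) == pytest.approx(0.5)

    def test_zero_cap_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            drop_ratio(0.3, 0.0)


class TestPairSeries:
    def test_identical_series_on_diagonal(self):
        t = np.arange(0, 500, 10.0)
        v = np.sin(t / 100.0) * 0.2 + 0.8
        a = make_series(t, v, kind="ATP")
        c = make_series(t, v, kind="CAP")
        pairs, r = pair_series(a, c)
        assert r == pytest.approx(1.0)
        np.testing.assert_allclose(pairs[:, 1], pairs[:, 2])

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 3000, 10.0)
        a = make_series(t, 1 + 0.05 * rng.standard_normal(t.size), kind="ATP")
        c = make_series(t, 1 + 0.05 * rng.standard_normal(t.size), kind="CAP")
        _, r = pair_series(a, c)
        assert abs(r) < 0.15

    def test_disjoint_ranges_rejected(self):
        a = make_series(np.arange(0, 100, 10.0), np.ones(10))
        c = make_series(np.arange(500, 600, 10.0), np.ones(10), kind="CAP")
        with pytest.raises(ValueError, match="overlap"):
            pair_series(a, c)
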