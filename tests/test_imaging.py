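"""Imaging pipeline: ROI means, ratio, normalization, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axatp.imaging import (
    FluorescenceTrace,
    channel_qc,
    compute_ratio,
    extract_roi_means,
    normalize_ratio,
    percent_change,
)
from axatp.workflows import atp_series


def simple_trace(cfp, fret, yfp=None, dt=10.4):
    n = len(cfp)
    return FluorescenceTrace(time_s=np.arange(n) * dt, cfp=np.asarray(cfp, float),
                             fret=np.asarray(fret, float),
                             yfp=None if yfp is None else np.asarray(yfp, float))


class TestExtractRoiMeans:
    def test_uniform_frames_give_their_value(self):
        stack = np.full((4, 3, 8, 8), 7.0)
        stack[:, 1] = 3.0
        tr = extract_roi_means(stack)
        np.testing.assert_allclose(tr.cfp, 7.0)
        np.testing.assert_allclose(tr.fret, 3.0)

    def test_half_field_mask_averages_masked_half_only(self):
        stack = np.zeros((3, 2, 4, 4))
        stack[:, :, :, :2] = 10.0
        stack[:, :, :, 2:] = 2.0
        mask = np.zeros((4, 4), bool)
        mask[:, :2] = True
        tr = extract_roi_means(stack, mask=mask)
        np.testing.assert_allclose(tr.cfp, 10.0)

    def test_empty_mask_and_bad_channel_count_rejected(self):
        stack = np.ones((3, 2, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            extract_roi_means(stack, mask=np.zeros((4, 4), bool))
        with pytest.raises(ValueError, match="channels"):
            extract_roi_means(np.ones((3, 1, 4, 4)))


class TestComputeRatio:
    def test_equal_channels_give_unity(self):
        tr = simple_trace([5, 5, 5], [5, 5, 5])
        np.testing.assert_allclose(compute_ratio(tr), 1.0)

    def test_common_gain_cancels(self):
        """Multiplying both channels by any gain leaves the ratio intact."""
        cfp = np.array([4.0, 5.0, 6.0])
        fret = np.array([6.0, 5.5, 5.0])
        r1 = compute_ratio(simple_trace(cfp, fret))
        r2 = compute_ratio(simple_trace(3.7 * cfp, 3.7 * fret))
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_zero_cfp_frame_named_in_error(self):
        tr = simple_trace([5, 5, 5], [5, 5, 5])
        tr.cfp[1] = 0.0
        with pytest.raises(ValueError, match="frame 1"):
            compute_ratio(tr)


class TestNormalizeRatio:
    t = np.arange(20) * 10.0

    def test_baseline_level_maps_to_one_anchor_to_zero(self):
        r = np.concatenate([np.full(10, 3.0), np.full(10, 1.5)])
        s = normalize_ratio(self.t, r, (0, 90), (100, 190))
        np.testing.assert_allclose(s.value[:10], 1.0)
        np.testing.assert_allclose(s.value[10:], 0.0)

    @given(alpha=st.floats(0.1, 10.0), beta=st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, alpha, beta):
        """Any positive affine transform of the raw ratio produces an
        identical normalized series."""
        rng = np.random.default_rng(0)
        r = 2.0 + rng.random(20)
        s1 = normalize_ratio(self.t, r, (0, 90), (100, 190))
        s2 = normalize_ratio(self.t, alpha * r + beta, (0, 90), (100, 190))
        np.testing.assert_allclose(s1.value, s2.value, rtol=1e-9, atol=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        r = 2.0 + rng.random(20)
        s1 = normalize_ratio(self.t, r, (0, 90), (100, 190))
        s2 = normalize_ratio(self.t, s1.value, (0, 90), (100, 190))
        np.testing.assert_allclose(s1.value, s2.value, rtol=1e-12)

    def test_degenerate_windows_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_ratio(self.t, np.ones(20), (0, 90), (100, 190))


class TestPercentChange:
    def test_constant_trace_reports_unity_everywhere(self):
        tr = simple_trace([5] * 10, [7] * 10, [4] * 10)
        rep = percent_change(tr, (0, 40), (50, 90))
        assert rep["cfp"] == rep["fret"] == rep["yfp"] == pytest.approx(1.0)
        assert rep["fc_reduction_percent"] == pytest.approx(0.0)

    def test_mbgd_depletion_moves_channels_in_opposite_directions(self, mbgd_noisy):
        """During full ATP depletion CFP rises, FRET falls, direct-YFP is
        flat — the pH-artifact control."""
        cfg = mbgd_noisy.config
        t0 = cfg.treatment_window[0]
        rep = percent_change(mbgd_noisy.trace, (t0 - 60, t0), (t0 + 90, t0 + 120))
        assert rep["cfp"] > 1.02
        assert rep["fret"] < 0.9
        assert rep["yfp"] == pytest.approx(1.0, abs=0.02)
        assert rep["fc_reduction_percent"] > 25.0

    def test_windows_outside_trace_rejected(self):
        tr = simple_trace([5] * 10, [7] * 10)
        with pytest.raises(ValueError, match="window"):
            percent_change(tr, (0, 40), (500, 600))


class TestChannelQc:
    def test_constant_yfp_passes(self):
        tr = simple_trace([5] * 40, [7] * 40, [4] * 40)
        assert channel_qc(tr)["verdict"] == "pass"

    def test_yfp_step_fails(self):
        yfp = np.full(40, 4.0)
        yfp[20:] *= 1.2
        tr = simple_trace([5] * 40, [7] * 40, yfp)
        assert channel_qc(tr)["verdict"] == "fail"

    def test_missing_yfp_not_assessable(self):
        tr = simple_trace([5] * 40, [7] * 40)
        assert channel_qc(tr)["verdict"] == "not assessable"


class TestEndToEnd:
    def test_normalized_atp_is_monotone_transform_of_true_atp(self, mbgd_noiseless):
        """On noiseless generator output the pipeline's normalized ATP
        preserves the ordering of the underlying ATP concentration."""
        series = atp_series(mbgd_noiseless)
        a = mbgd_noiseless.energy.at(series.time_s)
        order = np.argsort(a)
        assert np.all(np.diff(series.value[order]) >= -1e-9)

    def test_roi_means_recover_generating_trace_within_pixel_noise(self, mbgd_noiseless):
        from axatp.io import axon_stripe_texture

        rng = np.random.default_rng(5)
        tex = axon_stripe_texture((32, 32))
        tr = mbgd_noiseless.trace
        sub = slice(0, 20)
        stack = np.stack([
            np.stack([c[sub, None, None] * tex * (1 + rng.normal(0, 0.05, (20, 32, 32)))
                      for c in (tr.cfp, tr.fret, tr.yfp)], axis=1)
        ]).squeeze(0)
        rec = extract_roi_means(stack, time_s=tr.time_s[sub])
        np.testing.assert_allclose(rec.cfp, tr.cfp[sub], rtol=0.01)
        np.testing.assert_allclose(rec.fret, tr.fret[sub], rtol=0.01)
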