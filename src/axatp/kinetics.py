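"""Kinetic metrics on normalized ATP and CAP series.

All rates are slopes (m coefficients) of centered least-squares line fits
in units of normalized signal per second.  Onsets are detected as the
first time the sliding slope exceeds a threshold derived from the
baseline slope variability (k_sd x SD), sustained for two consecutive
samples.  HFS metrics follow the fixed-window convention: overall
amplitude = mean over the last 15 s of stimulation, initial decay rate =
slope over the first 45 s of stimulation, recovery rate = slope over the
60 s after stimulation end.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

from .imaging import NormalizedSeries

Window = Tuple[float, float]

#: Relative floor on the onset threshold, in units of the series' value
#: range per second.  It sets the minimum effect size a slope must reach
#: to count as an onset; scaling it by the value range keeps onset times
#: invariant under affine rescaling.  At the default channel noise the
#: baseline 3*SD term sits below this floor, so noiseless and noisy
#: detection use the same effective threshold (the k_sd * SD term takes
#: over on noisier data).
SLOPE_FLOOR = 3.5e-3

NO_ONSET = float("nan")


@dataclass
class KineticsResult:
    """Kinetic parameters of one normalized series (ATP or CAP)."""

    kind: str = "ATP"
    onset_s: Optional[float] = None
    max_decay_rate_per_s: Optional[float] = None
    recovery_onset_s: Optional[float] = None
    recovery_rate_per_s: Optional[float] = None
    overall_recovery: Optional[float] = None
    overall_amplitude: Optional[float] = None
    initial_decay_rate_per_s: Optional[float] = None
    hfs_recovery_rate_per_s: Optional[float] = None
    drop_ratio: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def sliding_slope(
    series: NormalizedSeries,
    window_frames: int = 5,
    mode: str = "centered",
) -> np.ndarray:
    """Sliding least-squares slope at every sample (normalized units / s).

    ``mode="centered"`` fits a line over a window centred on each sample
    (best local derivative estimate, used for rate metrics);
    ``mode="trailing"`` uses only the current and preceding samples, so
    the slope at time t depends on data up to t — onset detection uses
    this causal variant so a detected onset never precedes the change.
    At the series ends the window shrinks (down to 2 samples) rather than
    being padded.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    if mode not in ("centered", "trailing"):
        raise ValueError("mode must be 'centered' or 'trailing'")
    n = len(series)
    if n < window_frames:
        raise ValueError(f"series of length {n} shorter than window {window_frames}")
    t, v = series.time_s, series.value
    slopes = np.empty(n)
    for i in range(n):
        if mode == "centered":
            half = window_frames // 2
            lo = max(0, i - half)
            hi = min(n, i + half + 1)
        else:
            lo = max(0, i - window_frames + 1)
            hi = i + 1
        if hi - lo < 2:
            lo, hi = max(0, i - 1), min(n, i + 2)
        tw = t[lo:hi] - t[lo:hi].mean()
        vw = v[lo:hi]
        slopes[i] = float(tw @ (vw - vw.mean()) / (tw @ tw))
    return slopes


def max_decay_rate(
    series: NormalizedSeries,
    interval: Window,
    window_frames: int = 5,
) -> float:
    """Maximal decay velocity within ``interval``, reported positive.

    The most negative sliding slope over the interval, sign-flipped; a
    series that only rises yields a value <= 0.
    """
    mask = series.window_mask(interval)
    if not mask.any():
        raise ValueError(f"interval {interval} contains no samples")
    slopes = sliding_slope(series, window_frames)
    return float(-slopes[mask].min())


def detect_onset(
    series: NormalizedSeries,
    baseline_window: Window,
    k_sd: float = 3.0,
    direction: str = "down",
    search_start_s: Optional[float] = None,
    window_frames: int = 5,
    slope_floor: float = SLOPE_FLOOR,
) -> float:
    """First time the sliding slope exceeds the baseline-derived threshold.

    threshold = max(k_sd * SD(baseline slopes), slope_floor * value range);
    the onset is the first sample at/after ``search_start_s`` (default:
    end of the baseline window) whose trailing-window slope exceeds the
    threshold in the stated direction for two consecutive samples.
    Returns NaN ("no onset") if the threshold is never exceeded.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    bmask = series.window_mask(baseline_window)
    if not bmask.any():
        raise ValueError(f"baseline window {baseline_window} contains no samples")
    slopes = sliding_slope(series, window_frames, mode="trailing")
    thr = max(k_sd * float(slopes[bmask].std()),
              slope_floor * float(np.ptp(series.value)))
    start = baseline_window[1] if search_start_s is None else search_start_s
    if start < baseline_window[0]:
        raise ValueError("search region must not precede the baseline window")
    signed = -slopes if direction == "down" else slopes
    candidates = np.flatnonzero((series.time_s >= start) & (signed > thr))
    for i in candidates:
        if i + 1 < len(series) and signed[i + 1] > thr:
            return float(series.time_s[i])
    return NO_ONSET


def recovery_metrics(
    series: NormalizedSeries,
    reperfusion_start_s: float,
    k_sd: float = 3.0,
    window_frames: int = 5,
    final_window_s: float = 120.0,
    baseline_window: Optional[Window] = None,
) -> tuple[float, float, float]:
    """Onset, rate and extent of recovery after reperfusion.

    Returns ``(recovery_onset_s, recovery_rate_per_s, overall_recovery)``:
    onset via :func:`detect_onset` with positive direction from
    ``reperfusion_start_s``; rate = maximal positive slope after
    reperfusion; overall recovery = mean normalized level over the final
    ``final_window_s`` of the series.
    """
    t0, t1 = float(series.time_s[0]), float(series.time_s[-1])
    if not (t0 <= reperfusion_start_s <= t1):
        raise ValueError("reperfusion_start_s outside the series")
    if baseline_window is None:
        baseline_window = series.baseline_window or (t0, t0 + 300.0)
    onset = detect_onset(
        series, baseline_window, k_sd=k_sd, direction="up",
        search_start_s=reperfusion_start_s, window_frames=window_frames,
    )
    slopes = sliding_slope(series, window_frames)
    m = series.time_s >= reperfusion_start_s
    rate = float(np.clip(slopes[m].max(), 0.0, None))
    overall = series.window_mean((t1 - final_window_s, t1))
    return onset, rate, overall


def _window_slope(series: NormalizedSeries, window: Window) -> float:
    m = series.window_mask(window)
    if m.sum() < 2:
        raise ValueError(f"window {window} has fewer than 2 samples")
    t = series.time_s[m] - series.time_s[m].mean()
    v = series.value[m]
    return float(t @ (v - v.mean()) / (t @ t))


def hfs_metrics(
    series: NormalizedSeries,
    stim_start_s: float,
    stim_end_s: float,
    amplitude_window_s: float = 15.0,
    decay_window_s: float = 45.0,
    recovery_window_s: float = 60.0,
) -> tuple[float, float, float]:
    """The three windowed HFS statistics of a normalized series.

    Returns ``(overall_amplitude, initial_decay_rate, hfs_recovery_rate)``:
    mean over the last 15 s of stimulation, least-squares slope over the
    first 45 s of stimulation, and slope over the 60 s following
    stimulation end.
    """
    if stim_end_s - stim_start_s < 60.0:
        raise ValueError("stimulation window must be at least 60 s")
    t1 = float(series.time_s[-1])
    if stim_end_s + recovery_window_s > t1 + 1e-9:
        raise ValueError("recovery window extends beyond the series")
    overall = series.window_mean((stim_end_s - amplitude_window_s, stim_end_s))
    decay = _window_slope(series, (stim_start_s, stim_start_s + decay_window_s))
    recovery = _window_slope(series, (stim_end_s, stim_end_s + recovery_window_s))
    return overall, decay, recovery


def drop_ratio(atp_amp: float, cap_amp: float, decrement: bool = False) -> float:
    """Ratio of remaining normalized ATP to remaining normalized CAP.

    Defined on remaining amplitudes at the end of HFS (default), staying
    near 1 when both signals drop by the same factor; ``decrement=True``
    uses the (1 - amplitude) decrements instead.
    """
    if decrement:
        atp_amp, cap_amp = 1.0 - atp_amp, 1.0 - cap_amp
    if cap_amp == 0:
        raise ValueError("CAP amplitude is zero; drop ratio undefined")
    return atp_amp / cap_amp


def pair_series(
    atp: NormalizedSeries,
    cap: NormalizedSeries,
) -> tuple[np.ndarray, float]:
    """Nearest-neighbour pairing of ATP frames with CAP sweeps.

    CAP sweeps are sparser than imaging frames during HFS and denser at
    baseline; each CAP point is paired with the nearest ATP frame.
    Returns ``(pairs, pearson_r)`` with ``pairs`` of shape (n, 3):
    time, ATP value, CAP value.
    """
    lo = max(atp.time_s[0], cap.time_s[0])
    hi = min(atp.time_s[-1], cap.time_s[-1])
    if lo > hi:
        raise ValueError("series time ranges do not overlap")
    m = (cap.time_s >= lo) & (cap.time_s <= hi)
    idx = np.searchsorted(atp.time_s, cap.time_s[m])
    idx = np.clip(idx, 1, len(atp) - 1)
    left = np.abs(atp.time_s[idx - 1] - cap.time_s[m])
    right = np.abs(atp.time_s[idx] - cap.time_s[m])
    idx = np.where(left < right, idx - 1, idx)
    pairs = np.column_stack([cap.time_s[m], atp.value[idx], cap.value[m]])
    if pairs.shape[0] < 2 or np.std(pairs[:, 1]) == 0 or np.std(pairs[:, 2]) == 0:
        r = float("nan")
    else:
        r = float(sps.pearsonr(pairs[:, 1], pairs[:, 2]).statistic)
    return pairs, r
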