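"""CAP pipeline: evoked sweeps -> area metric -> normalized time course.

The compound action potential (CAP) of a stimulated nerve is quantified as
the area under the evoked waveform over a fixed window spanning the first
two peaks (~0.2-1.7 ms after the stimulus, a span of roughly 1.5 ms).  The
window is defined once from the averaged baseline sweep and then frozen
for the whole experiment, so both amplitude loss and latency drift reduce
the measured area.  Per-sweep areas are normalized to the mean over the
initial baseline period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .imaging import NormalizedSeries

EXPECTED_SPAN_MS = 1.5   # nominal window span; warn if off by more than 2x


@dataclass
class CapSweep:
    """One evoked waveform: voltage samples around a stimulus at t = 0."""

    stim_time_s: float
    t_ms: np.ndarray
    v_mV: np.ndarray
    sample_rate: int = 20_000
    sweep_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        if self.t_ms.size != self.v_mV.size:
            raise ValueError("t_ms and v_mV must have equal length")
        if self.t_ms.size < 2:
            raise ValueError("sweep needs at least 2 samples")
        dts = np.diff(self.t_ms)
        if not np.all(dts > 0):
            raise ValueError("t_ms must be strictly increasing")
        step = 1000.0 / self.sample_rate
        if not np.allclose(dts, step, rtol=1e-6, atol=1e-9):
            raise ValueError(
                f"sweep {self.sweep_id}: non-uniform sampling "
                f"(expected {step:.4f} ms steps)"
            )
        if self.t_ms[0] > 0:
            raise ValueError("sweep must start at or before the stimulus (t_ms <= 0)")

    def __len__(self) -> int:
        return int(self.t_ms.size)


@dataclass
class CapWindow:
    """Frozen integration bounds for the CAP area, in ms post-stimulus."""

    start_ms: float
    end_ms: float
    provenance: str = "auto"     # "auto" | "manual"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start_ms < self.end_ms):
            raise ValueError("need 0 <= start_ms < end_ms")
        span = self.end_ms - self.start_ms
        if span > 2 * EXPECTED_SPAN_MS or span < EXPECTED_SPAN_MS / 2:
            warnings.warn(
                f"CAP window span {span:.2f} ms deviates >2x from the "
                f"nominal {EXPECTED_SPAN_MS} ms",
                stacklevel=2,
            )


def mean_sweep(sweeps: Sequence[CapSweep]) -> CapSweep:
    """Average several sweeps sampled on a common grid."""
    if not sweeps:
        raise ValueError("no sweeps to average")
    ref = sweeps[0]
    for s in sweeps[1:]:
        if s.t_ms.size != ref.t_ms.size or not np.allclose(s.t_ms, ref.t_ms):
            raise ValueError("sweeps must share a common time grid to average")
    v = np.mean([s.v_mV for s in sweeps], axis=0)
    return CapSweep(
        stim_time_s=ref.stim_time_s,
        t_ms=ref.t_ms.copy(),
        v_mV=v,
        sample_rate=ref.sample_rate,
        sweep_id=None,
    )


def detect_peaks(
    sweep: CapSweep,
    artifact_end_ms: float = 0.15,
    min_prominence_frac: float = 0.05,
) -> dict:
    """Latencies and prominences of CAP peaks in a (mean) baseline sweep.

    Local maxima after the stimulus artifact, ordered by latency; at least
    two peaks are required by the downstream window definition.

    Returns ``{"latencies_ms", "prominences_mV", "indices"}``; raises
    ``ValueError`` suggesting a manual window if fewer than 2 peaks are
    found.
    """
    if sweep.t_ms[-1] < 3.0:
        raise ValueError("sweep must cover at least 3 ms after the stimulus")
    mask = sweep.t_ms >= artifact_end_ms
    v = sweep.v_mV[mask]
    t = sweep.t_ms[mask]
    vrange = float(v.max() - v.min())
    if vrange <= 0:
        raise ValueError(
            "flat sweep: no CAP peaks found; supply a manual window"
        )
    idx, props = find_peaks(v, prominence=min_prominence_frac * vrange)
    if idx.size < 2:
        raise ValueError(
            f"only {idx.size} CAP peak(s) found; supply a manual window"
        )
    order = np.argsort(t[idx])
    idx = idx[order]
    return {
        "latencies_ms": t[idx],
        "prominences_mV": props["prominences"][order],
        "indices": np.flatnonzero(mask)[idx],
    }


def define_window(
    baseline_sweeps: Sequence[CapSweep],
    start_ms: Optional[float] = None,
    end_ms: Optional[float] = None,
    k_sd: float = 3.0,
    artifact_end_ms: float = 0.15,
    fallback_start_ms: float = 0.2,
) -> CapWindow:
    """Derive the frozen CAP integration window from baseline sweeps.

    start = first sustained rise of the averaged baseline sweep above the
    pre-stimulus noise band after the artifact (fallback 0.2 ms); end =
    trough following the second peak.  Manual bounds are returned verbatim
    with provenance "manual".  The window is then reused for every later
    sweep of the experiment.
    """
    if start_ms is not None and end_ms is not None:
        return CapWindow(start_ms=start_ms, end_ms=end_ms, provenance="manual")

    avg = mean_sweep(baseline_sweeps)
    peaks = detect_peaks(avg, artifact_end_ms=artifact_end_ms)
    lat = peaks["latencies_ms"]

    # start: sustained rise above pre-stimulus noise (artifact tail excluded)
    pre = avg.v_mV[avg.t_ms <= -0.2]
    if pre.size == 0:
        pre = avg.v_mV[avg.t_ms < 0]
    v0, sd = (float(pre.mean()), float(pre.std())) if pre.size else (0.0, 0.0)
    thr = v0 + k_sd * sd
    search = (avg.t_ms >= artifact_end_ms) & (avg.t_ms < lat[0])
    above = avg.v_mV > thr
    start = fallback_start_ms
    run = 0
    for i in np.flatnonzero(search):
        run = run + 1 if above[i] else 0
        if run >= 3:
            start = float(avg.t_ms[i - run + 1])
            break

    # end: trough between the 2nd peak and the next peak (or sweep end)
    hi = lat[2] if lat.size >= 3 else float(avg.t_ms[-1])
    seg = (avg.t_ms > lat[1]) & (avg.t_ms < hi)
    if not seg.any():
        raise ValueError("no samples after the second peak to place window end")
    end = float(avg.t_ms[seg][np.argmin(avg.v_mV[seg])])

    return CapWindow(
        start_ms=start,
        end_ms=end,
        provenance="auto",
        meta={"peak_latencies_ms": [float(x) for x in lat]},
    )


def cap_area(
    sweep: CapSweep,
    window: CapWindow,
    rectify: bool = True,
    baseline_end_ms: float = -0.2,
) -> float:
    """Area (mV*ms) under the baseline-subtracted CAP within the window.

    The pre-stimulus mean (samples before ``baseline_end_ms``, which keeps
    the stimulus-artifact tail out of the estimate) is subtracted and, by
    default, the positive part is integrated (trapezoidal rule);
    ``rectify=False`` integrates the signed deflection instead.  Linear in
    the voltage for non-negative deflections.
    """
    if window.start_ms < sweep.t_ms[0] or window.end_ms > sweep.t_ms[-1]:
        raise ValueError(
            f"window [{window.start_ms}, {window.end_ms}] ms outside sweep "
            f"support [{sweep.t_ms[0]:.2f}, {sweep.t_ms[-1]:.2f}] ms"
        )
    pre = sweep.v_mV[sweep.t_ms <= baseline_end_ms]
    if pre.size == 0:
        pre = sweep.v_mV[sweep.t_ms < 0]
    v_pre = float(pre.mean()) if pre.size else 0.0
    m = (sweep.t_ms >= window.start_ms) & (sweep.t_ms <= window.end_ms)
    v = sweep.v_mV[m] - v_pre
    if rectify:
        v = np.maximum(v, 0.0)
    return float(np.trapezoid(v, sweep.t_ms[m]))


def build_cap_series(
    sweeps: Sequence[CapSweep],
    window: CapWindow,
    baseline_period_s: float = 900.0,
    rectify: bool = True,
) -> NormalizedSeries:
    """Per-sweep CAP areas normalized to the initial baseline period.

    Areas are computed with the frozen ``window`` at each sweep's stimulus
    time and divided by the mean area over sweeps with
    ``stim_time_s <= baseline_period_s`` (the pre-treatment baseline;
    default 15 min, any explicit period is allowed for short runs).
    """
    if not sweeps:
        raise ValueError("no sweeps")
    times = np.array([s.stim_time_s for s in sweeps], dtype=float)
    order = np.argsort(times)
    times = times[order]
    areas = np.array([cap_area(sweeps[i], window, rectify=rectify) for i in order])
    base = times <= baseline_period_s
    if not base.any():
        raise ValueError(f"no sweeps within the baseline period (0-{baseline_period_s}s)")
    base_mean = float(areas[base].mean())
    if base_mean <= 0:
        raise ValueError("baseline CAP area is non-positive")
    return NormalizedSeries(
        time_s=times,
        value=areas / base_mean,
        kind="CAP",
        baseline_window=(float(times[base].min()), float(baseline_period_s)),
        raw_baseline_mean=base_mean,
    )
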