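"""Imaging pipeline: raw channel intensities -> normalized ATP series.

Implements the standard ratiometric workflow for a FRET ATP sensor imaged
in three channels: per-frame ROI means (whole field by default — all
fibres in view are analysed without prior selection), the FRET/CFP ratio
as ATP proxy, and the two-point normalization that maps the pre-treatment
baseline to 1 and the full-depletion (mitochondrial blockade + glucose
deprivation) anchor to 0.  The direct-YFP channel is monitored as a
pH/artifact control (``channel_qc``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

Window = Tuple[float, float]


@dataclass
class FluorescenceTrace:
    """Time-stamped per-frame mean intensities of one nerve / ROI."""

    time_s: np.ndarray
    cfp: np.ndarray
    fret: np.ndarray
    yfp: Optional[np.ndarray] = None
    frame_interval_s: float = 10.4
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        if self.yfp is not None:
            self.yfp = np.asarray(self.yfp, dtype=float)
        n = self.time_s.size
        if not (self.cfp.size == n and self.fret.size == n
                and (self.yfp is None or self.yfp.size == n)):
            raise ValueError("channel arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        for name in ("cfp", "fret", "yfp"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr < 0):
                raise ValueError(f"{name} intensities must be >= 0")

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass
class NormalizedSeries:
    """A dimensionless ATP or CAP time course on the [0, 1] convention.

    ``value`` averages 1 over ``baseline_window`` and (for ATP) 0 over
    ``anchor_window``; values outside [0, 1] are retained (overshoot is
    real signal).
    """

    time_s: np.ndarray
    value: np.ndarray
    kind: str = "ATP"                     # "ATP" | "CAP"
    baseline_window: Optional[Window] = None
    anchor_window: Optional[Window] = None
    raw_baseline_mean: Optional[float] = None
    raw_anchor_mean: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.size != self.value.size:
            raise ValueError("time and value must have equal length")
        if self.kind not in ("ATP", "CAP"):
            raise ValueError("kind must be 'ATP' or 'CAP'")

    def window_mask(self, window: Window) -> np.ndarray:
        lo, hi = window
        return (self.time_s >= lo) & (self.time_s <= hi)

    def window_mean(self, window: Window) -> float:
        m = self.window_mask(window)
        if not m.any():
            raise ValueError(f"window {window} contains no samples")
        return float(self.value[m].mean())

    def __len__(self) -> int:
        return int(self.time_s.size)


def _window_mask(time_s: np.ndarray, window: Window) -> np.ndarray:
    lo, hi = window
    mask = (time_s >= lo) & (time_s <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no frames")
    return mask


def extract_roi_means(
    stack: np.ndarray,
    time_s: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    frame_interval_s: float = 10.4,
) -> FluorescenceTrace:
    """Per-frame ROI mean intensities from a T x C x H x W image stack.

    Channel order is (CFP, FRET[, YFP]).  ``mask`` is an optional binary
    H x W region; the default ROI is the whole field.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("stack must be T x C x H x W")
    n_t, n_c = stack.shape[:2]
    if n_c < 2:
        raise ValueError("stack needs at least CFP and FRET channels")
    if n_t < 2:
        raise ValueError("stack needs at least 2 frames")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape[2:]:
            raise ValueError("mask shape must match frame shape")
        if not mask.any():
            raise ValueError("empty ROI mask")
        means = stack[:, :, mask].mean(axis=2)
    else:
        means = stack.mean(axis=(2, 3))
    if time_s is None:
        time_s = np.arange(n_t) * frame_interval_s
    return FluorescenceTrace(
        time_s=np.asarray(time_s, dtype=float),
        cfp=means[:, 0],
        fret=means[:, 1],
        yfp=means[:, 2] if n_c >= 3 else None,
        frame_interval_s=frame_interval_s,
        meta={"source": "stack", "roi": "mask" if mask is not None else "whole-field"},
    )


def compute_ratio(trace: FluorescenceTrace) -> np.ndarray:
    """Element-wise FRET/CFP ratio (the ATP proxy).

    Raises ``ValueError`` naming the first offending frame if CFP is zero
    or negative anywhere.
    """
    bad = np.flatnonzero(trace.cfp <= 0)
    if bad.size:
        raise ValueError(f"non-positive CFP intensity at frame {int(bad[0])}")
    return trace.fret / trace.cfp


def normalize_ratio(
    time_s: np.ndarray,
    ratio: np.ndarray,
    baseline_window: Window,
    anchor_window: Window,
    kind: str = "ATP",
) -> NormalizedSeries:
    """Two-point normalization of a ratio series.

    value(t) = (R(t) - R0) / (Rb - R0) with Rb the mean over the baseline
    window (-> 1) and R0 the mean over the depletion anchor window (-> 0).
    Invariant under positive affine transforms of the input ratio.
    """
    time_s = np.asarray(time_s, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    rb = float(ratio[_window_mask(time_s, baseline_window)].mean())
    r0 = float(ratio[_window_mask(time_s, anchor_window)].mean())
    if np.isclose(rb, r0):
        raise ValueError(
            "degenerate normalization: baseline and anchor window means coincide"
        )
    value = (ratio - r0) / (rb - r0)
    return NormalizedSeries(
        time_s=time_s,
        value=value,
        kind=kind,
        baseline_window=tuple(baseline_window),
        anchor_window=tuple(anchor_window),
        raw_baseline_mean=rb,
        raw_anchor_mean=r0,
    )


def percent_change(
    trace: FluorescenceTrace,
    window_pre: Window,
    window_post: Window,
) -> dict:
    """Per-channel post/pre intensity ratios plus the raw-F/C reduction.

    For each channel the report holds mean(post-window)/mean(pre-window);
    ``fc_reduction_percent`` is the percent decrease of the raw FRET/CFP
    ratio between the two windows (positive = reduction).
    """
    pre = _window_mask(trace.time_s, window_pre)
    post = _window_mask(trace.time_s, window_post)
    report: dict = {}
    for name in ("cfp", "fret", "yfp"):
        arr = getattr(trace, name)
        if arr is None:
            continue
        report[name] = float(arr[post].mean() / arr[pre].mean())
    ratio = compute_ratio(trace)
    fc_pre = float(ratio[pre].mean())
    fc_post = float(ratio[post].mean())
    report["fc_ratio_post_over_pre"] = fc_post / fc_pre
    report["fc_reduction_percent"] = 100.0 * (1.0 - fc_post / fc_pre)
    return report


def channel_qc(
    trace: FluorescenceTrace,
    windows: Optional[list[Window]] = None,
    tolerance: float = 0.05,
) -> dict:
    """Flag traces whose direct-YFP control channel drifts between windows.

    The YFP channel reports acceptor fluorescence independent of FRET; a
    drift beyond ``tolerance`` (default 5%) between any two analysis
    windows indicates a pH or focus artifact.  Missing YFP yields verdict
    ``"not assessable"`` rather than failure.
    """
    if trace.yfp is None:
        return {"verdict": "not assessable", "reason": "no direct-YFP channel"}
    if windows is None:
        # default: quarters of the recording
        t0, t1 = float(trace.time_s[0]), float(trace.time_s[-1])
        edges = np.linspace(t0, t1, 5)
        windows = [(edges[i], edges[i + 1]) for i in range(4)]
    means = []
    for w in windows:
        means.append(float(trace.yfp[_window_mask(trace.time_s, w)].mean()))
    means = np.asarray(means)
    ref = means.mean()
    max_dev = float(np.max(np.abs(means - ref)) / ref)
    return {
        "verdict": "pass" if max_dev <= tolerance else "fail",
        "max_fractional_deviation": max_dev,
        "tolerance": tolerance,
        "window_means": means.tolist(),
    }
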