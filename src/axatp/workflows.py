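"""High-level measurement workflows.

These functions tie the generator and the analysis pipelines together the
way the documented experiments are evaluated: simulate a preset, push the
raw signals through the imaging and CAP pipelines, and extract the
kinetic readouts (onsets, HFS endpoints, drop ratios).  The analysis
drivers, the test suite and the acceptance script all call these.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from .cap import build_cap_series, define_window
from .imaging import NormalizedSeries, channel_qc, compute_ratio, normalize_ratio, percent_change
from .kinetics import detect_onset, hfs_metrics, max_decay_rate, recovery_metrics
from .presets import Preset, norm_anchor_window, preset
from .simulate import SimulationResult, simulate_experiment


def atp_series(sim: SimulationResult) -> NormalizedSeries:
    """Normalized ATP series of one simulated experiment.

    FRET/CFP ratio normalized to 1 over the pre-treatment baseline and to
    0 over the last 30 s of the MB+GD depletion anchor.
    """
    cfg = sim.config
    ratio = compute_ratio(sim.trace)
    return normalize_ratio(
        sim.trace.time_s,
        ratio,
        baseline_window=cfg.baseline_window,
        anchor_window=norm_anchor_window(cfg),
        kind="ATP",
    )


def cap_series(sim: SimulationResult) -> NormalizedSeries:
    """Normalized CAP-area series of one simulated experiment.

    The integration window is frozen from the averaged pre-treatment
    baseline sweeps; areas are normalized to the baseline-period mean.
    """
    cfg = sim.config
    t_end = cfg.baseline_window[1]
    baseline_sweeps = [s for s in sim.sweeps if s.stim_time_s <= t_end]
    window = define_window(baseline_sweeps)
    return build_cap_series(sim.sweeps, window, baseline_period_s=t_end)


def run(name: str, seed: int = 0, noiseless: bool = False) -> SimulationResult:
    """Simulate one replicate of a documented condition."""
    return simulate_experiment(preset(name, seed=seed, noiseless=noiseless))


def replicate_seeds(base_seed: int, n: int = 10) -> list[int]:
    """Per-nerve seeds derived from one base seed (kept below 2**31)."""
    ss = np.random.SeedSequence(entropy=base_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def mbgd_fc_reduction(sim: SimulationResult, minute: float = 2.0) -> float:
    """Raw F/C percent reduction after ``minute`` minutes of MB+GD.

    Compares the last minute of baseline against the 30 s leading up to
    the stated treatment minute (the channel-level ratio, before
    normalization).
    """
    cfg = sim.config
    t0 = cfg.treatment_window[0]
    pre = (t0 - 60.0, t0)
    post = (t0 + minute * 60.0 - 30.0, t0 + minute * 60.0)
    return percent_change(sim.trace, pre, post)["fc_reduction_percent"]


def decay_onset_min(
    sim: SimulationResult,
    series: NormalizedSeries | None = None,
    k_sd: float = 3.0,
) -> float:
    """ATP (or given series') decay onset relative to treatment start, min."""
    cfg = sim.config
    if series is None:
        series = atp_series(sim)
    onset_s = detect_onset(
        series,
        baseline_window=cfg.baseline_window,
        k_sd=k_sd,
        direction="down",
        search_start_s=cfg.treatment_window[0],
    )
    return (onset_s - cfg.treatment_window[0]) / 60.0


def hfs_endpoints(sim: SimulationResult) -> dict:
    """End-of-HFS readouts of one simulated HFS experiment.

    Returns normalized ATP and CAP overall amplitudes (mean of the last
    15 s of stimulation), the initial decay and post-stimulation recovery
    rates, the ATP/CAP drop ratio, and the YFP-channel QC verdict.
    """
    prot = sim.preset.protocol
    t0, t1 = prot.hfs_start_s, prot.hfs_end_s
    atp = atp_series(sim)
    cap = cap_series(sim)
    atp_amp, atp_decay, atp_rec = hfs_metrics(atp, t0, t1)
    cap_amp, cap_decay, cap_rec = hfs_metrics(cap, t0, t1)
    qc = channel_qc(sim.trace, windows=[sim.config.baseline_window, (t1 - 60.0, t1)])
    return {
        "atp_amplitude": atp_amp,
        "cap_amplitude": cap_amp,
        "atp_initial_decay_rate": atp_decay,
        "cap_initial_decay_rate": cap_decay,
        "atp_recovery_rate": atp_rec,
        "cap_recovery_rate": cap_rec,
        "drop_ratio": atp_amp / cap_amp if cap_amp else float("nan"),
        "yfp_qc": qc["verdict"],
    }


def deprivation_kinetics(sim: SimulationResult) -> dict:
    """Onset / decay-rate / recovery readouts of a deprivation experiment."""
    cfg = sim.config
    t0, t1 = cfg.treatment_window
    atp = atp_series(sim)
    cap = cap_series(sim)
    out: dict = {}
    for label, series in (("atp", atp), ("cap", cap)):
        onset = detect_onset(series, cfg.baseline_window, direction="down",
                             search_start_s=t0)
        rate = max_decay_rate(series, (t0, t1 + 60.0))
        rec_end = cfg.anchor_window[0] if cfg.treatment != "MBGD" else cfg.total_duration_s
        sub = NormalizedSeries(
            time_s=series.time_s[series.time_s <= rec_end],
            value=series.value[series.time_s <= rec_end],
            kind=series.kind,
            baseline_window=cfg.baseline_window,
        )
        rec_onset, rec_rate, overall = recovery_metrics(
            sub, reperfusion_start_s=t1, baseline_window=cfg.baseline_window
        )
        out[f"{label}_onset_min"] = (onset - t0) / 60.0
        out[f"{label}_max_decay_rate"] = rate
        out[f"{label}_recovery_onset_s"] = rec_onset - t1
        out[f"{label}_recovery_rate"] = rec_rate
        out[f"{label}_overall_recovery"] = overall
    return out


def mean_over_seeds(
    name: str,
    measure: Callable[[SimulationResult], float],
    seeds: Iterable[int],
) -> tuple[float, float, list[float]]:
    """Mean and s.e.m. of a scalar readout over replicate simulations."""
    values = [float(measure(run(name, seed=s))) for s in seeds]
    arr = np.asarray(values)
    sem = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else float("nan")
    return float(arr.mean()), float(sem), values
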