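"""Synthetic CAP sweep generator.

Each recorded sweep is a stimulus artifact at t = 0 plus a sum of Gaussian
peaks.  Peak amplitudes are scaled by ``psi_fatigue(f, t) * phi(A)``:

* ``psi_fatigue`` relaxes toward a frequency-dependent plateau
  ``1 - beta(f)`` with time constant ``tau_fatigue_s`` during stimulation
  and recovers toward 1 with ``tau_recovery_s`` afterwards (use-dependent
  conduction fatigue, present even at maintained ATP);
* ``phi(A) = min(1, A/A_safe)^q`` degrades conduction only once axonal ATP
  falls below the safety threshold ``A_safe``.

One sweep is recorded per baseline stimulus and one per HFS burst (the
CAP is acquired during the inter-burst recording gap).  Peak latencies
drift by ``latency_drift_ms * (1 - psi)`` during fatigue; amplitudes
generally decrease while latencies increase, and the frozen-window area
metric integrates both changes.
"""

from __future__ import annotations

import numpy as np

from .cap import CapSweep
from .energy import EnergyTrace
from .params import CapShapeParams, StimProtocol


def phi_conduction(a_mM, a_safe_mM: float, exponent: float = 4.0):
    """ATP-dependence of conduction: min(1, A/A_safe)^q (1 above A_safe)."""
    a = np.asarray(a_mM, dtype=float)
    out = np.minimum(1.0, a / a_safe_mM) ** exponent
    return float(out) if np.isscalar(a_mM) else out


def fatigue_trace(
    prot: StimProtocol,
    shape: CapShapeParams,
    total_s: float,
    dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """psi_fatigue(t) on a regular grid, by first-order relaxation.

    d(psi)/dt = (psi_target - psi)/tau with psi_target = 1 - beta(f(t)),
    tau = tau_fatigue_s while fatiguing (target below psi) and
    tau_recovery_s while recovering.
    """
    n = int(round(total_s / dt)) + 1
    time_s = np.arange(n) * dt
    target = np.ones(n)
    for start, end, mode, hz in prot.segments(total_s):
        if mode == "hfs":
            m = (time_s >= start) & (time_s < end)
            target[m] = 1.0 - shape.fatigue_beta(hz, prot.effective_rate(hz))
    psi = np.empty(n)
    x = 1.0
    for i in range(n):
        psi[i] = x
        if i == n - 1:
            break
        tau = shape.tau_fatigue_s if target[i] < x else shape.tau_recovery_s
        x += dt * (target[i] - x) / tau
    return time_s, psi


def sweep_times(prot: StimProtocol, total_s: float) -> np.ndarray:
    """Stimulus times at which a CAP sweep is recorded.

    One sweep per baseline stimulus (at ``baseline_hz``) and one per HFS
    burst, timestamped at the end of the burst (the sweep is acquired in
    the following inter-burst gap).
    """
    times: list[float] = []
    for start, end, mode, hz in prot.segments(total_s):
        if mode == "baseline":
            period = 1.0 / prot.baseline_hz
            times.extend(np.arange(start, end - 1e-9, period))
        else:
            cycle = prot.burst_size / hz + prot.inter_burst_ms / 1000.0
            t = start
            while t + prot.burst_size / hz <= end + 1e-9:
                times.append(t + prot.burst_size / hz)
                t += cycle
    return np.asarray(sorted(times))


def render_sweep(
    t_ms: np.ndarray,
    shape: CapShapeParams,
    scale: float = 1.0,
    drift_ms: float = 0.0,
) -> np.ndarray:
    """Noiseless sweep voltage: artifact + scaled, shifted Gaussian peaks."""
    v = shape.artifact_amplitude_mV * np.exp(
        -0.5 * (t_ms / shape.artifact_width_ms) ** 2
    )
    for amp, lat, w in zip(shape.amplitudes_mV, shape.latencies_ms, shape.widths_ms):
        v = v + scale * amp * np.exp(-0.5 * ((t_ms - (lat + drift_ms)) / w) ** 2)
    return v


def simulate_caps(
    energy: EnergyTrace,
    prot: StimProtocol,
    shape: CapShapeParams,
    rng: np.random.Generator,
    a_safe_mM: float = 0.3,
) -> list[CapSweep]:
    """Generate the recorded CAP sweeps for one experiment.

    Peak amplitudes at stimulus time t are scaled by
    ``psi_fatigue(t) * phi(A(t))``; latencies are shifted by
    ``latency_drift_ms * (1 - psi(t))``; Gaussian noise of s.d.
    ``shape.noise_sd`` (mV) is added per sample.

    Raises ``ValueError`` if the ATP trace does not cover the protocol.
    """
    total_s = float(energy.time_s[-1])
    stim_times = sweep_times(prot, total_s)
    if stim_times.size == 0:
        raise ValueError("protocol yields no sweeps within the ATP trace")
    if prot.hfs_end_s is not None and prot.hfs_end_s > total_s + 1e-9:
        raise ValueError("ATP trace shorter than the stimulation protocol")

    step_ms = 1000.0 / shape.sample_rate
    n_pre = int(round(shape.sweep_pre_ms / step_ms))
    n_post = int(round(shape.sweep_post_ms / step_ms))
    t_ms = (np.arange(n_pre + n_post + 1) - n_pre) * step_ms

    _, psi_grid = fatigue_trace(prot, shape, total_s, dt=0.1)
    psi_times = np.arange(psi_grid.size) * 0.1
    psi = np.interp(stim_times, psi_times, psi_grid)
    a = energy.at(stim_times)
    scale = psi * phi_conduction(a, a_safe_mM, shape.phi_exponent)
    drift = shape.latency_drift_ms * (1.0 - psi)

    sweeps = []
    for k, st in enumerate(stim_times):
        v = render_sweep(t_ms, shape, scale=float(scale[k]), drift_ms=float(drift[k]))
        if shape.noise_sd > 0:
            v = v + rng.normal(0.0, shape.noise_sd, size=v.shape)
        sweeps.append(
            CapSweep(
                stim_time_s=float(st),
                t_ms=t_ms.copy(),
                v_mV=v,
                sample_rate=shape.sample_rate,
                sweep_id=k,
            )
        )
    return sweeps
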