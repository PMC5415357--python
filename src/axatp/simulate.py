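"""End-to-end simulation of one nerve experiment.

``simulate_experiment`` runs the energy model, renders the fluorescence
channels at the imaging cadence and the CAP sweeps at the stimulation
schedule, and returns everything in one bundle.  All randomness derives
from the config seed through a ``SeedSequence``, so identical seeds and
configs yield bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cap import CapSweep
from .capsim import simulate_caps
from .energy import EnergyTrace, simulate_energy
from .imaging import FluorescenceTrace
from .presets import Preset
from .sensor import emit_channels


@dataclass
class SimulationResult:
    """Raw outputs of one simulated experiment."""

    preset: Preset
    energy: EnergyTrace
    trace: FluorescenceTrace
    sweeps: list[CapSweep]
    qc: dict = field(default_factory=dict)

    @property
    def config(self):
        return self.preset.config


def frame_times(total_s: float, frame_interval_s: float) -> np.ndarray:
    n = int(np.floor(total_s / frame_interval_s)) + 1
    return np.arange(n) * frame_interval_s


def simulate_experiment(preset: Preset, dt: float = 0.1) -> SimulationResult:
    """Simulate energy state, imaging channels and CAP sweeps for a preset."""
    cfg = preset.config
    energy = simulate_energy(cfg, preset.protocol, preset.energy, dt=dt)

    ss = np.random.SeedSequence(entropy=cfg.seed)
    rng_img, rng_cap = (np.random.default_rng(s) for s in ss.spawn(2))

    t_frames = frame_times(cfg.total_duration_s, cfg.frame_interval_s)
    trace, qc = emit_channels(t_frames, energy.at(t_frames), preset.sensor, rng_img)
    trace.meta.update({"preset": cfg.name, "seed": cfg.seed})

    sweeps = simulate_caps(
        energy,
        preset.protocol,
        preset.cap_shape,
        rng_cap,
        a_safe_mM=preset.energy.A_safe,
    )
    return SimulationResult(preset=preset, energy=energy, trace=trace,
                            sweeps=sweeps, qc=qc)
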