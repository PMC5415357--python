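"""Calibrated experiment presets.

Each preset bundles the experiment layout (bath, treatment and analysis
windows), the stimulation protocol, and the calibrated generator
parameters for one documented condition:

* energy-deprivation experiments: ``"GD"`` (45 min glucose deprivation),
  ``"MB"`` (5 min azide), ``"MBGD"`` (5 min azide + glucose deprivation);
* high-frequency stimulation: ``"HFS{16|50|100}@glc{10|3.3|2}"`` (150 s
  of burst stimulation in the given bath glucose) and ``"ramp"``
  (1 -> 100 Hz, 45 s per step);
* substrate experiments at 100 Hz: ``"lactate10"``, ``"pyruvate10"``
  (10 mM exogenous monocarboxylate, no glucose), ``"Dlac"`` (3.3 mM
  glucose + 20 mM D-lactate) and ``"ARC"`` (3.3 mM glucose + 10 uM
  AR-C155858).

Treatment and HFS onsets sit on the 10.4 s imaging frame grid (312 s = 30
frames of baseline), and every preset ends with (or contains) a
mitochondrial-blockade + glucose-deprivation application whose last 30 s
anchor the normalized ATP zero.

The free model constants below (``CAL``) were fitted with the noiseless
generator -> pipeline loop against the documented endpoint and onset
values (see ``scripts/calibrate_presets.py``); they are the package
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

from .energy import balanced_glc10_params
from .params import (
    CapShapeParams,
    EnergyModelParams,
    ExperimentConfig,
    SensorParams,
    StimProtocol,
)

FRAME_S = 10.4
BASELINE_END_S = 312.0          # 30 frames of pre-treatment baseline

#: Calibrated constants (fitted against the documented endpoints with the
#: noiseless pipeline; see scripts/calibrate_presets.py).
CAL: Dict[str, float] = {
    "c_spike": 0.00213411,      # mM ATP per propagated spike (100 Hz ATP endpoint)
    "B_0": 1.0,                 # mM buffer (MB+GD onset ~0.5 min)
    "pasteur_boost": 3.5625,    # azide glycolytic boost (MB onset ~1.8 min)
    "G_0": 60.4167,             # mM glycogen reserve (GD onset ~13 min)
    "R_min": 1.3093,           # sensor floor (raw F/C drop ~35.1% under MB+GD)
    "exo_eff_lactate": 0.232505,   # 10 mM lactate ATP endpoint
    "exo_eff_pyruvate": 0.200975,  # 10 mM pyruvate ATP endpoint
    "mct_dlac": 0.562964,       # D-lactate shuttle inhibition (ATP endpoint)
    "mct_arc": 0.510182,        # AR-C155858 shuttle inhibition (ATP endpoint)
    "beta_16": 0.0515675,       # fatigue depths (CAP endpoints at 10 mM glucose)
    "beta_50": 0.206944,
    "beta_100": 0.341511,
}


@dataclass
class Preset:
    """Fully populated parameter bundle for one documented condition."""

    config: ExperimentConfig
    protocol: StimProtocol
    energy: EnergyModelParams
    sensor: SensorParams
    cap_shape: CapShapeParams

    def with_seed(self, seed: int) -> "Preset":
        return replace(self, config=replace(self.config, seed=seed))

    def noiseless(self) -> "Preset":
        return replace(
            self,
            sensor=replace(self.sensor, noise_sd=0.0),
            cap_shape=replace(self.cap_shape, noise_sd=0.0),
        )


def _sensor() -> SensorParams:
    return SensorParams(R_min=CAL["R_min"], R_max=CAL["R_min"] + 1.0)


def _cap_shape() -> CapShapeParams:
    return CapShapeParams(
        fatigue_table={16.0: CAL["beta_16"], 50.0: CAL["beta_50"], 100.0: CAL["beta_100"]}
    )


def _energy(**overrides) -> EnergyModelParams:
    base = dict(
        c_spike=CAL["c_spike"],
        B_0=CAL["B_0"],
        pasteur_boost=CAL["pasteur_boost"],
        G_0=CAL["G_0"],
    )
    base.update(overrides)
    return balanced_glc10_params(**base)


def _deprivation(name: str, treatment: str, treat_len_s: float,
                 recovery_len_s: float) -> Preset:
    t0 = BASELINE_END_S
    t1 = t0 + treat_len_s
    if treatment == "MBGD":
        anchor = (t0, t1)
        total = t1 + recovery_len_s
    else:
        a0 = t1 + recovery_len_s
        anchor = (a0, a0 + 300.0)
        total = a0 + 300.0
    cfg = ExperimentConfig(
        name=name,
        glucose_mM=10.0,
        treatment=treatment,
        treatment_window=(t0, t1),
        anchor_window=anchor,
        baseline_window=(0.0, t0),
        total_duration_s=total,
    )
    prot = StimProtocol(baseline_hz=0.1)
    return Preset(cfg, prot, _energy(), _sensor(), _cap_shape())


def _hfs(name: str, hz: Optional[float], glucose_mM: float,
         substrate: str = "none", substrate_mM: float = 0.0,
         inhibitor: str = "none",
         ramp: Optional[Tuple[Tuple[float, float], ...]] = None,
         energy_overrides: Optional[dict] = None) -> Preset:
    t0 = BASELINE_END_S
    prot = StimProtocol(
        baseline_hz=0.1,
        hfs_hz=hz,
        ramp=list(ramp) if ramp else None,
        hfs_start_s=t0,
    )
    t1 = prot.hfs_end_s
    a0 = t1 + 300.0                      # post-HFS recovery before the anchor
    cfg = ExperimentConfig(
        name=name,
        glucose_mM=glucose_mM,
        substrate=substrate,
        substrate_mM=substrate_mM,
        inhibitor=inhibitor,
        treatment="none",
        treatment_window=(t0, t1),
        anchor_window=(a0, a0 + 300.0),
        baseline_window=(0.0, t0),
        total_duration_s=a0 + 300.0,
    )
    return Preset(
        cfg, prot, _energy(**(energy_overrides or {})), _sensor(), _cap_shape()
    )


def _build(name: str) -> Preset:
    if name == "GD":
        return _deprivation("GD", "GD", 2700.0, 900.0)
    if name == "MB":
        return _deprivation("MB", "MB", 300.0, 900.0)
    if name == "MBGD":
        return _deprivation("MBGD", "MBGD", 300.0, 600.0)
    if name.startswith("HFS"):
        freq_part, glc_part = name[3:].split("@glc")
        return _hfs(name, float(freq_part), float(glc_part))
    if name == "lactate10":
        return _hfs(name, 100.0, 0.0, substrate="lactate", substrate_mM=10.0,
                    energy_overrides={"exo_efficiency": CAL["exo_eff_lactate"],
                                      "G_0": 0.0})
    if name == "pyruvate10":
        return _hfs(name, 100.0, 0.0, substrate="pyruvate", substrate_mM=10.0,
                    energy_overrides={"exo_efficiency": CAL["exo_eff_pyruvate"],
                                      "G_0": 0.0})
    if name == "Dlac":
        return _hfs(name, 100.0, 3.3, inhibitor="D-lactate",
                    energy_overrides={"mct_factor": CAL["mct_dlac"]})
    if name == "ARC":
        return _hfs(name, 100.0, 3.3, inhibitor="AR-C155858",
                    energy_overrides={"mct_factor": CAL["mct_arc"]})
    if name == "ramp":
        steps = tuple((float(f), 45.0) for f in (1, 2, 4, 8, 16, 32, 50, 100))
        return _hfs(name, None, 10.0, ramp=steps)
    raise KeyError(
        f"unknown preset {name!r}; valid names: {', '.join(preset_names())}"
    )


def preset_names() -> list[str]:
    names = ["GD", "MB", "MBGD"]
    names += [f"HFS{f}@glc{g}" for f in (16, 50, 100) for g in ("10", "3.3", "2")]
    names += ["lactate10", "pyruvate10", "Dlac", "ARC", "ramp"]
    return names


def preset(name: str, seed: int = 0, noiseless: bool = False) -> Preset:
    """Look up a documented condition by name.

    Raises ``KeyError`` listing the valid names for unknown conditions.
    """
    b = _build(name)
    b = b.with_seed(seed)
    if noiseless:
        b = b.noiseless()
    return b


def norm_anchor_window(cfg: ExperimentConfig, span_s: float = 30.0) -> Tuple[float, float]:
    """Normalization zero-anchor: the last ``span_s`` of the MB+GD application."""
    a0, a1 = cfg.anchor_window
    return (max(a0, a1 - span_s), a1)
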