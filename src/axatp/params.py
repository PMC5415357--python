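"""Parameter containers for the synthetic-data generator.

Four parameter sets fully describe a simulated experiment:

``SensorParams``
    Hill-type binding/emission model of the FRET ATP sensor (CFP donor,
    YFP acceptor) and the gains/noise of the three recorded channels.
``EnergyModelParams``
    Minimal lumped axonal energy-balance model: direct axonal glycolysis
    fed by bath glucose, mitochondrial ATP production fed by
    monocarboxylates (glucose- or glycogen-derived lactate/pyruvate
    shuttled through MCTs, or exogenous lactate/pyruvate), a
    phosphagen-like rapid buffer, an ion-gradient debt pool, and
    activity-dependent consumption.
``StimProtocol``
    Baseline stimulation plus optional high-frequency stimulation (HFS)
    delivered as bursts of ``burst_size`` stimuli separated by a recording
    gap, as used for evoked CAP experiments.
``CapShapeParams``
    Parametric evoked-waveform model: stimulus artifact plus a sum of
    Gaussian peaks, with frequency/time-dependent fatigue and latency
    drift.

All classes validate their invariants on construction and raise
``ValueError`` on violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SensorParams:
    """Hill binding + three-channel emission model of the ATP sensor.

    The intrinsic FRET/CFP ratio of the sensor at ATP concentration ``A``
    (mM) is ``R(A) = R_min + (R_max - R_min) * A^n / (K_D^n + A^n)``.
    ``K_D`` defaults to 1.2 mM (ATeam1.03-YEMK class sensor); ``R_min``,
    ``R_max``, ``hill_n``, gains, bleed-through and noise are generator
    conventions, not measured in-situ constants.  ``R_min``/``R_max`` are
    calibrated so that depleting ATP from rest to zero lowers the raw
    channel-level F/C ratio by about 35%.
    """

    K_D: float = 1.2                 # mM, half-saturation
    hill_n: float = 2.0              # Hill coefficient
    R_min: float = 1.3093           # intrinsic F/C at zero ATP (calibrated)
    R_max: float = 2.3093           # intrinsic F/C at saturating ATP
    cfp_gain: float = 1000.0         # a.u., donor-channel scale
    fret_gain: float = 1000.0        # a.u., FRET-channel scale
    yfp_gain: float = 800.0          # a.u., direct-YFP channel scale
    bleedthrough: float = 0.05       # fraction of donor emission in FRET channel
    noise_sd: float = 0.005          # per-frame additive noise, fraction of baseline

    def __post_init__(self) -> None:
        _require(self.K_D > 0, "K_D must be > 0")
        _require(self.hill_n > 0, "hill_n must be > 0")
        _require(0 < self.R_min < self.R_max, "need 0 < R_min < R_max")
        _require(0 <= self.bleedthrough < 1, "bleedthrough must be in [0, 1)")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(
            self.cfp_gain > 0 and self.fret_gain > 0 and self.yfp_gain > 0,
            "channel gains must be > 0",
        )


@dataclass
class EnergyModelParams:
    """Lumped axonal energy-balance model (all fluxes in mM ATP / s).

    dA/dt = J_glyc + J_mito + J_buf - C - dB_refill with:

    * direct glycolysis ``J_glyc = V_glc * glc/(glc + K_glc) * pasteur``
      plus, while bath glucose is absent and glycogen remains, a small
      azide-insensitive glycogen-fed term ``V_gly * G/(G + K_G)``; the
      Pasteur factor transiently boosts glycolysis after respiratory
      blockade (``pasteur_boost`` decaying to ``pasteur_floor`` with
      ``tau_pasteur_s``) and is 1 otherwise;
    * ``J_mito = (1 - azide) * V_mito * min(1, s)`` with substrate supply
      ``s = (eta_shuttle * glc/(glc+K_glc) * mct + gly_shuttle *
      [glc~0] * G/(G+K_G) * mct + exo_efficiency * mct * S/(S+K_sub)) *
      (1 + demand_gain * max(0, 1 - A/A_base))`` — glucose- and
      glycogen-derived monocarboxylates plus exogenous lactate/pyruvate,
      all scaled by an ADP-like demand factor and by the MCT transport
      factor ``mct`` (reduced by D-lactate / AR-C155858);
    * rapid buffer ``J_buf = k_buf * (B/B_0) * max(0, A_base - A)/A_base``
      with dB/dt = -J_buf, plus slow ATP-consuming refill (``k_refill``)
      once A is back at rest;
    * consumption ``C = (c_0 + c_spike * f(t)) * A/(A + K_A)`` plus
      repayment of the ion-gradient debt pool D, which accrues while ATP
      is too low to sustain pumping (A below ``debt_threshold``) and is
      repaid at ``min(c_repay * D/(D + K_debt), repay_frac * production)``
      — the pumps claim most newly made ATP first, so the ATP signal
      recovers after conduction does.

    A is clipped to [0, A_max].  Defaults are the calibrated 10 mM glucose
    condition.
    """

    A_base: float = 2.0              # mM, resting axonal ATP
    A_max: float = 2.6               # mM, ceiling
    V_glc: float = 0.02144567         # mM/s, maximal glucose-fed glycolytic flux
    K_glc: float = 0.7               # mM, glucose half-saturation
    V_gly: float = 0.012             # mM/s, glycogen-fed (azide-insensitive) flux
    G_0: float = 60.4167             # mM ATP-equivalents, glycogen reserve
    K_G: float = 1.5                 # mM, glycogen tail half-saturation
    gly_shuttle: float = 0.27268292    # glycogen-derived monocarboxylate supply (sat units)
    V_mito: float = 0.25             # mM/s, maximal mitochondrial ATP flux
    K_sub: float = 1.0               # mM, exogenous monocarboxylate half-saturation
    eta_shuttle: float = 0.25734804    # glucose-derived shuttle supply at rest (sat units)
    exo_efficiency: float = 1.0      # per-substrate mitochondrial yield factor
    mct_factor: float = 1.0          # MCT transport factor (reduced by inhibitors)
    demand_gain: float = 4.0         # ADP-like activation of substrate supply
    pasteur_boost: float = 3.5625    # initial glycolytic boost under azide
    pasteur_floor: float = 0.5       # late glycolytic factor under azide
    tau_pasteur_s: float = 150.0     # decay of the azide glycolytic boost
    B_0: float = 1.0                 # mM, phosphagen-like buffer size
    k_buf: float = 0.3               # 1/s, buffer release rate
    k_refill: float = 0.01           # 1/s, slow buffer refill rate
    c_0: float = 0.1                 # mM/s, resting consumption scale
    c_spike: float = 2.13411e-3      # mM per propagated action potential
    K_A: float = 0.5                 # mM, consumption half-saturation in ATP
    A_safe: float = 0.3              # mM, ATP level below which conduction degrades
    k_debt: float = 0.02             # mM/s, ion-gradient debt accrual at zero ATP
    debt_threshold: float = 0.4      # mM, ATP level below which debt accrues
    debt_max: float = 8.0            # mM, debt pool ceiling
    c_repay: float = 0.5             # mM/s, maximal debt repayment consumption
    K_debt: float = 1.0              # mM, debt repayment half-saturation
    repay_frac: float = 0.82         # production share claimed by repayment

    def __post_init__(self) -> None:
        nonneg = [
            "V_glc", "K_glc", "V_gly", "G_0", "K_G", "gly_shuttle", "V_mito",
            "K_sub", "B_0", "k_buf", "k_refill", "c_0", "c_spike", "K_A",
            "A_safe", "A_base", "A_max", "exo_efficiency", "mct_factor",
            "demand_gain", "k_debt", "debt_threshold", "debt_max", "c_repay",
            "K_debt",
        ]
        for name in nonneg:
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.A_base <= self.A_max, "A_base must be <= A_max")
        _require(0 <= self.eta_shuttle <= 1, "eta_shuttle must be in [0, 1]")
        _require(self.pasteur_boost >= self.pasteur_floor >= 0,
                 "need pasteur_boost >= pasteur_floor >= 0")
        _require(self.tau_pasteur_s > 0, "tau_pasteur_s must be > 0")
        _require(0 <= self.repay_frac <= 1, "repay_frac must be in [0, 1]")


@dataclass
class StimProtocol:
    """Stimulation schedule: baseline rate plus an optional HFS block.

    During HFS, stimuli are delivered as bursts of ``burst_size`` pulses
    at ``hfs_hz``; bursts are separated by a recording gap of
    ``inter_burst_ms`` during which one CAP sweep is acquired.  A ramp
    protocol (list of ``(hz, duration_s)`` steps) may be supplied instead
    of a single frequency.
    """

    baseline_hz: float = 0.1
    hfs_hz: Optional[float] = None
    ramp: Optional[Sequence[Tuple[float, float]]] = None   # (hz, duration_s) steps
    burst_size: int = 100
    inter_burst_ms: float = 460.0
    hfs_duration_s: float = 150.0
    hfs_start_s: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.baseline_hz > 0, "baseline_hz must be > 0")
        _require(self.burst_size >= 1, "burst_size must be >= 1")
        _require(self.inter_burst_ms > 0, "inter_burst_ms must be > 0")
        _require(self.hfs_duration_s > 0, "hfs_duration_s must be > 0")
        if self.hfs_hz is not None or self.ramp is not None:
            _require(self.hfs_start_s is not None, "HFS requires hfs_start_s")
        if self.ramp is not None:
            _require(len(self.ramp) > 0, "ramp must have at least one step")
            _require(all(f > 0 and d > 0 for f, d in self.ramp),
                     "ramp steps need positive frequency and duration")

    def effective_rate(self, hz: float) -> float:
        """Burst-averaged stimulation rate (Hz) at burst frequency ``hz``."""
        burst_s = self.burst_size / hz
        return self.burst_size / (burst_s + self.inter_burst_ms / 1000.0)

    @property
    def hfs_end_s(self) -> Optional[float]:
        if self.hfs_start_s is None:
            return None
        if self.ramp is not None:
            return self.hfs_start_s + sum(d for _, d in self.ramp)
        return self.hfs_start_s + self.hfs_duration_s

    def segments(self, total_s: float) -> list[tuple[float, float, str, float]]:
        """Time-ordered ``(start, end, mode, hz)`` schedule over the run.

        ``mode`` is ``"baseline"`` or ``"hfs"``; ``hz`` is the burst
        frequency of the segment.
        """
        if self.hfs_start_s is None:
            return [(0.0, total_s, "baseline", self.baseline_hz)]
        segs: list[tuple[float, float, str, float]] = []
        t0 = float(self.hfs_start_s)
        _require(0 < t0 < total_s, "HFS window must lie inside the run")
        segs.append((0.0, t0, "baseline", self.baseline_hz))
        if self.ramp is not None:
            t = t0
            for hz, dur in self.ramp:
                segs.append((t, t + dur, "hfs", float(hz)))
                t += dur
        else:
            t = t0 + self.hfs_duration_s
            segs.append((t0, t, "hfs", float(self.hfs_hz)))
        _require(t <= total_s, "HFS extends beyond the run")
        if t < total_s:
            segs.append((t, total_s, "baseline", self.baseline_hz))
        return segs


#: Fatigue depths at the three standard burst frequencies, calibrated so the
#: full sweep pipeline reproduces the documented end-of-HFS CAP levels at
#: 10 mM glucose.  Other frequencies use a power law anchored at 100 Hz.
DEFAULT_FATIGUE_TABLE: Dict[float, float] = {
    16.0: 0.0515675,
    50.0: 0.206944,
    100.0: 0.341511,
}


@dataclass
class CapShapeParams:
    """Parametric CAP waveform: stimulus artifact + sum of Gaussian peaks.

    The three peaks of the baseline optic-nerve CAP are modelled as
    Gaussians; only the first two fall inside the standard analysis
    window.  During HFS peak amplitudes are scaled by
    ``psi_fatigue(f, t) * phi(A)`` and latencies drift by
    ``latency_drift_ms * (1 - psi)``.
    """

    amplitudes_mV: Tuple[float, ...] = (1.4, 1.0, 0.35)
    latencies_ms: Tuple[float, ...] = (0.6, 1.15, 2.3)
    widths_ms: Tuple[float, ...] = (0.10, 0.16, 0.30)
    response_onset_ms: float = 0.2
    artifact_amplitude_mV: float = 3.0
    artifact_width_ms: float = 0.04
    latency_drift_ms: float = 0.3    # maximal drift at full fatigue
    fatigue_table: Dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_FATIGUE_TABLE)
    )
    fatigue_exponent: float = 1.24   # power-law scaling of beta with burst rate
    tau_fatigue_s: float = 40.0      # fatigue onset time constant
    tau_recovery_s: float = 60.0     # fatigue recovery time constant
    phi_exponent: float = 4.0        # exponent of the ATP-dependence phi(A)
    sweep_pre_ms: float = 1.0        # recorded time before the stimulus
    sweep_post_ms: float = 5.0       # recorded time after the stimulus
    sample_rate: int = 20_000        # Hz, 20 or 100 kHz
    noise_sd: float = 0.02           # mV, per-sample additive noise

    def __post_init__(self) -> None:
        n = len(self.amplitudes_mV)
        _require(len(self.latencies_ms) == n and len(self.widths_ms) == n,
                 "per-peak parameter tuples must have equal length")
        _require(all(w > 0 for w in self.widths_ms), "peak widths must be > 0")
        _require(all(l >= self.response_onset_ms for l in self.latencies_ms),
                 "peak latencies must be >= response_onset_ms")
        _require(self.sample_rate in (20_000, 100_000),
                 "sample_rate must be 20 kHz or 100 kHz")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.sweep_pre_ms > 0 and self.sweep_post_ms > 0,
                 "sweep extents must be > 0")
        _require(all(0 <= b < 1 for b in self.fatigue_table.values()),
                 "fatigue depths must be in [0, 1)")

    @property
    def n_peaks(self) -> int:
        return int(len(self.amplitudes_mV))

    def fatigue_beta(self, hz: float, effective_rate: float) -> float:
        """Fatigue depth (asymptotic fractional CAP loss) at burst rate ``hz``.

        Uses the calibrated per-frequency table when available; otherwise a
        power law in the burst-averaged rate anchored at the 100 Hz entry.
        Baseline-rate stimulation produces no fatigue.
        """
        if effective_rate <= 0.2:
            return 0.0
        for key, beta in self.fatigue_table.items():
            if abs(hz - key) < 1e-6:
                return float(beta)
        ref_hz = 100.0
        ref_beta = self.fatigue_table.get(ref_hz, 0.344)
        ref_rate = self.burst_rate(ref_hz)
        beta = ref_beta * (effective_rate / ref_rate) ** self.fatigue_exponent
        return float(min(beta, 0.95))

    @staticmethod
    def burst_rate(hz: float, burst_size: int = 100, gap_ms: float = 460.0) -> float:
        return burst_size / (burst_size / hz + gap_ms / 1000.0)


@dataclass
class ExperimentConfig:
    """One simulated nerve experiment.

    ``treatment`` names what is applied during ``treatment_window``:
    ``"none"`` (bath unchanged; HFS experiments change only stimulation),
    ``"GD"`` (bath glucose removed), ``"MB"`` (azide added) or ``"MBGD"``
    (both).  ``anchor_window`` is the terminal (or, for MBGD treatments,
    the in-treatment) full-depletion window that defines normalized zero;
    ``baseline_window`` defines normalized one.
    """

    name: str = "custom"
    glucose_mM: float = 10.0
    substrate: str = "none"          # none | lactate | pyruvate
    substrate_mM: float = 0.0
    inhibitor: str = "none"          # none | D-lactate | AR-C155858
    treatment: str = "none"          # none | GD | MB | MBGD
    treatment_window: Tuple[float, float] = (312.0, 612.0)
    anchor_window: Tuple[float, float] = (582.0, 612.0)
    baseline_window: Tuple[float, float] = (0.0, 312.0)
    total_duration_s: float = 1212.0
    frame_interval_s: float = 10.4
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.frame_interval_s > 0, "frame_interval_s must be > 0")
        _require(self.total_duration_s > 0, "total_duration_s must be > 0")
        _require(self.glucose_mM >= 0 and self.substrate_mM >= 0,
                 "concentrations must be >= 0")
        _require(self.substrate in ("none", "lactate", "pyruvate"),
                 f"unknown substrate {self.substrate!r}")
        _require(self.inhibitor in ("none", "D-lactate", "AR-C155858"),
                 f"unknown inhibitor {self.inhibitor!r}")
        _require(self.treatment in ("none", "GD", "MB", "MBGD"),
                 f"unknown treatment {self.treatment!r}")
        for w, label in [
            (self.treatment_window, "treatment_window"),
            (self.anchor_window, "anchor_window"),
            (self.baseline_window, "baseline_window"),
        ]:
            _require(0 <= w[0] < w[1] <= self.total_duration_s,
                     f"{label} must lie inside the run")

    def bath_at(self, t: float) -> dict:
        """Bath composition at experiment time ``t`` (s).

        Returns glucose (mM), exogenous substrate kind and concentration,
        and the azide flag.  The anchor window always applies MB+GD
        (azide, zero glucose) to deplete ATP.
        """
        glc = self.glucose_mM
        azide = False
        t0, t1 = self.treatment_window
        if t0 <= t < t1:
            if self.treatment in ("GD", "MBGD"):
                glc = 0.0
            if self.treatment in ("MB", "MBGD"):
                azide = True
        a0, a1 = self.anchor_window
        if a0 <= t < a1:
            glc, azide = 0.0, True
        return {
            "glucose_mM": glc,
            "substrate": self.substrate,
            "substrate_mM": self.substrate_mM,
            "azide": azide,
        }

    def azide_onset_before(self, t: float) -> Optional[float]:
        """Start time of the azide application covering ``t``, if any."""
        t0, t1 = self.treatment_window
        if self.treatment in ("MB", "MBGD") and t0 <= t < t1:
            return t0
        a0, a1 = self.anchor_window
        if a0 <= t < a1:
            return a0
        return None

    def to_dict(self) -> dict:
        return asdict(self)
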