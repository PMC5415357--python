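"""Minimal axonal energy-balance model.

Forward-integrates the lumped ATP balance described in
:class:`axatp.params.EnergyModelParams` with fixed-step explicit Euler
(default dt = 0.1 s; the system is non-stiff by construction and a
step-halving convergence check is part of the test suite).

State variables: A (axonal ATP, mM), G (glycogen reserve, mM
ATP-equivalents), B (phosphagen-like rapid buffer, mM), D (ion-gradient
debt, mM).  The stimulation drive f(t) is the burst-averaged stimulation
rate from the protocol schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import EnergyModelParams, ExperimentConfig, StimProtocol


@dataclass
class EnergyTrace:
    """Output of :func:`simulate_energy` on the integration grid."""

    time_s: np.ndarray       # integration grid
    A_mM: np.ndarray         # axonal ATP
    G_mM: np.ndarray         # glycogen reserve remaining
    B_mM: np.ndarray         # buffer remaining
    D_mM: np.ndarray         # ion-gradient debt
    rate_hz: np.ndarray      # burst-averaged stimulation rate f(t)

    def at(self, t: np.ndarray) -> np.ndarray:
        """ATP linearly interpolated at arbitrary times ``t`` (s)."""
        return np.interp(np.asarray(t, dtype=float), self.time_s, self.A_mM)


def stim_rate_schedule(
    prot: StimProtocol, total_s: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Burst-averaged stimulation rate f(t) on the integration grid.

    During an HFS segment at burst frequency ``hz`` the average rate is
    ``burst_size / (burst_size/hz + gap)``; outside HFS it is the baseline
    stimulation frequency.
    """
    n = int(round(total_s / dt)) + 1
    time_s = np.arange(n) * dt
    rate = np.full(n, prot.baseline_hz, dtype=float)
    for start, end, mode, hz in prot.segments(total_s):
        if mode == "hfs":
            m = (time_s >= start) & (time_s < end)
            rate[m] = prot.effective_rate(hz)
    return time_s, rate


def production_fluxes(
    p: EnergyModelParams,
    bath: dict,
    A: float,
    G: float,
    t_since_azide: float | None,
) -> tuple[float, float, float]:
    """Instantaneous (J_glyc, J_mito, glycogen usage) for one state.

    ``t_since_azide`` is the elapsed time of an ongoing azide application
    (None if azide is absent); it drives the transient Pasteur boost of
    glycolysis.
    """
    glc = bath["glucose_mM"]
    glc_frac = glc / (glc + p.K_glc) if glc > 0 else 0.0
    gly_frac = G / (G + p.K_G) if (glc <= 1e-9 and G > 0) else 0.0

    pasteur = 1.0
    if t_since_azide is not None:
        pasteur = p.pasteur_floor + (p.pasteur_boost - p.pasteur_floor) * np.exp(
            -t_since_azide / p.tau_pasteur_s
        )
    j_glyc = p.V_glc * glc_frac * pasteur + p.V_gly * gly_frac

    demand = 1.0 + p.demand_gain * max(0.0, 1.0 - A / p.A_base)
    s_endo = p.eta_shuttle * glc_frac * p.mct_factor
    s_gly = p.gly_shuttle * gly_frac * p.mct_factor
    s_exo = 0.0
    if bath["substrate"] != "none" and bath["substrate_mM"] > 0:
        sub = bath["substrate_mM"]
        s_exo = p.exo_efficiency * p.mct_factor * sub / (sub + p.K_sub)
    supply = (s_endo + s_gly + s_exo) * demand
    azide = bath["azide"]
    j_mito = 0.0 if azide else p.V_mito * min(1.0, supply)

    # glycogen is consumed by its direct glycolytic term and by its share
    # of the mitochondrial substrate supply
    gly_use = p.V_gly * gly_frac
    if not azide and supply > 0 and s_gly > 0:
        gly_use += j_mito * (s_gly / (s_endo + s_gly + s_exo))
    return j_glyc, j_mito, gly_use


def simulate_energy(
    cfg: ExperimentConfig,
    prot: StimProtocol,
    p: EnergyModelParams,
    dt: float = 0.1,
) -> EnergyTrace:
    """Integrate the axonal ATP balance over one experiment.

    dA/dt = J_glyc + J_mito + J_buf - C with the flux definitions of
    :class:`EnergyModelParams`; A is clipped to [0, A_max].  Bath
    composition (glucose, exogenous substrate, azide) follows
    ``cfg.bath_at``; the anchor window always applies MB+GD.

    Raises ``ValueError`` for dt > 0.5 s and ``FloatingPointError`` with a
    diagnostic if the state turns non-finite.
    """
    if dt > 0.5:
        raise ValueError(f"dt={dt} too large; use dt <= 0.5 s")

    time_s, rate = stim_rate_schedule(prot, cfg.total_duration_s, dt)
    n = time_s.size
    A = np.empty(n)
    G = np.empty(n)
    B = np.empty(n)
    D = np.empty(n)
    a, g, b, d = p.A_base, p.G_0, p.B_0, 0.0

    for i in range(n):
        A[i], G[i], B[i], D[i] = a, g, b, d
        if i == n - 1:
            break
        t = time_s[i]
        bath = cfg.bath_at(t)
        az0 = cfg.azide_onset_before(t)
        t_since_azide = (t - az0) if az0 is not None else None
        j_glyc, j_mito, gly_use = production_fluxes(p, bath, a, g, t_since_azide)

        if a < p.A_base and b > 0 and p.B_0 > 0:
            j_buf = p.k_buf * (b / p.B_0) * (p.A_base - a) / p.A_base
            db = -j_buf
        else:
            j_buf = 0.0
            # slow refill once ATP is back at rest; refill consumes ATP
            db = p.k_refill * (p.B_0 - b) if a >= p.A_base and b < p.B_0 else 0.0

        sat_a = a / (a + p.K_A)
        consumption = (p.c_0 + p.c_spike * rate[i]) * sat_a
        # ion-gradient debt: accrues in the conduction-failure zone, repaid
        # with priority over free ATP accumulation during recovery
        production = j_glyc + j_mito + j_buf
        if d > 0:
            repay = min(p.c_repay * d / (d + p.K_debt), p.repay_frac * production)
        else:
            repay = 0.0
        pump_deficit = max(0.0, 1.0 - a / p.debt_threshold) if p.debt_threshold > 0 else 0.0
        dd = p.k_debt * pump_deficit - repay

        da = production - consumption - repay - db

        a = min(max(a + dt * da, 0.0), p.A_max)
        g = max(g - dt * gly_use, 0.0)
        b = min(max(b + dt * db, 0.0), p.B_0)
        d = min(max(d + dt * dd, 0.0), p.debt_max)
        if not (np.isfinite(a) and np.isfinite(g) and np.isfinite(b) and np.isfinite(d)):
            raise FloatingPointError(
                f"non-finite state at t={t:.1f}s: A={a}, G={g}, B={b}, D={d}"
            )

    return EnergyTrace(time_s=time_s, A_mM=A, G_mM=G, B_mM=B, D_mM=D, rate_hz=rate)


def resting_consumption(p: EnergyModelParams, baseline_hz: float = 0.1) -> float:
    """Consumption flux at rest (A = A_base, baseline stimulation)."""
    return (p.c_0 + p.c_spike * baseline_hz) * p.A_base / (p.A_base + p.K_A)


def balanced_glc10_params(
    glyc_share: float = 0.25,
    baseline_hz: float = 0.1,
    glucose_mM: float = 10.0,
    **overrides,
) -> EnergyModelParams:
    """Energy parameters whose 10 mM glucose resting state is an exact
    fixed point at A_base.

    ``glyc_share`` is the fraction of resting ATP production carried by
    direct axonal glycolysis; the rest is mitochondrial, fed by the
    glucose-derived monocarboxylate shuttle.  V_glc and eta_shuttle are
    derived accordingly; everything else can be overridden.
    """
    p = EnergyModelParams(**overrides)
    c_rest = resting_consumption(p, baseline_hz)
    glc_frac = glucose_mM / (glucose_mM + p.K_glc)
    v_glc = glyc_share * c_rest / glc_frac
    eta = (1.0 - glyc_share) * c_rest / (p.V_mito * glc_frac)
    gly_shuttle = (c_rest - p.V_gly) / p.V_mito   # glycogen fully replaces glucose
    return EnergyModelParams(
        **{
            **overrides,
            "V_glc": v_glc,
            "eta_shuttle": eta,
            "gly_shuttle": gly_shuttle,
        }
    )
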