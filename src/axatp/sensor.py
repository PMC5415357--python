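"""Hill-type FRET sensor model and three-channel emission rendering.

``sensor_ratio`` maps ATP concentration to the intrinsic FRET/CFP ratio of
the sensor; ``emit_channels`` renders an ATP trace into the three recorded
fluorescence channels (CFP: donor emission on donor excitation; FRET:
acceptor emission on donor excitation; YFP: acceptor emission on direct
acceptor excitation, which is ATP-independent and serves as a pH/artifact
control).
"""

from __future__ import annotations

import numpy as np

from .imaging import FluorescenceTrace
from .params import SensorParams


def sensor_ratio(A, p: SensorParams | None = None):
    """Intrinsic FRET/CFP ratio at ATP concentration ``A`` (mM).

    R(A) = R_min + (R_max - R_min) * A^n / (K_D^n + A^n).  Strictly
    increasing in A, bounded in [R_min, R_max), with R((R_min+R_max)/2)
    attained exactly at A = K_D for every Hill coefficient.

    Accepts a scalar or array; raises ``ValueError`` for negative ATP.
    """
    if p is None:
        p = SensorParams()
    A_arr = np.asarray(A, dtype=float)
    if np.any(A_arr < 0):
        raise ValueError("ATP concentration must be >= 0")
    An = A_arr ** p.hill_n
    R = p.R_min + (p.R_max - p.R_min) * An / (p.K_D ** p.hill_n + An)
    return float(R) if np.isscalar(A) or A_arr.ndim == 0 else R


def fret_efficiency(R) -> np.ndarray:
    """FRET efficiency convention used by the generator: E = R / (1 + R).

    Inverse of R = E / (1 - E), so that for unit gains and zero
    bleed-through the rendered FRET/CFP channel ratio reproduces the
    intrinsic sensor ratio exactly.
    """
    R = np.asarray(R, dtype=float)
    return R / (1.0 + R)


def measured_ratio(R, p: SensorParams):
    """Noiseless channel-level FRET/CFP ratio implied by intrinsic ratio R.

    With the emission conventions below this is affine in R:
    (fret_gain/cfp_gain) * R + bleedthrough.
    """
    return (p.fret_gain / p.cfp_gain) * np.asarray(R, dtype=float) + p.bleedthrough


def emit_channels(
    time_s: np.ndarray,
    A_mM: np.ndarray,
    p: SensorParams,
    rng: np.random.Generator,
) -> tuple[FluorescenceTrace, dict]:
    """Render an ATP trace into per-frame CFP / FRET / direct-YFP means.

    Per frame: E = R/(1+R) with R = ``sensor_ratio``(A); then
    CFP = (1-E) * cfp_gain, FRET = E * fret_gain + bleedthrough * CFP,
    YFP = yfp_gain (ATP-independent).  Gaussian noise with s.d.
    ``noise_sd`` x (noiseless baseline of the channel) is added per frame
    and channel; negative intensities are clipped to zero and counted in
    the returned QC log.

    Returns ``(trace, qc)`` where ``qc`` records clipped-frame counts.
    """
    time_s = np.asarray(time_s, dtype=float)
    A_mM = np.asarray(A_mM, dtype=float)
    if time_s.size == 0 or A_mM.size == 0:
        raise ValueError("empty trace")
    if time_s.shape != A_mM.shape:
        raise ValueError("time and ATP arrays must have matching shape")

    R = sensor_ratio(A_mM, p)
    E = fret_efficiency(R)
    cfp = (1.0 - E) * p.cfp_gain
    fret = E * p.fret_gain + p.bleedthrough * cfp
    yfp = np.full_like(cfp, p.yfp_gain)

    qc = {"clipped_frames": {"cfp": 0, "fret": 0, "yfp": 0}}
    if p.noise_sd > 0:
        channels = {}
        for name, clean in (("cfp", cfp), ("fret", fret), ("yfp", yfp)):
            sd = p.noise_sd * clean[0]
            noisy = clean + rng.normal(0.0, sd, size=clean.shape)
            n_clip = int(np.sum(noisy < 0))
            qc["clipped_frames"][name] = n_clip
            channels[name] = np.clip(noisy, 0.0, None)
        cfp, fret, yfp = channels["cfp"], channels["fret"], channels["yfp"]

    trace = FluorescenceTrace(
        time_s=time_s.copy(),
        cfp=cfp,
        fret=fret,
        yfp=yfp,
        frame_interval_s=float(np.median(np.diff(time_s))) if time_s.size > 1 else 10.4,
        meta={"source": "synthetic"},
    )
    return trace, qc
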