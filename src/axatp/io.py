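"""File formats, run manifests and experiment orchestration.

CSV is the interchange format: fluorescence traces as
``time_s, cfp, fret, yfp``; CAP sweeps as long-format
``sweep_id, stim_time_s, t_ms, mV``; normalized series as
``time_s, value, kind``.  Times are seconds on the experiment clock and
milliseconds within a sweep (0 at the stimulus).  An optional OME-TIFF
image mode renders the fluorescence channels as a T x C x Y x X stack
with an axon-stripe texture for testing the ROI-extraction path.

Every pipeline output directory carries a JSON run manifest (config hash,
seed, file checksums, package version, QC verdicts) so that runs are
reproducible bitwise for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cap import CapSweep
from .imaging import FluorescenceTrace, NormalizedSeries, extract_roi_means
from .presets import Preset, preset
from .simulate import SimulationResult, simulate_experiment

TRACE_COLUMNS = ["time_s", "cfp", "fret", "yfp"]
SWEEP_COLUMNS = ["sweep_id", "stim_time_s", "t_ms", "mV"]


# ---------------------------------------------------------------- traces

def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": trace.time_s,
        "cfp": trace.cfp,
        "fret": trace.fret,
        "yfp": trace.yfp if trace.yfp is not None else np.nan,
    })
    df.to_csv(path, index=False, float_format="%.10g")


def read_trace_csv(path: str | Path) -> FluorescenceTrace:
    """Read a fluorescence trace; schema ``time_s, cfp, fret, yfp``.

    Missing required columns, non-monotone time, or NaN rows are
    rejected (NaNs with their row numbers); extra columns are preserved
    in ``trace.meta["extra_columns"]``.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "cfp", "fret") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    required = [c for c in TRACE_COLUMNS if c in df.columns]
    bad = df[required].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()   # 1-based incl. header
        raise ValueError(f"{path}: NaN values in rows {rows[:10]}")
    time_s = df["time_s"].to_numpy(float)
    if time_s.size >= 2 and not np.all(np.diff(time_s) > 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    extra = [c for c in df.columns if c not in TRACE_COLUMNS]
    yfp = df["yfp"].to_numpy(float) if "yfp" in df.columns else None
    if yfp is not None and np.all(np.isnan(yfp)):
        yfp = None
    interval = float(np.median(np.diff(time_s))) if time_s.size > 1 else 10.4
    return FluorescenceTrace(
        time_s=time_s,
        cfp=df["cfp"].to_numpy(float),
        fret=df["fret"].to_numpy(float),
        yfp=yfp,
        frame_interval_s=interval,
        meta={
            "source": str(path),
            "extra_columns": {c: df[c].tolist() for c in extra},
        },
    )


# ---------------------------------------------------------------- sweeps

def write_sweeps_csv(sweeps: list[CapSweep], path: str | Path) -> None:
    frames = []
    for k, s in enumerate(sweeps):
        frames.append(pd.DataFrame({
            "sweep_id": s.sweep_id if s.sweep_id is not None else k,
            "stim_time_s": s.stim_time_s,
            "t_ms": s.t_ms,
            "mV": s.v_mV,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")


def read_sweeps_csv(path: str | Path) -> list[CapSweep]:
    """Read long-format CAP sweeps.

    Sample rates are inferred per sweep from the time grid (mixed rates
    across sweeps are allowed); a gap or irregularity in a sweep's grid
    raises an error naming the sweep id.
    """
    df = pd.read_csv(path)
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df[SWEEP_COLUMNS].isna().any().any():
        raise ValueError(f"{path}: NaN values in sweep table")
    sweeps = []
    for sid, grp in df.groupby("sweep_id", sort=True):
        t_ms = grp["t_ms"].to_numpy(float)
        step = float(np.median(np.diff(t_ms)))
        rate = int(round(1000.0 / step))
        if rate not in (20_000, 100_000):
            raise ValueError(
                f"{path}: sweep {sid}: inferred sample rate {rate} Hz "
                "not in {20 kHz, 100 kHz}"
            )
        try:
            sweeps.append(CapSweep(
                stim_time_s=float(grp["stim_time_s"].iloc[0]),
                t_ms=t_ms,
                v_mV=grp["mV"].to_numpy(float),
                sample_rate=rate,
                sweep_id=int(sid),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: sweep {sid}: {exc}") from exc
    sweeps.sort(key=lambda s: s.stim_time_s)
    return sweeps


# ------------------------------------------------------------- series

def write_series_csv(series: NormalizedSeries, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": series.time_s,
        "value": series.value,
        "kind": series.kind,
    }).to_csv(path, index=False, float_format="%.10g")


def read_series_csv(path: str | Path) -> NormalizedSeries:
    df = pd.read_csv(path)
    for c in ("time_s", "value", "kind"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return NormalizedSeries(
        time_s=df["time_s"].to_numpy(float),
        value=df["value"].to_numpy(float),
        kind=str(df["kind"].iloc[0]),
    )


# ---------------------------------------------------------- image mode

def axon_stripe_texture(shape: tuple[int, int] = (48, 48),
                        n_axons: int = 8) -> np.ndarray:
    """Unit-mean horizontal-stripe texture mimicking axons in the field."""
    h, w = shape
    y = np.arange(h)[:, None]
    tex = 0.35 + np.zeros((h, w))
    for k in range(n_axons):
        centre = (k + 0.5) * h / n_axons
        tex += 1.3 * np.exp(-0.5 * ((y - centre) / (0.09 * h / 1.0)) ** 2)
    return tex / tex.mean()


def write_ome_stack(
    trace: FluorescenceTrace,
    path: str | Path,
    shape: tuple[int, int] = (48, 48),
    rng: Optional[np.random.Generator] = None,
    pixel_noise_frac: float = 0.05,
) -> None:
    """Render a trace as a T x C x Y x X OME-TIFF with axon stripes.

    Per-frame channel means of the stack reproduce the trace up to
    pixel noise / sqrt(n_pixels).
    """
    import tifffile

    rng = rng or np.random.default_rng(0)
    tex = axon_stripe_texture(shape)
    channels = [trace.cfp, trace.fret]
    if trace.yfp is not None:
        channels.append(trace.yfp)
    stack = np.empty((len(trace), len(channels), *shape), dtype=np.float32)
    for c, ch in enumerate(channels):
        base = ch[:, None, None] * tex[None, :, :]
        noise = rng.normal(0.0, pixel_noise_frac, size=stack.shape[0:1] + shape)
        stack[:, c] = np.clip(base * (1.0 + noise), 0.0, None)
    tifffile.imwrite(path, stack, metadata={"axes": "TCYX"})


def read_ome_stack(path: str | Path, time_s: Optional[np.ndarray] = None,
                   frame_interval_s: float = 10.4) -> FluorescenceTrace:
    import tifffile

    stack = tifffile.imread(path)
    return extract_roi_means(np.asarray(stack, float), time_s=time_s,
                             frame_interval_s=frame_interval_s)


# ------------------------------------------------------------ manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(cfg_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def build_manifest(sim: SimulationResult, files: dict[str, Path],
                   qc: Optional[dict] = None) -> dict:
    from . import __version__

    cfg = asdict(sim.config)
    return {
        "package": "axatp",
        "version": __version__,
        "python": platform.python_version(),
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": sim.config.seed,
        "files": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                  for k, p in files.items()},
        "qc": qc or {},
    }


# ------------------------------------------------------- orchestration

def run_experiment(
    preset_name: str,
    seed: int = 0,
    out_dir: str | Path = "axatp_run",
    image_mode: bool = False,
    noise_sd: Optional[float] = None,
) -> dict:
    """Simulate a preset and run the full analysis, writing all artifacts.

    Pipeline: simulate -> imaging pipeline -> CAP pipeline -> kinetics;
    writes raw CSVs, normalized series, a kinetics JSON, a QC report and
    the run manifest into ``out_dir``.  Raises before creating any file
    for an unknown preset; stage errors abort with the stage name.
    """
    from dataclasses import replace as _replace

    from .imaging import channel_qc
    from .workflows import atp_series, cap_series, deprivation_kinetics, hfs_endpoints

    b = preset(preset_name, seed=seed)     # raises KeyError before any IO
    if noise_sd is not None:
        b = Preset(b.config, b.protocol, b.energy,
                   _replace(b.sensor, noise_sd=noise_sd),
                   _replace(b.cap_shape, noise_sd=noise_sd))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        sim = simulate_experiment(b)
        files: dict[str, Path] = {}

        stage = "write-raw"
        files["trace"] = out / "trace.csv"
        write_trace_csv(sim.trace, files["trace"])
        files["sweeps"] = out / "sweeps.csv"
        write_sweeps_csv(sim.sweeps, files["sweeps"])
        if image_mode:
            files["stack"] = out / "stack.ome.tif"
            rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
            write_ome_stack(sim.trace, files["stack"], rng=rng)

        stage = "imaging-pipeline"
        atp = atp_series(sim)
        files["atp_series"] = out / "atp_series.csv"
        write_series_csv(atp, files["atp_series"])
        qc = channel_qc(sim.trace)

        stage = "cap-pipeline"
        cap = cap_series(sim)
        files["cap_series"] = out / "cap_series.csv"
        write_series_csv(cap, files["cap_series"])

        stage = "kinetics"
        if b.protocol.hfs_start_s is not None:
            kin = hfs_endpoints(sim)
        else:
            kin = deprivation_kinetics(sim)
        files["kinetics"] = out / "kinetics.json"
        with open(files["kinetics"], "w") as fh:
            json.dump(kin, fh, indent=2, default=float)

        stage = "manifest"
        qc_all = {"yfp": qc, "generator": sim.qc}
        files["qc"] = out / "qc.json"
        with open(files["qc"], "w") as fh:
            json.dump(qc_all, fh, indent=2)
        manifest = build_manifest(sim, files, qc=qc_all)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {"out_dir": out, "files": files, "kinetics": kin,
            "qc": qc_all, "manifest": manifest}
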