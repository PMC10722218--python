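"""2D ventricular sheet: spiral-wave initiation, tip tracking, rotor metrics.

An isotropic monodomain sheet (5-point Laplacian, no-flux boundaries,
D = 0.18 mm^2/ms, dt = 0.02 ms) is composed of transmural ENDO / MIDDLE /
EPI bands (ratio 1 : 1.3 : 1) along the S1 propagation axis.  Re-entry is
initiated by the cross-field S1-S2 protocol: a planar wave from the left
edge, then a premature stimulus over the top half delivered when the S1
wave-back crosses the domain midline, so the broken wavefront end curls
into a spiral.

Rotor quantification uses a time-delay phase embedding

    phi(x, t) = atan2(V(t) - V*, V(t - tau) - V*),   V* = -40 mV, tau = 2 ms

and counts phase singularities as 2x2 plaquettes whose closed-loop phase
winding is +/-2 pi (the topological charge is the winding sign).  Derived
metrics: rotor-count time series, breakup time (first instant the count
exceeds 2 sustained for 100 ms), dominant frequency of a probe AP trace
(spectral peak in 0.5-15 Hz) and the meander area of the pre-breakup tip
trajectory (convex hull).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _tnnp_core as core
from .cell_tnnp import CellConfig, CellType, steady_state_cell
from .errors import (
    ConfigurationError,
    InvalidInputError,
    MeasurementError,
    NumericalFailureError,
    ProtocolFailureError,
)
from .ikr_markov import Genotype, MCParams

__all__ = [
    "Tissue2DConfig",
    "TipObservation",
    "SpiralMetrics",
    "Tissue2DResult",
    "simulate_2d",
    "phase_field",
    "find_tips",
    "tip_count_series",
    "rotor_metrics",
    "dominant_frequency",
    "save_frames_h5",
    "tips_to_csv",
    "metrics_to_json",
]

PHASE_VSTAR = -40.0  # mV, phase-embedding origin
PHASE_TAU_MS = 2.0   # ms, embedding delay


@dataclass(frozen=True)
class Tissue2DConfig:
    """Geometry, physics and protocol parameters of the 2D sheet."""

    genotype: Genotype = Genotype.WT
    mc_params: MCParams | None = None
    nx: int = 300
    ny: int = 300
    dx_mm: float = 0.15
    D: float = 0.18
    dt: float = 0.02
    stim_amplitude: float = -52.0
    stim_duration: float = 2.0
    frame_interval_ms: float = 1.0
    bcl: float = 1000.0

    def __post_init__(self):
        object.__setattr__(self, "genotype", Genotype.coerce(self.genotype))
        if self.nx < 10 or self.ny < 10:
            raise ConfigurationError("grid must be at least 10x10")
        if self.dx_mm <= 0 or self.dt <= 0:
            raise ConfigurationError("dx and dt must be positive")
        if self.D * self.dt / self.dx_mm**2 > 0.25:
            raise ConfigurationError(
                f"explicit 2D scheme unstable: D*dt/dx^2 = {self.D * self.dt / self.dx_mm**2:.3f} > 0.25"
            )
        if self.genotype is not Genotype.HOM and self.mc_params is None:
            raise ConfigurationError("non-HOM tissue requires mc_params")

    def cell_config(self, cell_type: CellType) -> CellConfig:
        mcp = self.mc_params
        if mcp is None:
            mcp = MCParams(a=np.full(8, 1e-3), b=np.zeros(8), g_kr=0.0, genotype=Genotype.HOM)
        return CellConfig(cell_type=cell_type, genotype=self.genotype, mc_params=mcp, dt=self.dt)


def band_map(config: Tissue2DConfig) -> np.ndarray:
    """Cell-type index per column (bands along x, ENDO at the S1 edge)."""
    n = config.nx
    weights = np.array([1.0, 1.3, 1.0])
    exact = weights / weights.sum() * n
    base = np.floor(exact).astype(int)
    rem = exact - base
    for _ in range(n - base.sum()):
        # ties go to the EPI (last) segment, keeping ENDO at 42 of 140
        k = len(rem) - 1 - int(np.argmax(rem[::-1]))
        base[k] += 1
        rem[k] = -1
    cols = np.empty(n, np.int64)
    cols[: base[0]] = int(CellType.ENDO)
    cols[base[0] : base[0] + base[1]] = int(CellType.MIDDLE)
    cols[base[0] + base[1] :] = int(CellType.EPI)
    return cols


@dataclass
class TipObservation:
    """One phase singularity at one frame."""

    time_ms: float
    x_mm: float
    y_mm: float
    charge: int

    def __post_init__(self):
        if self.charge not in (-1, 1):
            raise InvalidInputError("topological charge must be +1 or -1")


@dataclass
class SpiralMetrics:
    """Quantitative re-entry summary."""

    times_ms: np.ndarray
    rotor_count: np.ndarray
    max_rotors: int
    breakup_time_ms: float | None
    dominant_frequency_hz: dict     # per probe label
    meander_area_cm2: float | None


@dataclass
class Tissue2DResult:
    """Frames, probe traces and protocol timing of one 2D run."""

    frame_times_ms: np.ndarray
    frames: np.ndarray              # (n_frames, ny, nx)
    probe_times_ms: np.ndarray
    probes: np.ndarray              # (n_samples, n_probes)
    probe_labels: list
    probe_xy_mm: np.ndarray
    s1_time_ms: float
    s2_time_ms: float | None
    config: Tissue2DConfig
    S: np.ndarray                   # final state (ny*nx, 22)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _initial_sheet(config: Tissue2DConfig) -> tuple:
    cols = band_map(config)
    ct = np.tile(cols, config.ny)                       # node i = iy*nx + ix
    S = np.empty((config.nx * config.ny, core.NSTATE))
    mult = np.array([1.0, 0.8, 1.3])
    for t in (CellType.ENDO, CellType.MIDDLE, CellType.EPI):
        st, _ = steady_state_cell(config.cell_config(t), config.bcl)
        S[ct == int(t)] = st.y
    if config.genotype is Genotype.HOM or config.mc_params is None:
        g = 0.0
    else:
        g = config.mc_params.g_kr
    gkr = g * mult[ct]
    return S, ct, gkr


def _default_probes(config: Tissue2DConfig) -> tuple:
    """One probe per transmural band, at 3/4 height."""
    cols = band_map(config)
    labels = []
    idx = []
    xy = []
    iy = (3 * config.ny) // 4
    for t, name in ((CellType.ENDO, "ENDO"), (CellType.MIDDLE, "MIDDLE"), (CellType.EPI, "EPI")):
        xs = np.nonzero(cols == int(t))[0]
        ix = int(xs[len(xs) // 2])
        labels.append(name)
        idx.append(iy * config.nx + ix)
        xy.append((ix * config.dx_mm, iy * config.dx_mm))
    return labels, np.asarray(idx, np.int64), np.asarray(xy, float)


def simulate_2d(
    config: Tissue2DConfig,
    duration_ms: float,
    s2_time_ms: float | str = "auto",
    probe_every_ms: float = 1.0,
) -> Tissue2DResult:
    """Cross-field S1-S2 run of the sheet.

    S1 is applied to the left edge at t = 0.  With ``s2_time_ms='auto'`` the
    S2 (top half of the domain) fires when the S1 wave-back — V recovering
    down through -60 mV — reaches the domain midline column; a float gives
    an explicit coupling time, ``None`` suppresses S2.  Frames of V are
    stored every ``frame_interval_ms``.
    """
    nx, ny, dt = config.nx, config.ny, config.dt
    S, ct, gkr = _initial_sheet(config)
    mcp = config.mc_params
    tb = core.get_tables(dt, mcp.a if mcp else np.full(8, 1e-3), mcp.b if mcp else np.zeros(8))

    frame_every = max(1, int(round(config.frame_interval_ms / dt)))
    probe_every = max(1, int(round(probe_every_ms / dt)))
    n_steps_total = int(round(duration_ms / dt))
    n_frames = n_steps_total // frame_every + 1
    n_psamples = n_steps_total // probe_every + 1
    frames = np.empty((n_frames, nx * ny))
    labels, probe_idx, probe_xy = _default_probes(config)
    probes = np.empty((n_psamples, probe_idx.size))

    stim_dur_steps = max(1, int(round(config.stim_duration / dt)))
    s1 = (0, stim_dur_steps, 0, 2, 0, ny - 1, config.stim_amplitude)

    def run_chunk(n_steps, step_offset, stims, f_off, p_off):
        arr = lambda k: np.array([s[k] for s in stims], np.int64)
        amp = np.array([s[6] for s in stims], float)
        nf, np_ = core.run_sheet(
            S, ct, gkr, nx, ny, config.D, config.dx_mm, dt, n_steps, step_offset,
            arr(0), arr(1), arr(2), arr(3), arr(4), arr(5), amp,
            tb.vtab, tb.ik1, tb.fca_inf, tb.g_inf, tb.mcr, tb.e_fcag, 1,
            frame_every, frames[f_off:], probe_idx, probe_every, probes[p_off:],
        )
        return f_off + nf, p_off + np_

    mid_col = nx // 2
    midline = np.arange(ny) * nx + mid_col

    if s2_time_ms == "auto":
        # advance in chunks until the wave-back passes the midline; chunk
        # length is a multiple of both recording strides so frame/probe
        # cadence is unbroken across chunk boundaries
        chunk = int(np.lcm(frame_every, probe_every))
        while chunk * dt < 5.0:
            chunk *= 2
        f_off = p_off = 0
        t_steps = 0
        activated = False
        s2_steps = None
        while t_steps < n_steps_total:
            n = min(chunk, n_steps_total - t_steps)
            f_off, p_off = run_chunk(n, t_steps, [s1], f_off, p_off)
            t_steps += n
            vmid = S[midline, 0]
            if not activated and np.median(vmid) > -20.0:
                activated = True
            if activated and np.median(vmid) < -60.0:
                s2_steps = t_steps
                break
        if s2_steps is None:
            raise ProtocolFailureError("S1 wave-back never crossed the midline; no S2 delivered")
        s2 = (s2_steps, stim_dur_steps, 0, nx - 1, 0, ny // 2 - 1, config.stim_amplitude)
        f_off, p_off = run_chunk(n_steps_total - t_steps, t_steps, [s1, s2], f_off, p_off)
        s2_time = s2_steps * dt
    elif s2_time_ms is None:
        f_off, p_off = run_chunk(n_steps_total, 0, [s1], 0, 0)
        s2_time = None
    else:
        s2_steps = int(round(float(s2_time_ms) / dt))
        s2 = (s2_steps, stim_dur_steps, 0, nx - 1, 0, ny // 2 - 1, config.stim_amplitude)
        f_off, p_off = run_chunk(n_steps_total, 0, [s1, s2], 0, 0)
        s2_time = s2_steps * dt

    if not np.all(np.isfinite(S)):
        raise NumericalFailureError("2D simulation produced non-finite state")
    frames = frames[:f_off].reshape(f_off, ny, nx)
    frame_times = config.frame_interval_ms * np.arange(f_off)
    probe_times = probe_every_ms * np.arange(p_off)
    return Tissue2DResult(
        frame_times_ms=frame_times, frames=frames,
        probe_times_ms=probe_times, probes=probes[:p_off],
        probe_labels=labels, probe_xy_mm=probe_xy,
        s1_time_ms=0.0, s2_time_ms=s2_time, config=config, S=S,
    )


# ---------------------------------------------------------------------------
# Phase analysis
# ---------------------------------------------------------------------------

def phase_field(frame_now: np.ndarray, frame_delayed: np.ndarray,
                v_star: float = PHASE_VSTAR) -> np.ndarray:
    """Time-delay phase embedding, per node, in (-pi, pi]."""
    if frame_now.shape != frame_delayed.shape:
        raise InvalidInputError("phase embedding needs frames of equal shape")
    return np.arctan2(frame_now - v_star, frame_delayed - v_star)


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def find_tips(phase: np.ndarray, dx_mm: float = 1.0, time_ms: float = 0.0) -> list:
    """Phase singularities: 2x2 plaquettes with closed-loop winding +/-2 pi.

    Returns TipObservation objects whose position is the plaquette centre.
    """
    p = np.asarray(phase)
    if p.ndim != 2:
        raise InvalidInputError("phase field must be 2-D")
    # winding around the loop (iy,ix) -> (iy,ix+1) -> (iy+1,ix+1) -> (iy+1,ix)
    d1 = _wrap(p[:-1, 1:] - p[:-1, :-1])
    d2 = _wrap(p[1:, 1:] - p[:-1, 1:])
    d3 = _wrap(p[1:, :-1] - p[1:, 1:])
    d4 = _wrap(p[:-1, :-1] - p[1:, :-1])
    w = d1 + d2 + d3 + d4
    tips = []
    for iy, ix in zip(*np.nonzero(np.abs(w) > np.pi)):
        tips.append(
            TipObservation(
                time_ms=time_ms,
                x_mm=(ix + 0.5) * dx_mm,
                y_mm=(iy + 0.5) * dx_mm,
                charge=int(np.sign(w[iy, ix])),
            )
        )
    return tips


def tip_count_series(result: Tissue2DResult, tau_ms: float = PHASE_TAU_MS,
                     start_ms: float | None = None) -> tuple:
    """Tips per frame after S2 (or ``start_ms``); returns (times, counts, tips).

    ``tips`` is a flat list of TipObservation over all frames.
    """
    dt_frame = float(result.frame_times_ms[1] - result.frame_times_ms[0]) if result.frame_times_ms.size > 1 else 1.0
    lag = max(1, int(round(tau_ms / dt_frame)))
    t0 = result.s2_time_ms if start_ms is None else start_ms
    if t0 is None:
        t0 = 0.0
    times = []
    counts = []
    all_tips = []
    for k in range(lag, result.frames.shape[0]):
        t = result.frame_times_ms[k]
        if t < t0:
            continue
        phase = phase_field(result.frames[k], result.frames[k - lag])
        tips = find_tips(phase, dx_mm=result.config.dx_mm, time_ms=t)
        times.append(t)
        counts.append(len(tips))
        all_tips.extend(tips)
    return np.asarray(times), np.asarray(counts, int), all_tips


def dominant_frequency(trace: np.ndarray, sample_interval_ms: float,
                       band_hz: tuple = (0.5, 15.0)) -> float:
    """Spectral-peak frequency (Hz) of an AP trace within the band."""
    v = np.asarray(trace, float)
    if v.size < 16:
        raise MeasurementError("trace too short for spectral analysis")
    v = v - v.mean()
    fs = 1000.0 / sample_interval_ms
    spec = np.abs(np.fft.rfft(v * np.hanning(v.size))) ** 2
    freqs = np.fft.rfftfreq(v.size, 1.0 / fs)
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(sel):
        raise MeasurementError("no spectral bins inside the analysis band")
    return float(freqs[sel][np.argmax(spec[sel])])


def rotor_metrics(
    result: Tissue2DResult,
    tau_ms: float = PHASE_TAU_MS,
    breakup_count: int = 2,
    sustain_ms: float = 100.0,
    min_analysis_ms: float = 4000.0,
) -> SpiralMetrics:
    """Rotor counts, breakup time, dominant frequencies and meander area.

    Breakup = first time the rotor count exceeds ``breakup_count`` sustained
    for ``sustain_ms``.  Dominant frequency is measured per probe trace over
    the post-S2 interval.  The meander area is the convex hull of the tip
    trajectory before breakup (or the whole run when no breakup occurs).
    """
    if result.s2_time_ms is None:
        raise InvalidInputError("rotor metrics need an S2-initiated run")
    post = result.probe_times_ms >= result.s2_time_ms
    if result.probe_times_ms[post].size * (result.probe_times_ms[1] - result.probe_times_ms[0]) < min_analysis_ms:
        raise MeasurementError(
            f"need at least {min_analysis_ms} ms of post-S2 data for rotor metrics"
        )
    times, counts, tips = tip_count_series(result, tau_ms)

    breakup = None
    if times.size >= 2:
        dt_frame = float(times[1] - times[0])
        need = max(1, int(round(sustain_ms / dt_frame)))
        over = counts > breakup_count
        run = 0
        for k, flag in enumerate(over):
            run = run + 1 if flag else 0
            if run >= need:
                breakup = float(times[k - need + 1])
                break

    sample_int = float(result.probe_times_ms[1] - result.probe_times_ms[0])
    freqs = {}
    for j, lab in enumerate(result.probe_labels):
        try:
            freqs[lab] = dominant_frequency(result.probes[post, j], sample_int)
        except MeasurementError:
            freqs[lab] = float("nan")

    lim = breakup if breakup is not None else np.inf
    pts = np.array([(t.x_mm, t.y_mm) for t in tips if t.time_ms <= lim])
    area = None
    if pts.shape[0] >= 3:
        try:
            from scipy.spatial import ConvexHull

            area = float(ConvexHull(pts).volume) / 100.0  # mm^2 -> cm^2
        except Exception:
            area = None

    return SpiralMetrics(
        times_ms=times,
        rotor_count=counts,
        max_rotors=int(counts.max()) if counts.size else 0,
        breakup_time_ms=breakup,
        dominant_frequency_hz=freqs,
        meander_area_cm2=area,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_frames_h5(result: Tissue2DResult, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=result.frame_times_ms)
        f.create_dataset("V", data=result.frames, compression="gzip", compression_opts=4)
        f.attrs["dx_mm"] = result.config.dx_mm
        f.attrs["dt_ms"] = result.config.dt
        f.attrs["genotype"] = result.config.genotype.value
        if result.s2_time_ms is not None:
            f.attrs["s2_time_ms"] = result.s2_time_ms


def tips_to_csv(tips: Sequence[TipObservation], path) -> None:
    pd.DataFrame(
        {
            "t_ms": [t.time_ms for t in tips],
            "x_mm": [t.x_mm for t in tips],
            "y_mm": [t.y_mm for t in tips],
            "charge": [t.charge for t in tips],
        }
    ).to_csv(path, index=False)


def metrics_to_json(metrics: SpiralMetrics, path) -> None:
    doc = {
        "max_rotors": metrics.max_rotors,
        "breakup_time_ms": metrics.breakup_time_ms,
        "dominant_frequency_hz": metrics.dominant_frequency_hz,
        "meander_area_cm2": metrics.meander_area_cm2,
        "rotor_count": metrics.rotor_count.tolist(),
        "times_ms": metrics.times_ms.tolist(),
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=2)
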