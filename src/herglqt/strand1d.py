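"""1D transmural strand: conduction, pseudo-ECG/QT and vulnerable window.

A 21 mm cable of 140 nodes (dx = 0.15 mm) spans the ventricular wall with
ENDO, MIDDLE and EPI segments in the proportion 1 : 1.3 : 1 (nodes 0-41,
42-96, 97-139; ENDO at the stimulated end).  Excitation propagates by the
monodomain equation dV/dt = D d2V/dx2 - I_ion with no-flux ends, solved by
explicit finite differences at dt = 0.02 ms, D = 0.18 mm^2/ms.

The unipolar pseudo-ECG is evaluated at a virtual electrode on the fibre
axis beyond the EPI end:  Phi(t) = -sum_i dV/dx * d(1/r)/dx * dx.  Its QT
interval runs from QRS onset (first 5%-of-QRS-peak crossing) to T-wave end
(last 5%-of-T-peak crossing after the T peak).

Vulnerability: after an S1 from the ENDO end, a premature S2 applied to
nodes 4-14 is classified as bidirectional block, unidirectional conduction
(the re-entry substrate) or bidirectional conduction, by watching for fresh
activation at sentinel nodes on each side of the S2 segment; the vulnerable
window is the span of S2 delays that conduct unidirectionally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _tnnp_core as core
from .cell_tnnp import CellConfig, CellState, CellType, steady_state_cell
from .errors import (
    ConfigurationError,
    InvalidInputError,
    MeasurementError,
    NumericalFailureError,
)
from .ikr_markov import Genotype, MCParams

__all__ = [
    "StrandConfig",
    "Stimulus",
    "StrandHistory",
    "ECGTrace",
    "ECGMetrics",
    "S2Outcome",
    "VWResult",
    "region_map",
    "initial_strand_array",
    "conditioned_state",
    "simulate_strand",
    "activation_times",
    "measure_cv",
    "pseudo_ecg",
    "measure_qt",
    "classify_s2",
    "scan_vw",
    "save_history_h5",
    "ecg_to_csv",
]


@dataclass(frozen=True)
class StrandConfig:
    """Geometry, physics and genotype of the transmural strand."""

    genotype: Genotype = Genotype.WT
    mc_params: MCParams | None = None
    length_mm: float = 21.0
    dx_mm: float = 0.15
    D: float = 0.18            # mm^2/ms
    Cm: float = 1.0            # currents are per-capacitance (pA/pF)
    dt: float = 0.02           # ms
    stim_amplitude: float = -52.0
    stim_duration: float = 2.0  # ms (tissue stimulus)
    n_condition_beats: int = 1
    bcl: float = 1000.0

    def __post_init__(self):
        object.__setattr__(self, "genotype", Genotype.coerce(self.genotype))
        if self.dx_mm <= 0 or self.length_mm <= 0:
            raise ConfigurationError("length and dx must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.D < 0:
            raise ConfigurationError("D must be non-negative")
        if self.D * self.dt / self.dx_mm**2 > 0.5:
            raise ConfigurationError(
                f"explicit scheme unstable: D*dt/dx^2 = {self.D * self.dt / self.dx_mm**2:.3f} > 0.5"
            )
        if self.genotype is not Genotype.HOM and self.mc_params is None:
            raise ConfigurationError("non-HOM strand requires mc_params")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length_mm / self.dx_mm))

    def cell_config(self, cell_type: CellType) -> CellConfig:
        mcp = self.mc_params
        if mcp is None:  # HOM: kinetics irrelevant, current is zero
            mcp = MCParams(a=np.full(8, 1e-3), b=np.zeros(8), g_kr=0.0, genotype=Genotype.HOM)
        return CellConfig(
            cell_type=cell_type, genotype=self.genotype, mc_params=mcp, dt=self.dt,
        )


def region_map(config: StrandConfig) -> np.ndarray:
    """Cell-type index per node: ENDO : MIDDLE : EPI = 1 : 1.3 : 1.

    Largest-remainder rounding over the node count; for the default 140
    nodes this gives ENDO 0-41, MIDDLE 42-96, EPI 97-139.
    """
    n = config.n_nodes
    weights = np.array([1.0, 1.3, 1.0])
    exact = weights / weights.sum() * n
    base = np.floor(exact).astype(int)
    rem = exact - base
    for _ in range(n - base.sum()):
        # ties go to the EPI (last) segment, keeping ENDO at 42 of 140
        k = len(rem) - 1 - int(np.argmax(rem[::-1]))
        base[k] += 1
        rem[k] = -1
    ct = np.empty(n, np.int64)
    ct[: base[0]] = int(CellType.ENDO)
    ct[base[0] : base[0] + base[1]] = int(CellType.MIDDLE)
    ct[base[0] + base[1] :] = int(CellType.EPI)
    return ct


@dataclass(frozen=True)
class Stimulus:
    """A rectangular current stimulus on a node range (inclusive)."""

    onset_ms: float
    node_lo: int
    node_hi: int
    duration_ms: float = 2.0
    amplitude: float = -52.0


@dataclass
class StrandHistory:
    """Sub-sampled V(x, t) plus the final full per-node state."""

    time_ms: np.ndarray          # frame times
    V: np.ndarray                # (n_frames, n_nodes)
    S: np.ndarray                # final state array (n_nodes, 22)
    config: StrandConfig

    @property
    def x_mm(self) -> np.ndarray:
        return self.config.dx_mm * np.arange(self.V.shape[1])

    def final_states(self) -> list:
        return [CellState(self.S[i].copy()) for i in range(self.S.shape[0])]


@dataclass
class ECGTrace:
    time_ms: np.ndarray
    phi: np.ndarray              # arbitrary units


@dataclass
class ECGMetrics:
    qrs_onset_ms: float
    t_end_ms: float
    qt_ms: float

    def __post_init__(self):
        if self.t_end_ms <= self.qrs_onset_ms:
            raise InvalidInputError("T end must come after QRS onset")


class S2Outcome(str, enum.Enum):
    BIDIRECTIONAL_BLOCK = "bidirectional-block"
    UNIDIRECTIONAL = "unidirectional"
    BIDIRECTIONAL_CONDUCTION = "bidirectional-conduction"


@dataclass
class VWResult:
    delays_ms: np.ndarray
    outcomes: list                # S2Outcome per delay
    vw_ms: float                  # width of the unidirectional span
    step_ms: float


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def initial_strand_array(config: StrandConfig, init: str = "steady") -> np.ndarray:
    """Per-node state array; each node starts at its cell type's 1 Hz steady
    state (``init='steady'``) or at the host-model initial conditions."""
    ct = region_map(config)
    S = np.empty((config.n_nodes, core.NSTATE))
    for t in (CellType.ENDO, CellType.MIDDLE, CellType.EPI):
        mask = ct == int(t)
        if not np.any(mask):
            continue
        if init == "steady":
            st, _ = steady_state_cell(config.cell_config(t), config.bcl)
            S[mask] = st.y
        else:
            S[mask] = CellState.initial(config.cell_config(t)).y
    return S


def _gkr_eff_array(config: StrandConfig) -> np.ndarray:
    ct = region_map(config)
    mult = np.array([1.0, 0.8, 1.3])  # ENDO, MIDDLE, EPI
    if config.genotype is Genotype.HOM or config.mc_params is None:
        g = 0.0
    else:
        g = config.mc_params.g_kr
    return g * mult[ct]


def simulate_strand(
    config: StrandConfig,
    stimuli: Sequence[Stimulus],
    duration_ms: float,
    rec_every_ms: float = 0.5,
    S0: np.ndarray | None = None,
) -> StrandHistory:
    """Run the monodomain cable for ``duration_ms`` under the given stimuli.

    ``S0`` (a (n_nodes, 22) state array) continues a previous run; otherwise
    every node starts from its single-cell 1 Hz steady state.
    """
    n = config.n_nodes
    for st in stimuli:
        if not (0 <= st.node_lo <= st.node_hi < n):
            raise InvalidInputError(f"stimulus nodes [{st.node_lo}, {st.node_hi}] outside grid")
    S = initial_strand_array(config) if S0 is None else np.array(S0, dtype=float)
    if S.shape != (n, core.NSTATE):
        raise InvalidInputError("S0 has wrong shape for this strand")
    ct = region_map(config)
    gkr = _gkr_eff_array(config)
    dt = config.dt
    n_steps = int(round(duration_ms / dt))
    rec_every = max(1, int(round(rec_every_ms / dt)))
    n_frames = (n_steps + rec_every - 1) // rec_every
    Vrec = np.empty((n_frames, n))

    stim_start = np.array([int(round(s.onset_ms / dt)) for s in stimuli], np.int64)
    stim_dur = np.array([max(1, int(round(s.duration_ms / dt))) for s in stimuli], np.int64)
    stim_lo = np.array([s.node_lo for s in stimuli], np.int64)
    stim_hi = np.array([s.node_hi for s in stimuli], np.int64)
    stim_amp = np.array([s.amplitude for s in stimuli], float)

    mcp = config.mc_params
    tb = core.get_tables(dt, mcp.a if mcp else np.full(8, 1e-3), mcp.b if mcp else np.zeros(8))
    core.run_strand(
        S, ct, gkr, config.D, config.dx_mm, dt, n_steps,
        stim_start, stim_dur, stim_lo, stim_hi, stim_amp,
        tb.vtab, tb.ik1, tb.fca_inf, tb.g_inf, tb.mcr, tb.e_fcag, 1,
        rec_every, Vrec,
    )
    if not np.all(np.isfinite(S)):
        raise NumericalFailureError("strand simulation produced non-finite state")
    t = dt * rec_every * np.arange(n_frames)
    return StrandHistory(time_ms=t, V=Vrec, S=S, config=config)


def conditioned_state(config: StrandConfig) -> np.ndarray:
    """State array after the configured number of conditioning S1 beats."""
    S = initial_strand_array(config)
    for _ in range(config.n_condition_beats):
        h = simulate_strand(
            config,
            [Stimulus(0.0, 0, 4, config.stim_duration, config.stim_amplitude)],
            config.bcl, rec_every_ms=config.bcl, S0=S,
        )
        S = h.S
    return S


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def activation_times(history: StrandHistory, threshold: float = -20.0) -> np.ndarray:
    """Per-node activation time: first upward crossing of the threshold."""
    V = history.V
    t = history.time_ms
    act = np.full(V.shape[1], np.nan)
    for i in range(V.shape[1]):
        up = np.nonzero((V[1:, i] >= threshold) & (V[:-1, i] < threshold))[0]
        if up.size:
            k = up[0]
            # sub-frame interpolation
            act[i] = t[k] + (threshold - V[k, i]) / (V[k + 1, i] - V[k, i]) * (t[k + 1] - t[k])
    return act


def measure_cv(history: StrandHistory) -> float:
    """Conduction velocity (m/s) between the 25% and 75% strand positions.

    Uses activation times of a single planar wave; mm/ms equals m/s.
    """
    act = activation_times(history)
    n = act.size
    i25, i75 = int(round(0.25 * (n - 1))), int(round(0.75 * (n - 1)))
    if not (np.isfinite(act[i25]) and np.isfinite(act[i75])) or act[i75] <= act[i25]:
        raise MeasurementError("no planar activation between the 25% and 75% positions")
    dx = history.config.dx_mm
    return float((i75 - i25) * dx / (act[i75] - act[i25]))


def pseudo_ecg(history: StrandHistory, electrode_mm: float = 20.0) -> ECGTrace:
    """Unipolar pseudo-ECG at ``electrode_mm`` beyond the EPI end, on-axis.

    Phi(t) = -sum_i (dV/dx)_i * d(1/r)/dx |_i * dx  with r the distance from
    node i to the electrode.
    """
    if electrode_mm <= 0:
        raise InvalidInputError("electrode must lie outside the tissue (distance > 0)")
    x = history.x_mm
    xe = x[-1] + electrode_mm
    r = xe - x
    dinv = 1.0 / r**2            # d(1/r)/dx for an electrode beyond the strand
    dx = history.config.dx_mm
    dVdx = np.gradient(history.V, dx, axis=1)
    phi = -np.sum(dVdx * dinv[None, :], axis=1) * dx
    return ECGTrace(history.time_ms.copy(), phi)


def measure_qt(ecg: ECGTrace, qrs_window_ms: float = 150.0, frac: float = 0.05) -> ECGMetrics:
    """QT from QRS onset to T-wave end using 5%-of-peak thresholds."""
    t, phi = ecg.time_ms, ecg.phi
    a = np.abs(phi)
    qrs_sel = t <= qrs_window_ms
    qrs_peak = a[qrs_sel].max()
    if qrs_peak <= 0:
        raise MeasurementError("flat trace: no QRS complex")
    onset_idx = np.nonzero(a >= frac * qrs_peak)[0]
    if onset_idx.size == 0:
        raise MeasurementError("no QRS onset found")
    onset = t[onset_idx[0]]
    late = t > qrs_window_ms
    if not np.any(late):
        raise MeasurementError("trace too short for a T wave")
    a_late = a[late]
    t_late = t[late]
    k_peak = int(np.argmax(a_late))
    t_peak_amp = a_late[k_peak]
    if t_peak_amp <= frac * qrs_peak:
        raise MeasurementError("no T wave detected")
    above = np.nonzero(a_late[k_peak:] >= frac * t_peak_amp)[0]
    t_end = t_late[k_peak + above[-1]]
    return ECGMetrics(qrs_onset_ms=float(onset), t_end_ms=float(t_end), qt_ms=float(t_end - onset))


# ---------------------------------------------------------------------------
# Vulnerable window
# ---------------------------------------------------------------------------

S2_NODES = (4, 14)
_RETRO_SENTINEL = 1
_ANTE_SENTINEL = 30


def _fresh_activation(V: np.ndarray, t: np.ndarray, node: int, after_ms: float,
                      window_ms: float = 200.0, threshold: float = -20.0) -> bool:
    sel = (t > after_ms) & (t <= after_ms + window_ms)
    v = V[sel, node]
    if v.size < 2:
        return False
    return bool(np.any((v[1:] >= threshold) & (v[:-1] < threshold)))


def classify_s2(
    config: StrandConfig,
    s2_delay_ms: float,
    base: np.ndarray | None = None,
    s2_nodes: tuple = S2_NODES,
    observe_ms: float = 200.0,
) -> S2Outcome:
    """Outcome of an S2 at ``s2_delay_ms`` after the S1 stimulus onset.

    Antegrade / retrograde propagation is detected as a fresh upward -20 mV
    crossing at sentinel nodes beyond each side of the S2 segment within
    ``observe_ms`` of the S2.
    """
    if base is None:
        base = conditioned_state(config)
    stims = [
        Stimulus(0.0, 0, 4, config.stim_duration, config.stim_amplitude),
        Stimulus(s2_delay_ms, s2_nodes[0], s2_nodes[1], config.stim_duration, config.stim_amplitude),
    ]
    h = simulate_strand(
        config, stims, s2_delay_ms + observe_ms + 5.0, rec_every_ms=0.5, S0=base
    )
    retro = _fresh_activation(h.V, h.time_ms, _RETRO_SENTINEL, s2_delay_ms, observe_ms)
    ante = _fresh_activation(h.V, h.time_ms, _ANTE_SENTINEL, s2_delay_ms, observe_ms)
    if retro and ante:
        return S2Outcome.BIDIRECTIONAL_CONDUCTION
    if retro or ante:
        return S2Outcome.UNIDIRECTIONAL
    return S2Outcome.BIDIRECTIONAL_BLOCK


def scan_vw(
    config: StrandConfig,
    delays_ms: Sequence[float] | None = None,
    step_ms: float = 1.0,
    s2_nodes: tuple = S2_NODES,
    observe_ms: float = 200.0,
) -> VWResult:
    """Classify S2 outcomes over a delay grid; VW = unidirectional span.

    The vulnerable-window width is the number of unidirectional delays times
    the grid step.  The default grid covers 200-420 ms at ``step_ms``
    resolution, which brackets the block-to-conduction transition for 1 Hz
    pacing of all genotypes.  The scan advances a single S1-only simulation
    incrementally and branches a short S2 run at each delay, so its cost is
    linear in the observation window rather than the delay.
    """
    if delays_ms is None:
        delays_ms = np.arange(200.0, 420.0 + step_ms / 2, step_ms)
    delays = np.asarray(list(delays_ms), float)
    if delays.size == 0 or np.any(np.diff(delays) <= 0):
        raise InvalidInputError("delays must be a non-empty increasing grid")
    base = conditioned_state(config)
    s1 = Stimulus(0.0, 0, 4, config.stim_duration, config.stim_amplitude)
    outcomes = []
    S_run = base
    t_run = 0.0
    for d in delays:
        if d > t_run:
            h = simulate_strand(config, [s1] if t_run == 0.0 else [],
                                d - t_run, rec_every_ms=max(d - t_run, 1.0), S0=S_run)
            S_run = h.S
            t_run = d
        elif t_run == 0.0 and d == 0.0:
            pass
        # branch: S2 fires immediately from the advanced state
        s2 = Stimulus(0.0, s2_nodes[0], s2_nodes[1], config.stim_duration, config.stim_amplitude)
        hb = simulate_strand(config, [s2], observe_ms + 5.0, rec_every_ms=0.5, S0=S_run)
        retro = _fresh_activation(hb.V, hb.time_ms, _RETRO_SENTINEL, 0.0, observe_ms)
        ante = _fresh_activation(hb.V, hb.time_ms, _ANTE_SENTINEL, 0.0, observe_ms)
        if retro and ante:
            outcomes.append(S2Outcome.BIDIRECTIONAL_CONDUCTION)
        elif retro or ante:
            outcomes.append(S2Outcome.UNIDIRECTIONAL)
        else:
            outcomes.append(S2Outcome.BIDIRECTIONAL_BLOCK)
    n_uni = sum(1 for o in outcomes if o is S2Outcome.UNIDIRECTIONAL)
    return VWResult(delays_ms=delays, outcomes=outcomes, vw_ms=float(n_uni * step_ms), step_ms=step_ms)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_history_h5(history: StrandHistory, path) -> None:
    """V(x, t) snapshots to HDF5 with grid attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=history.time_ms)
        f.create_dataset("V", data=history.V)
        f.attrs["dx_mm"] = history.config.dx_mm
        f.attrs["dt_ms"] = history.config.dt
        f.attrs["D_mm2_ms"] = history.config.D
        f.attrs["genotype"] = history.config.genotype.value


def ecg_to_csv(ecg: ECGTrace, path) -> None:
    pd.DataFrame({"time_ms": ecg.time_ms, "phi": ecg.phi}).to_csv(path, index=False)
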