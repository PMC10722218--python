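"""Human ventricular action-potential model with Markov-chain I_Kr.

The host model is the ten Tusscher 2004 human ventricular formulation with
its three transmural cell types (ENDO, MIDDLE, EPI).  The Hodgkin-Huxley
I_Kr of the host is replaced by the five-state Markov chain of
:mod:`herglqt.ikr_markov`; regional I_Kr density heterogeneity is expressed
as a conductance multiplier ENDO : MIDDLE : EPI = 1.0 : 0.8 : 1.3.
Genotypes: WT uses the (fitted) Markov kinetics, HET the same kinetics at
reduced conductance, HOM eliminates I_Kr entirely.

This module provides pacing to steady state, APD90 measurement, S1-S2
restitution with alternans (bifurcation) detection, and restitution-slope
analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _tnnp_core as core
from .errors import (
    ConfigurationError,
    InvalidInputError,
    MeasurementError,
    NumericalFailureError,
    ProtocolFailureError,
)
from .ikr_markov import Genotype, MCParams, MCState, steady_state_occupancy

__all__ = [
    "CellType",
    "REGIONAL_GKR_MULTIPLIER",
    "CellConfig",
    "CellState",
    "PacingProtocol",
    "APMetrics",
    "BeatRecord",
    "RestitutionResult",
    "step_cell",
    "resting_state",
    "simulate_beat",
    "pace_to_steady_state",
    "steady_state_cell",
    "measure_apd90",
    "restitution",
    "max_restitution_slope",
]


class CellType(enum.IntEnum):
    """Transmural cell type (index matches the kernel convention)."""

    ENDO = 0
    MIDDLE = 1
    EPI = 2

    @classmethod
    def coerce(cls, value) -> "CellType":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError as exc:
            raise InvalidInputError(f"unknown cell type {value!r}") from exc


#: Transmural I_Kr density ratio ENDO : MIDDLE : EPI.
REGIONAL_GKR_MULTIPLIER = {CellType.ENDO: 1.0, CellType.MIDDLE: 0.8, CellType.EPI: 1.3}


@dataclass(frozen=True)
class CellConfig:
    """Configuration of a single ventricular cell simulation."""

    cell_type: CellType = CellType.EPI
    genotype: Genotype = Genotype.WT
    mc_params: MCParams | None = None
    gkr_multiplier: float | None = None  # defaults to the regional ratio
    dt: float = 0.02                     # ms
    stim_amplitude: float = -52.0        # pA/pF
    stim_duration: float = 1.0           # ms
    model_variant: str = "TNNP2004"
    ikr_formulation: str = "markov"      # "markov" or "hh" (host-model reference)

    def __post_init__(self):
        object.__setattr__(self, "cell_type", CellType.coerce(self.cell_type))
        object.__setattr__(self, "genotype", Genotype.coerce(self.genotype))
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.stim_duration <= 0:
            raise ConfigurationError("stimulus duration must be positive")
        if self.model_variant != "TNNP2004":
            raise ConfigurationError(
                f"model_variant {self.model_variant!r} is not available; "
                "this build implements the 2004 host formulation (TNNP2004)"
            )
        if self.ikr_formulation not in ("markov", "hh"):
            raise ConfigurationError("ikr_formulation must be 'markov' or 'hh'")
        if self.ikr_formulation == "markov" and self.mc_params is None:
            raise ConfigurationError("markov I_Kr requires mc_params")

    @property
    def multiplier(self) -> float:
        if self.gkr_multiplier is not None:
            return float(self.gkr_multiplier)
        return REGIONAL_GKR_MULTIPLIER[self.cell_type]

    @property
    def use_mc(self) -> int:
        return 1 if self.ikr_formulation == "markov" else 0

    @property
    def gkr_eff(self) -> float:
        """Effective conductance handed to the kernel (zero for HOM)."""
        if self.ikr_formulation == "hh":
            g = core.GKR_HH
        else:
            if self.genotype is Genotype.HOM:
                return 0.0
            g = self.mc_params.g_kr
        return g * self.multiplier

    def tables(self) -> core.Tables:
        if self.mc_params is not None:
            a, b = self.mc_params.a, self.mc_params.b
        else:
            a = np.full(8, 1e-6)
            b = np.zeros(8)
        return core.get_tables(self.dt, a, b)


@dataclass
class CellState:
    """Full membrane state: V, host gates, concentrations, MC occupancies."""

    y: np.ndarray  # length-22 vector, layout per _tnnp_core

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.shape != (core.NSTATE,):
            raise InvalidInputError(f"state vector must have shape ({core.NSTATE},)")
        self.y = y

    @property
    def V(self) -> float:
        return float(self.y[0])

    @property
    def mc(self) -> MCState:
        return MCState.from_array(self.y[17:22] / max(self.y[17:22].sum(), 1e-300))

    def copy(self) -> "CellState":
        return CellState(self.y.copy())

    def validate(self) -> "CellState":
        if not np.all(np.isfinite(self.y)):
            raise InvalidInputError("cell state contains non-finite entries")
        if np.any(self.y[13:17] <= 0):
            raise InvalidInputError("ionic concentrations must be positive")
        return self

    @classmethod
    def initial(cls, config: CellConfig) -> "CellState":
        """Host-model standard initial conditions; MC occupancy stationary at V0."""
        y = core.INITIAL_STATE.copy()
        if config.mc_params is not None:
            y[17:22] = steady_state_occupancy(y[0], config.mc_params).as_array()
        return cls(y)


@dataclass(frozen=True)
class PacingProtocol:
    """S1(-S2) pacing description."""

    bcl: float = 1000.0          # ms
    n_s1: int = 200              # maximum number of conditioning beats
    si_list: tuple = ()          # S2 coupling intervals (ms), stimulus to stimulus
    n_s2: int = 2                # S2 stimuli delivered at short coupling
    apd_tolerance: float = 0.1   # ms; steady-state criterion on consecutive APD90

    def __post_init__(self):
        if self.bcl <= 0:
            raise ConfigurationError("BCL must be positive")
        if any(si < 0 for si in self.si_list):
            raise ConfigurationError("S2 intervals must be non-negative")


@dataclass
class APMetrics:
    """Summary measurements of one action potential."""

    apd90: float        # ms
    v_rest: float       # mV
    v_peak: float       # mV
    dvdt_max: float     # mV/ms
    ikr_peak: float     # pA/pF


@dataclass
class BeatRecord:
    """Recorded time courses over one paced interval."""

    time_ms: np.ndarray
    V: np.ndarray
    IKr: np.ndarray
    INa: np.ndarray
    ICaL: np.ndarray
    IKs: np.ndarray
    IK1: np.ndarray
    Ito: np.ndarray


@dataclass
class RestitutionResult:
    """APD restitution: one or two APD90 values per S1-S2 interval."""

    si: np.ndarray         # ms, decreasing
    apd_a: np.ndarray      # first S2 APD90 (nan = no capture)
    apd_b: np.ndarray      # second S2 APD90 (nan = not measured / no capture)
    alternans: np.ndarray  # bool: |apd_a - apd_b| > threshold
    onset_si: float | None  # largest SI with alternans
    max_slope: float
    alternans_threshold: float = 1.0


# ---------------------------------------------------------------------------
# Stepping and pacing
# ---------------------------------------------------------------------------

def step_cell(state: CellState, config: CellConfig, I_stim: float, dt: float | None = None) -> CellState:
    """Advance the cell one time step under stimulus current I_stim (pA/pF)."""
    if dt is None:
        dt = config.dt
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    cfg = config if dt == config.dt else replace(config, dt=dt)
    tb = cfg.tables()
    S = state.y.copy().reshape(1, core.NSTATE)
    buf = np.empty(2)
    cur = np.empty(1)
    core.run_cell(
        S, int(cfg.cell_type), cfg.gkr_eff, dt, 1, 0, 1, I_stim,
        tb.vtab, tb.ik1, tb.fca_inf, tb.g_inf, tb.mcr, tb.e_fcag, cfg.use_mc,
        buf, cur, cur.copy(), cur.copy(), cur.copy(), cur.copy(), cur.copy(),
    )
    if not np.all(np.isfinite(S)):
        raise NumericalFailureError("non-finite state after step")
    return CellState(S[0].copy())


def _run_interval(S, config: CellConfig, duration_ms: float, stim_at: float | None,
                  tb: core.Tables) -> BeatRecord:
    """Advance the raw state array over an interval, optionally stimulating."""
    dt = config.dt
    n = int(round(duration_ms / dt))
    Vrec = np.empty(n + 1)
    IKr = np.empty(n)
    INa = np.empty(n)
    ICaL = np.empty(n)
    IKs = np.empty(n)
    IK1 = np.empty(n)
    Ito = np.empty(n)
    if stim_at is None:
        stim_start, stim_dur, amp = n + 1, 0, 0.0
    else:
        stim_start = int(round(stim_at / dt))
        stim_dur = max(1, int(round(config.stim_duration / dt)))
        amp = config.stim_amplitude
    core.run_cell(
        S, int(config.cell_type), config.gkr_eff, dt, n, stim_start, stim_dur, amp,
        tb.vtab, tb.ik1, tb.fca_inf, tb.g_inf, tb.mcr, tb.e_fcag, config.use_mc,
        Vrec, IKr, INa, ICaL, IKs, IK1, Ito,
    )
    t = dt * np.arange(n + 1)
    return BeatRecord(t, Vrec, IKr, INa, ICaL, IKs, IK1, Ito)


def simulate_beat(state: CellState, config: CellConfig, bcl: float) -> tuple:
    """One paced interval of length ``bcl``: stimulus at t = 0, full records."""
    S = state.y.copy().reshape(1, core.NSTATE)
    rec = _run_interval(S, config, bcl, 0.0, config.tables())
    return CellState(S[0].copy()), rec


def resting_state(config: CellConfig, settle_ms: float = 10000.0) -> CellState:
    """Quiescent equilibrium: relax the standard initial conditions unstimulated."""
    S = CellState.initial(config).y.reshape(1, core.NSTATE).copy()
    _run_interval(S, config, settle_ms, None, config.tables())
    return CellState(S[0].copy())


def measure_apd90(time_ms: np.ndarray, V: np.ndarray) -> float:
    """APD at 90% repolarization of a single-upstroke trace.

    The interval runs from the maximum-dV/dt instant to the first downward
    crossing of V_rest + 0.1 (V_peak - V_rest); V_rest is the pre-upstroke
    (first-sample) potential of the beat.  Sub-sample crossing position by
    linear interpolation.
    """
    time_ms = np.asarray(time_ms, float)
    V = np.asarray(V, float)
    if V.size < 3:
        raise MeasurementError("trace too short")
    dv = np.diff(V) / np.diff(time_ms)
    k_up = int(np.argmax(dv))
    v_rest = V[0]
    k_peak = k_up + int(np.argmax(V[k_up:]))
    v_peak = V[k_peak]
    if v_peak < -20.0 or dv[k_up] < 5.0:
        raise MeasurementError("no action-potential upstroke in trace")
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    below = np.nonzero(V[k_peak:] < v90)[0]
    if below.size == 0:
        raise MeasurementError("no 90% repolarization within trace")
    k = k_peak + below[0]
    # linear interpolation between samples k-1 and k
    t_cross = time_ms[k - 1] + (v90 - V[k - 1]) * (time_ms[k] - time_ms[k - 1]) / (V[k] - V[k - 1])
    t_up = time_ms[k_up]
    return float(t_cross - t_up)


def _beat_metrics(rec: BeatRecord) -> APMetrics:
    apd = measure_apd90(rec.time_ms, rec.V)
    dv = np.diff(rec.V) / np.diff(rec.time_ms)
    return APMetrics(
        apd90=apd,
        v_rest=float(rec.V[0]),
        v_peak=float(np.max(rec.V)),
        dvdt_max=float(np.max(dv)),
        ikr_peak=float(np.max(rec.IKr)),
    )


def pace_to_steady_state(
    config: CellConfig,
    protocol: PacingProtocol | None = None,
    return_last_record: bool = False,
):
    """Pace at the protocol BCL until APD90 settles.

    Stops when consecutive beats differ in APD90 by less than the protocol
    tolerance (default 0.1 ms) or when ``n_s1`` beats have been delivered.
    Returns ``(final CellState, list of per-beat APMetrics)`` — the state is
    the one at the instant the next stimulus would be due.  With
    ``return_last_record`` the full last-beat record is appended.
    """
    if protocol is None:
        protocol = PacingProtocol()
    tb = config.tables()
    S = CellState.initial(config).y.reshape(1, core.NSTATE).copy()
    history: list[APMetrics] = []
    last_rec = None
    for beat in range(protocol.n_s1):
        rec = _run_interval(S, config, protocol.bcl, 0.0, tb)
        try:
            m = _beat_metrics(rec)
        except MeasurementError as exc:
            raise ProtocolFailureError(
                f"stimulus failed to evoke an action potential at beat {beat + 1}"
            ) from exc
        history.append(m)
        last_rec = rec
        if len(history) >= 2 and abs(history[-1].apd90 - history[-2].apd90) < protocol.apd_tolerance:
            break
    out = (CellState(S[0].copy()), history)
    if return_last_record:
        out = out + (last_rec,)
    return out


_steady_cache: dict = {}


def steady_state_cell(config: CellConfig, bcl: float = 1000.0):
    """Cached pace-to-steady-state; returns (state copy, metrics history)."""
    key = (
        int(config.cell_type), config.genotype.value, config.ikr_formulation,
        None if config.mc_params is None
        else (tuple(config.mc_params.a), tuple(config.mc_params.b), config.mc_params.g_kr),
        config.multiplier, config.dt, bcl,
    )
    hit = _steady_cache.get(key)
    if hit is None:
        state, history = pace_to_steady_state(config, PacingProtocol(bcl=bcl))
        if len(_steady_cache) > 64:
            _steady_cache.clear()
        _steady_cache[key] = (state, history)
        hit = _steady_cache[key]
    state, history = hit
    return state.copy(), list(history)


# ---------------------------------------------------------------------------
# Restitution
# ---------------------------------------------------------------------------

def _extract_ap(rec: BeatRecord) -> APMetrics | None:
    """Measure the AP evoked by the stimulus at the start of rec, or None.

    Sub-threshold (graded) responses are not counted as capture: a genuine
    AP overshoots 0 mV, while a stimulus artifact on refractory tissue only
    lifts V by a few tens of mV.
    """
    try:
        m = _beat_metrics(rec)
    except MeasurementError:
        return None
    # require a regenerative overshoot persisting past the stimulus artifact
    past_stim = rec.time_ms >= 5.0
    if m.v_peak < 0.0 or not np.any(rec.V[past_stim] > 0.0):
        return None
    return m


def restitution(
    config: CellConfig,
    si_grid: Sequence[float],
    protocol: PacingProtocol | None = None,
    alternans_threshold: float = 1.0,
) -> RestitutionResult:
    """APD restitution by the S1-S2(-S2) protocol.

    After a steady S1 train (protocol BCL) and one final S1 beat, two S2
    stimuli are delivered at the coupling interval SI (stimulus onset to
    stimulus onset).  Both S2-evoked APD90 values are registered; when they
    differ by more than ``alternans_threshold`` (ms) the point is flagged as
    alternans — the bifurcation of the restitution curve.  SI values where
    the first S2 fails to capture are reported as NaN.
    """
    si_grid = np.asarray(list(si_grid), float)
    if si_grid.size >= 2 and not np.all(np.diff(si_grid) < 0):
        raise InvalidInputError("SI grid must be decreasing")
    if protocol is None:
        protocol = PacingProtocol()
    base_state, _ = steady_state_cell(config, protocol.bcl)
    tb = config.tables()

    apd_a = np.full(si_grid.size, np.nan)
    apd_b = np.full(si_grid.size, np.nan)
    captured_any = False
    tail = 1200.0  # ms recorded after the last S2 stimulus
    for k, si in enumerate(si_grid):
        S = base_state.y.copy().reshape(1, core.NSTATE)
        _run_interval(S, config, si, 0.0, tb)           # final S1
        rec2 = _run_interval(S, config, si, 0.0, tb)    # first S2
        rec3 = _run_interval(S, config, tail, 0.0, tb)  # second S2 + tail
        a = _extract_ap(rec2)
        b = _extract_ap(rec3)
        if a is not None:
            apd_a[k] = a.apd90
            captured_any = True
            if b is not None:
                apd_b[k] = b.apd90
    if not captured_any:
        raise ProtocolFailureError("S2 never captured at any coupling interval")

    diff = np.abs(apd_a - apd_b)
    alternans = np.isfinite(diff) & (diff > alternans_threshold)
    onset = float(si_grid[alternans].max()) if np.any(alternans) else None
    result = RestitutionResult(
        si=si_grid, apd_a=apd_a, apd_b=apd_b, alternans=alternans,
        onset_si=onset, max_slope=np.nan, alternans_threshold=alternans_threshold,
    )
    try:
        result.max_slope = max_restitution_slope(result)
    except MeasurementError:
        result.max_slope = np.nan
    return result


def max_restitution_slope(result: RestitutionResult) -> float:
    """Maximal centred-difference slope dAPD90/dSI on the single-valued branch."""
    mask = np.isfinite(result.apd_a) & ~result.alternans
    si = result.si[mask]
    apd = result.apd_a[mask]
    if si.size < 3:
        raise MeasurementError("need at least 3 single-valued restitution points")
    order = np.argsort(si)
    si, apd = si[order], apd[order]
    slopes = (apd[2:] - apd[:-2]) / (si[2:] - si[:-2])
    return float(np.max(slopes))
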