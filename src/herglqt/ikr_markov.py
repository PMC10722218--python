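"""Five-state Markov-chain model of the rapid delayed rectifier current I_Kr.

The channel is described by a linear chain of five states,

    C3 <-> C2 <-> C1 <-> O <-> I

with three closed states, one open state and one inactive state.  Every
directed transition ``k`` has a mono-exponential voltage-dependent rate

    r_k(V) = a_k * exp(b_k * V)        [1/ms]

with amplitude ``a_k > 0`` (1/ms) and voltage slope ``b_k`` (1/mV).  The
macroscopic current is carried by the open state only,

    I_Kr = g_kr * sqrt(Ko / 5.4) * o * (V - E_K)     [pA/pF]

which keeps the square-root external-potassium dependence of the host
ventricular model so the Markov formulation is conductance-compatible with
the Hodgkin-Huxley I_Kr it replaces.  A homozygous loss-of-function genotype
(``HOM``) is represented by an identically zero current, reflecting
experimental recordings in which the mutant current is negligible.

Occupancies are advanced with the exact matrix exponential of the generator
at frozen voltage, which conserves total occupancy and positivity
unconditionally; voltage-clamp simulations exploit the piecewise-constant
command voltage to propagate whole segments analytically.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import InvalidInputError, NumericalFailureError

__all__ = [
    "Genotype",
    "TRANSITIONS",
    "STATE_NAMES",
    "MCParams",
    "MCState",
    "ClampProtocol",
    "CurrentTrace",
    "IVCurve",
    "ClampResult",
    "transition_rates",
    "build_generator",
    "advance_occupancy",
    "steady_state_occupancy",
    "ikr_current",
    "run_voltage_clamp",
    "traces_to_csv",
    "traces_from_csv",
]

#: Directed transitions of the linear chain, in canonical order.
TRANSITIONS = ("C3_C2", "C2_C3", "C2_C1", "C1_C2", "C1_O", "O_C1", "O_I", "I_O")

#: Occupancy-vector ordering used throughout the package.
STATE_NAMES = ("c3", "c2", "c1", "o", "i")

#: Reference external potassium of the host model (mM).
KO_REF = 5.4


class Genotype(str, enum.Enum):
    """Genotype of the simulated channel population."""

    WT = "WT"
    HET = "HET"
    HOM = "HOM"

    @classmethod
    def coerce(cls, value) -> "Genotype":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError as exc:
            raise InvalidInputError(f"unknown genotype {value!r}") from exc


@dataclass(frozen=True)
class MCParams:
    """Transition-rate coefficients and conductance of the Markov I_Kr model.

    Parameters
    ----------
    a : array-like of shape (8,)
        Rate amplitudes, 1/ms, ordered as :data:`TRANSITIONS`.  All must be
        positive and finite.
    b : array-like of shape (8,)
        Voltage slopes, 1/mV, same ordering.
    g_kr : float
        Maximal conductance, nS/pF.  Must be non-negative.
    genotype : Genotype
        ``HOM`` forces the effective current to be identically zero.
    """

    a: np.ndarray
    b: np.ndarray
    g_kr: float
    genotype: Genotype = Genotype.WT

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (8,) or b.shape != (8,):
            raise InvalidInputError("MCParams.a and .b must have shape (8,)")
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(b)):
            raise InvalidInputError("MCParams coefficients must be finite")
        if np.any(a <= 0):
            raise InvalidInputError("all rate amplitudes a_k must be positive")
        if not np.isfinite(self.g_kr) or self.g_kr < 0:
            raise InvalidInputError("g_kr must be finite and non-negative")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "genotype", Genotype.coerce(self.genotype))

    def with_conductance(self, g_kr: float) -> "MCParams":
        return replace(self, g_kr=g_kr)

    def to_dict(self) -> dict:
        return {
            "units": {"a": "1/ms", "b": "1/mV", "g_kr": "nS/pF"},
            "transitions": list(TRANSITIONS),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "g_kr": float(self.g_kr),
            "genotype": self.genotype.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MCParams":
        return cls(
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            g_kr=float(d["g_kr"]),
            genotype=Genotype.coerce(d.get("genotype", "WT")),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "MCParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class MCState:
    """Occupancy vector (probabilities) of the five channel states."""

    c3: float
    c2: float
    c1: float
    o: float
    i: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c3, self.c2, self.c1, self.o, self.i], dtype=float)

    @classmethod
    def from_array(cls, pi: np.ndarray) -> "MCState":
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (5,):
            raise InvalidInputError("occupancy vector must have shape (5,)")
        return cls(*pi.tolist())

    def validate(self, atol: float = 1e-9) -> "MCState":
        pi = self.as_array()
        if not np.all(np.isfinite(pi)):
            raise InvalidInputError("occupancies must be finite")
        if np.any(pi < -1e-12) or np.any(pi > 1 + 1e-12):
            raise InvalidInputError("occupancies must lie in [0, 1]")
        if abs(pi.sum() - 1.0) > atol:
            raise InvalidInputError(
                f"occupancies must sum to 1 within {atol} (got {pi.sum()!r})"
            )
        return self

    @classmethod
    def resting(cls) -> "MCState":
        """All channels in the deepest closed state C3."""
        return cls(1.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ClampProtocol:
    """Voltage-clamp protocol with one variable-voltage step per sweep.

    ``segments`` lists ``(voltage_mV, duration_ms)`` pairs executed in order
    for every sweep; a voltage of ``None`` marks the segment whose command
    voltage is taken from ``step_voltages`` (one sweep per entry).  The
    segment immediately after the variable one is treated as the tail
    (repolarising) segment when building peak-tail I-V summaries.
    """

    holding_mV: float
    segments: tuple
    step_voltages: tuple
    sample_interval_ms: float = 1.0

    def __post_init__(self):
        segs = tuple((None if v is None else float(v), float(d)) for v, d in self.segments)
        steps = tuple(float(v) for v in self.step_voltages)
        if not segs:
            raise InvalidInputError("protocol needs at least one segment")
        if any(d <= 0 for _, d in segs):
            raise InvalidInputError("segment durations must be positive")
        if self.sample_interval_ms <= 0:
            raise InvalidInputError("sample interval must be positive")
        n_var = sum(1 for v, _ in segs if v is None)
        if n_var != 1:
            raise InvalidInputError("exactly one segment must have voltage None (the step)")
        for _, d in segs:
            n = d / self.sample_interval_ms
            if abs(n - round(n)) > 1e-9:
                raise InvalidInputError(
                    "segment durations must be integer multiples of the sample interval"
                )
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "step_voltages", steps)

    @property
    def step_segment_index(self) -> int:
        return next(i for i, (v, _) in enumerate(self.segments) if v is None)

    @property
    def tail_segment_index(self) -> int:
        idx = self.step_segment_index + 1
        if idx >= len(self.segments):
            raise InvalidInputError("protocol has no tail segment after the step")
        return idx

    @property
    def sweep_duration_ms(self) -> float:
        return float(sum(d for _, d in self.segments))

    def sweep_segments(self, step_mV: float) -> list:
        return [(step_mV if v is None else v, d) for v, d in self.segments]

    def n_samples(self) -> int:
        return int(round(self.sweep_duration_ms / self.sample_interval_ms)) + 1

    def to_dict(self) -> dict:
        return {
            "units": {"voltage": "mV", "duration": "ms", "sample_interval": "ms"},
            "holding_mV": self.holding_mV,
            "segments": [[v, d] for v, d in self.segments],
            "step_voltages": list(self.step_voltages),
            "sample_interval_ms": self.sample_interval_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClampProtocol":
        return cls(
            holding_mV=float(d["holding_mV"]),
            segments=tuple(tuple(s) for s in d["segments"]),
            step_voltages=tuple(d["step_voltages"]),
            sample_interval_ms=float(d.get("sample_interval_ms", 1.0)),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ClampProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CurrentTrace:
    """A sampled current trace for one voltage-clamp sweep."""

    time_ms: np.ndarray
    current_pApF: np.ndarray
    sweep_mV: float

    def __post_init__(self):
        t = np.asarray(self.time_ms, dtype=float)
        c = np.asarray(self.current_pApF, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise InvalidInputError("time and current must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("time must be strictly increasing")
        self.time_ms = t
        self.current_pApF = c


@dataclass
class IVCurve:
    """Per-step summary current versus step voltage."""

    step_voltages: np.ndarray
    current: np.ndarray
    kind: str  # "end-pulse" or "peak-tail"

    def __post_init__(self):
        v = np.asarray(self.step_voltages, dtype=float)
        c = np.asarray(self.current, dtype=float)
        if v.shape != c.shape or v.ndim != 1:
            raise InvalidInputError("IVCurve needs one summary value per step voltage")
        if self.kind not in ("end-pulse", "peak-tail"):
            raise InvalidInputError("IVCurve.kind must be 'end-pulse' or 'peak-tail'")
        self.step_voltages = v
        self.current = c

    def normalized(self) -> "IVCurve":
        peak = np.max(np.abs(self.current))
        scale = peak if peak > 0 else 1.0
        return IVCurve(self.step_voltages, self.current / scale, self.kind)


@dataclass
class ClampResult:
    traces: list
    iv_end_pulse: IVCurve
    iv_peak_tail: IVCurve


# ---------------------------------------------------------------------------
# Rates and generator
# ---------------------------------------------------------------------------

def transition_rates(V: float, params: MCParams) -> dict:
    """Evaluate all eight directed transition rates at membrane potential V.

    Returns a mapping transition-name -> rate (1/ms); every rate is
    ``a_k * exp(b_k * V)`` and therefore strictly positive.
    """
    if not np.isfinite(V):
        raise InvalidInputError("membrane potential must be finite")
    rates = params.a * np.exp(params.b * float(V))
    if not np.all(np.isfinite(rates)):
        raise InvalidInputError("non-finite transition rate; check params and V")
    return dict(zip(TRANSITIONS, rates.tolist()))


def build_generator(V: float, params: MCParams) -> np.ndarray:
    """Generator matrix Q (5x5) with d(pi)/dt = pi Q for the chain C3-C2-C1-O-I.

    Off-diagonal entry Q[i, j] is the rate from state i to state j; rows sum
    to zero exactly.
    """
    r = params.a * np.exp(params.b * float(V))
    if not np.all(np.isfinite(r)):
        raise InvalidInputError("non-finite transition rate; check params and V")
    c3c2, c2c3, c2c1, c1c2, c1o, oc1, oi, io = r
    Q = np.zeros((5, 5))
    # states: 0=c3, 1=c2, 2=c1, 3=o, 4=i
    Q[0, 1] = c3c2
    Q[1, 0] = c2c3
    Q[1, 2] = c2c1
    Q[2, 1] = c1c2
    Q[2, 3] = c1o
    Q[3, 2] = oc1
    Q[3, 4] = oi
    Q[4, 3] = io
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def advance_occupancy(state: MCState, V: float, dt: float, params: MCParams) -> MCState:
    """Advance the occupancy vector over ``dt`` ms at frozen voltage V.

    Uses the exact matrix exponential of the generator, which conserves total
    occupancy and keeps every entry in [0, 1] for any step size.
    """
    if dt < 0:
        raise InvalidInputError("dt must be non-negative")
    state.validate()
    if dt == 0:
        return state
    Q = build_generator(V, params)
    pi = state.as_array() @ scipy.linalg.expm(Q * dt)
    if not np.all(np.isfinite(pi)):
        raise NumericalFailureError("occupancy update produced non-finite values")
    drift = abs(pi.sum() - 1.0)
    if drift > 1e-9:
        raise NumericalFailureError(f"occupancy sum drifted by {drift:.3e}")
    pi = np.clip(pi, 0.0, 1.0)
    pi /= pi.sum()
    return MCState.from_array(pi)


def steady_state_occupancy(V: float, params: MCParams) -> MCState:
    """Stationary occupancy pi with pi Q = 0 and sum(pi) = 1, by linear algebra."""
    Q = build_generator(V, params)
    # Solve the (overdetermined, consistent) system [Q^T; 1] pi = [0; 1].
    A = np.vstack([Q.T, np.ones((1, 5))])
    rhs = np.zeros(6)
    rhs[5] = 1.0
    pi, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    resid = np.linalg.norm(pi @ Q)
    if not np.all(np.isfinite(pi)) or resid > 1e-8 * max(1.0, np.abs(Q).max()):
        raise NumericalFailureError("stationary solve failed (ill-conditioned generator)")
    if np.any(pi < -1e-10):
        raise NumericalFailureError("stationary occupancy has negative entries")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return MCState.from_array(pi)


def ikr_current(
    state: MCState,
    V: float,
    params: MCParams,
    Ko: float = KO_REF,
    EK: float = -88.0,
) -> float:
    """I_Kr = g_kr * sqrt(Ko/5.4) * o * (V - EK), in pA/pF.

    Genotype ``HOM`` yields exactly zero regardless of the occupancy.
    """
    if Ko <= 0:
        raise InvalidInputError("Ko must be positive")
    if params.genotype is Genotype.HOM:
        return 0.0
    return params.g_kr * math.sqrt(Ko / KO_REF) * state.o * (V - EK)


# ---------------------------------------------------------------------------
# Voltage clamp
# ---------------------------------------------------------------------------

def _propagate_segment(pi0: np.ndarray, Q: np.ndarray, n: int, dt: float) -> np.ndarray:
    """Occupancies at times 0, dt, ..., n*dt under a frozen generator.

    Uses the eigendecomposition of Q^T when it is well conditioned so the
    whole segment is evaluated in closed form; otherwise falls back to
    repeated application of expm(Q^T dt).
    Returns an array of shape (n + 1, 5).
    """
    QT = Q.T
    try:
        lam, S = np.linalg.eig(QT)
        cond = np.linalg.cond(S)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e10:
        # generator eigenvalues have non-positive real part; clip numerical
        # round-off so long-time factors cannot overflow
        lam = np.where(lam.real > 0, 1j * lam.imag, lam)
        c = np.linalg.solve(S, pi0.astype(complex))
        t = dt * np.arange(n + 1)
        out = (S @ (c[:, None] * np.exp(lam[:, None] * t[None, :]))).real.T
    else:
        P = scipy.linalg.expm(QT * dt)
        out = np.empty((n + 1, 5))
        out[0] = pi0
        v = pi0.copy()
        for k in range(1, n + 1):
            v = P @ v
            out[k] = v
    # Exact-arithmetic row sums are 1; renormalise away rounding noise.
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return out


def run_voltage_clamp(
    params: MCParams,
    protocol: ClampProtocol,
    Ko: float = KO_REF,
    EK: float = -88.0,
) -> ClampResult:
    """Simulate the full protocol and build end-pulse and peak-tail I-V curves.

    One :class:`CurrentTrace` is produced per step voltage; the occupancy is
    initialised at the stationary distribution of the holding potential.  The
    end-pulse summary is the current at the last sample of the variable
    (step) segment; the peak-tail summary is the extremum of the current in
    the following (tail) segment.
    """
    if Ko <= 0:
        raise InvalidInputError("Ko must be positive")
    dt = protocol.sample_interval_ms
    pi_hold = steady_state_occupancy(protocol.holding_mV, params).as_array()
    gfac = params.g_kr * math.sqrt(Ko / KO_REF)
    if params.genotype is Genotype.HOM:
        gfac = 0.0

    step_idx = protocol.step_segment_index
    tail_idx = protocol.tail_segment_index

    traces = []
    end_pulse = []
    peak_tail = []
    for step_mV in protocol.step_voltages:
        segs = protocol.sweep_segments(step_mV)
        n_total = protocol.n_samples()
        occ_o = np.empty(n_total)
        volt = np.empty(n_total)
        pi = pi_hold.copy()
        pos = 0
        seg_slices = []
        for k, (V, dur) in enumerate(segs):
            n = int(round(dur / dt))
            occ = _propagate_segment(pi, build_generator(V, params), n, dt)
            pi = occ[-1]
            if k == 0:
                occ_o[0] = occ[0, 3]
                volt[0] = V
                pos = 1
            seg_slices.append((k, pos, pos + n))
            occ_o[pos : pos + n] = occ[1:, 3]
            volt[pos : pos + n] = V
            pos += n
        current = gfac * occ_o * (volt - EK)
        time = dt * np.arange(n_total)
        traces.append(CurrentTrace(time, current, step_mV))
        s_end = next(sl for sl in seg_slices if sl[0] == step_idx)
        end_pulse.append(current[s_end[2] - 1])
        s_tail = next(sl for sl in seg_slices if sl[0] == tail_idx)
        tail = current[s_tail[1] : s_tail[2]]
        peak_tail.append(tail[np.argmax(np.abs(tail))])

    steps = np.asarray(protocol.step_voltages)
    return ClampResult(
        traces=traces,
        iv_end_pulse=IVCurve(steps, np.asarray(end_pulse), "end-pulse"),
        iv_peak_tail=IVCurve(steps, np.asarray(peak_tail), "peak-tail"),
    )


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

def traces_to_csv(traces: Sequence[CurrentTrace], path) -> None:
    """Write traces as long-format CSV: time_ms, current_pApF, sweep_mV."""
    frames = [
        pd.DataFrame(
            {"time_ms": tr.time_ms, "current_pApF": tr.current_pApF, "sweep_mV": tr.sweep_mV}
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path) -> list:
    df = pd.read_csv(path)
    required = {"time_ms", "current_pApF", "sweep_mV"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"trace CSV must have columns {sorted(required)}")
    out = []
    for sweep, grp in df.groupby("sweep_mV", sort=True):
        grp = grp.sort_values("time_ms")
        out.append(
            CurrentTrace(
                grp["time_ms"].to_numpy(), grp["current_pApF"].to_numpy(), float(sweep)
            )
        )
    return out
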