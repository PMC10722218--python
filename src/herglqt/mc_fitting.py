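"""Least-squares calibration of the Markov I_Kr model to clamp traces.

The objective is the plain sum of squared residuals between simulated and
observed current samples over all sweeps of the protocol (uniform weights).
Optimisation uses BFGS on a transformed parameter vector

    x = [log a_1..a_8, b_1..b_8, log g_kr]

so rate amplitudes and the conductance stay positive without a constrained
solver.  A deterministic multi-start (log-uniform perturbations of the
initial guess) guards against local minima; the best start is returned.

Raw rate constants of a Markov chain fitted to macroscopic currents are in
general not identifiable — two parameter sets can produce the same open
probability time course.  The package therefore treats *current* recovery
(trace and I-V agreement), not parameter recovery, as the meaningful
diagnostic, which :func:`validate_iv` quantifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.optimize

from .errors import InvalidInputError, OptimizationFailureError
from .ikr_markov import (
    ClampProtocol,
    CurrentTrace,
    Genotype,
    IVCurve,
    MCParams,
    run_voltage_clamp,
)

__all__ = ["FitResult", "objective", "fit", "validate_iv", "perturbed_init"]


@dataclass
class FitResult:
    """Outcome of a Markov-model fit."""

    params: MCParams
    objective: float                  # sum of squared residuals, (pA/pF)^2
    iterations: int
    n_evaluations: int
    converged: bool
    per_sweep_residual_norms: np.ndarray
    n_restarts: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective_pApF2": float(self.objective),
            "iterations": int(self.iterations),
            "n_evaluations": int(self.n_evaluations),
            "converged": bool(self.converged),
            "per_sweep_residual_norms": [float(v) for v in self.per_sweep_residual_norms],
            "n_restarts": int(self.n_restarts),
            "seed": int(self.seed),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _check_alignment(traces: Sequence[CurrentTrace], protocol: ClampProtocol) -> list:
    """Order traces by protocol step voltage; verify the sample grids."""
    n = protocol.n_samples()
    by_sweep = {float(tr.sweep_mV): tr for tr in traces}
    missing = [v for v in protocol.step_voltages if v not in by_sweep]
    if missing:
        raise InvalidInputError(f"traces missing for step voltages {missing}")
    ordered = []
    for v in protocol.step_voltages:
        tr = by_sweep[v]
        if tr.time_ms.size != n:
            raise InvalidInputError(
                f"sweep {v} mV has {tr.time_ms.size} samples, protocol implies {n}"
            )
        dt = np.diff(tr.time_ms)
        if not np.allclose(dt, protocol.sample_interval_ms, rtol=0, atol=1e-9):
            raise InvalidInputError(f"sweep {v} mV is not on the protocol sample grid")
        ordered.append(tr)
    return ordered


def _observed_matrix(traces: Sequence[CurrentTrace], protocol: ClampProtocol) -> np.ndarray:
    ordered = _check_alignment(traces, protocol)
    return np.stack([tr.current_pApF for tr in ordered])


def objective(
    params: MCParams,
    traces: Sequence[CurrentTrace],
    protocol: ClampProtocol,
    Ko: float = 5.4,
    EK: float = -88.0,
) -> float:
    """Sum over sweeps and samples of (simulated - observed)^2, (pA/pF)^2."""
    obs = _observed_matrix(traces, protocol)
    sim = run_voltage_clamp(params, protocol, Ko=Ko, EK=EK)
    sim_mat = np.stack([tr.current_pApF for tr in sim.traces])
    return float(np.sum((sim_mat - obs) ** 2))


def _pack(params: MCParams) -> np.ndarray:
    return np.concatenate([np.log(params.a), params.b, [np.log(max(params.g_kr, 1e-12))]])


def _unpack(x: np.ndarray, genotype: Genotype = Genotype.WT) -> MCParams:
    a = np.exp(np.clip(x[:8], -35.0, 10.0))
    b = np.clip(x[8:16], -0.5, 0.5)
    g = float(np.exp(np.clip(x[16], -35.0, 5.0)))
    return MCParams(a=a, b=b, g_kr=g, genotype=genotype)


def perturbed_init(base: MCParams, seed: int = 0, factor: float = 2.0) -> MCParams:
    """Deterministically perturb a parameter set (x/÷ ``factor`` on each a_k).

    The a_k are alternately multiplied and divided by ``factor`` (the pattern
    is rotated by the seed) and g_kr is multiplied by ``factor``; slopes are
    left unchanged.  Used to build fit starting points that are well away
    from a reference truth.
    """
    signs = np.array([1 if (k + seed) % 2 == 0 else -1 for k in range(8)], float)
    a = base.a * factor**signs
    return MCParams(a=a, b=base.b.copy(), g_kr=base.g_kr * factor, genotype=base.genotype)


def fit(
    traces: Sequence[CurrentTrace],
    protocol: ClampProtocol,
    init: MCParams,
    max_iter: int = 200,
    n_restarts: int = 8,
    seed: int = 0,
    Ko: float = 5.4,
    EK: float = -88.0,
    method: str = "BFGS",
    early_stop_objective: float | None = None,
) -> FitResult:
    """Calibrate MCParams to the traces by multi-start BFGS.

    ``n_restarts`` starting points are tried: the given ``init`` plus
    log-uniform perturbations of it drawn from ``default_rng(seed)`` (so the
    whole fit is deterministic under a fixed seed).  Each start runs BFGS
    and is then polished by a Gauss-Newton (trust-region least-squares)
    stage, which finishes the descent where the finite-difference BFGS line
    search loses precision.  Restarts stop early once the best objective
    falls below ``early_stop_objective`` (default 1e-8 per sample, the
    noiseless floor).
    """
    obs = _observed_matrix(traces, protocol)
    n_pts = obs.size
    if early_stop_objective is None:
        early_stop_objective = 1e-8 * n_pts

    def resid(x: np.ndarray) -> np.ndarray:
        # optimiser excursions can momentarily produce absurd rate sets;
        # overflow there is expected and handled by the penalty fallback
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                p = _unpack(x)
                sim = run_voltage_clamp(p, protocol, Ko=Ko, EK=EK)
                sim_mat = np.stack([tr.current_pApF for tr in sim.traces])
                r = (sim_mat - obs).ravel()
                return np.where(np.isfinite(r), r, 1e3)
        except Exception:
            return np.full(n_pts, 1e3)

    def fun(x: np.ndarray) -> float:
        r = resid(x)
        return float(r @ r)

    rng = np.random.default_rng(seed)
    x0_base = _pack(init)
    best_fun = np.inf
    best_x = None
    best_nit = 0
    n_eval_total = 0
    n_done = 0
    bfgs_success = False
    for k in range(max(1, n_restarts)):
        x0 = x0_base.copy()
        if k > 0:
            x0[:8] += rng.uniform(-np.log(2.0), np.log(2.0), 8)
            x0[8:16] *= rng.uniform(0.7, 1.4, 8)
            x0[16] += rng.uniform(-np.log(2.0), np.log(2.0))
        try:
            res = scipy.optimize.minimize(fun, x0, method=method, options={"maxiter": max_iter})
            n_eval_total += int(res.nfev)
            ls = scipy.optimize.least_squares(
                resid, res.x, method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=60,
            )
            n_eval_total += int(ls.nfev)
        except Exception:
            continue
        n_done += 1
        val = float(2.0 * ls.cost)
        if val < best_fun:
            best_fun = val
            best_x = ls.x.copy()
            best_nit = int(res.nit)
            bfgs_success = bool(res.success)
        if best_fun < early_stop_objective:
            break
    if best_x is None:
        raise OptimizationFailureError("all fit restarts failed", best=None)

    fitted = _unpack(best_x)
    sim = run_voltage_clamp(fitted, protocol, Ko=Ko, EK=EK)
    sim_mat = np.stack([tr.current_pApF for tr in sim.traces])
    res_norms = np.linalg.norm(sim_mat - obs, axis=1)
    return FitResult(
        params=fitted,
        objective=best_fun,
        iterations=best_nit,
        n_evaluations=n_eval_total,
        converged=bool(bfgs_success or best_fun < early_stop_objective),
        per_sweep_residual_norms=res_norms,
        n_restarts=n_done,
        seed=seed,
    )


def validate_iv(fitted_iv: IVCurve, reference: IVCurve) -> dict:
    """Compare two I-V curves after normalising each by its own maximum.

    Returns a report with per-voltage errors and the maximum error, both
    expressed relative to the curve maximum (so the comparison is invariant
    to a conductance rescaling of either input).  The two curves must share
    the step-voltage grid.
    """
    if fitted_iv.step_voltages.shape != reference.step_voltages.shape or not np.allclose(
        fitted_iv.step_voltages, reference.step_voltages
    ):
        raise InvalidInputError("I-V curves are on different step-voltage grids")
    f = fitted_iv.normalized().current
    r = reference.normalized().current
    err = f - r
    return {
        "step_voltages": reference.step_voltages.copy(),
        "per_voltage_error": err,
        "max_abs_error": float(np.max(np.abs(err))),
        "kind": reference.kind,
    }
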