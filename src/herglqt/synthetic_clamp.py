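"""Synthetic voltage-clamp datasets emulating HEK-cell hERG recordings.

Real patch-clamp characterisation of the wild-type and mutant channel is not
redistributable, so this module generates surrogate recordings with the same
qualitative structure: a wild-type current with sigmoidal voltage-dependent
activation (half-activation near -20 mV on the peak-tail I-V), inward
rectification of the end-pulse current above 0 mV, a heterozygous condition
with wild-type kinetics but strongly reduced conductance, a homozygous
condition with no measurable current, and additive Gaussian recording noise.

The heterozygous conductance factor is 0.36: with unchanged kinetics this
reduces the I_Kr amplitude during the ventricular action potential by
approximately 64% relative to wild type, matching the loss-of-function
severity the cellular simulations are built around.  The homozygous channel
carries no current at all.

The generator is the package's reference truth: fitting recovers its
parameters from its own noisy traces, and the cell/tissue stages inherit the
fitted kinetics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .ikr_markov import (
    ClampProtocol,
    ClampResult,
    CurrentTrace,
    Genotype,
    MCParams,
    run_voltage_clamp,
    traces_from_csv,
    traces_to_csv,
)

__all__ = [
    "ReferenceDataset",
    "default_true_params",
    "standard_protocol",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "HET_CONDUCTANCE_FACTOR",
    "WT_G_KR",
]

#: Heterozygous conductance scaling (gives ~64% I_Kr amplitude reduction
#: during the 1 Hz action potential relative to wild type).
HET_CONDUCTANCE_FACTOR = 0.36

#: Wild-type maximal conductance (nS/pF), calibrated so the epicardial cell
#: model paced at 1 Hz repolarises with the reference wild-type APD90.
WT_G_KR = 0.03116

# Wild-type transition-rate coefficients (amplitudes 1/ms, slopes 1/mV) for
# the chain C3-C2-C1-O-I, ordered as ikr_markov.TRANSITIONS.  The structure
# follows established five-state hERG Markov models: a slow voltage-
# dependent activation step C3<->C2 (hundreds of ms in the plateau range,
# the hallmark of hERG gating), a voltage-insensitive C2<->C1 step, a
# mildly voltage-dependent final opening C1<->O with slow closing (which
# produces the characteristic slowly deactivating tail), and fast strongly
# rectifying inactivation O<->I (midpoint near -47 mV).  The C3<->C2 and
# C1<->O equilibria are centred so the simulated 2-s-step peak-tail I-V is
# half-maximal near -20 mV with a sigmoidal rise saturating above +10 mV,
# and the end-pulse I-V rectifies inward above 0 mV.
_WT_A = np.array(
    [
        0.005,      # C3 -> C2 (slow activation, forward)
        0.0084638,  # C2 -> C3 (deactivation)
        0.05,       # C2 -> C1 (voltage-insensitive)
        0.05,       # C1 -> C2
        0.0274,     # C1 -> O  (final opening)
        0.001378,   # O  -> C1 (slow closing; sets the tail decay)
        0.090821,   # O  -> I  (inactivation, fast at depolarised V)
        0.006497,   # I  -> O  (recovery from inactivation)
    ]
)
_WT_B = np.array(
    [
        0.05,       # C3 -> C2
        -0.05,      # C2 -> C3
        0.0,        # C2 -> C1
        0.0,        # C1 -> C2
        0.038198,   # C1 -> O
        -0.04178,   # O  -> C1
        0.023391,   # O  -> I
        -0.03268,   # I  -> O
    ]
)


def default_true_params(genotype) -> MCParams:
    """Ground-truth Markov parameters for a genotype.

    WT: the documented default rate set above with conductance ``WT_G_KR``.
    HET: identical kinetics, conductance scaled by ``HET_CONDUCTANCE_FACTOR``.
    HOM: zero conductance and an identically zero effective current.
    """
    gt = Genotype.coerce(genotype)
    if gt is Genotype.WT:
        g = WT_G_KR
    elif gt is Genotype.HET:
        g = WT_G_KR * HET_CONDUCTANCE_FACTOR
    else:
        g = 0.0
    return MCParams(a=_WT_A.copy(), b=_WT_B.copy(), g_kr=g, genotype=gt)


def standard_protocol() -> ClampProtocol:
    """Conventional hERG activation/tail I-V protocol.

    Hold at -80 mV (100 ms pre-segment), 2 s depolarising steps from -40 to
    +60 mV in 10 mV increments, then a 4 s tail at -40 mV; sampled at 1 ms.
    """
    return ClampProtocol(
        holding_mV=-80.0,
        segments=((-80.0, 100.0), (None, 2000.0), (-40.0, 4000.0)),
        step_voltages=tuple(float(v) for v in range(-40, 61, 10)),
        sample_interval_ms=1.0,
    )


@dataclass
class ReferenceDataset:
    """A synthetic clamp dataset: truth, noiseless and noisy traces."""

    genotype: Genotype
    protocol: ClampProtocol
    true_params: MCParams
    noiseless: ClampResult
    noisy_traces: list
    noise_sd: float
    seed: int


def generate_dataset(
    genotype,
    protocol: ClampProtocol | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ReferenceDataset:
    """Simulate the protocol under the genotype truth and add recording noise.

    Noise is i.i.d. additive Gaussian with standard deviation ``noise_sd``
    (pA/pF), drawn from ``numpy.random.default_rng(seed)`` so a fixed seed
    reproduces the noisy traces exactly.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    if protocol is None:
        protocol = standard_protocol()
    params = default_true_params(genotype)
    clean = run_voltage_clamp(params, protocol)
    rng = np.random.default_rng(seed)
    noisy = [
        CurrentTrace(
            tr.time_ms.copy(),
            tr.current_pApF + rng.normal(0.0, noise_sd, tr.current_pApF.shape)
            if noise_sd > 0
            else tr.current_pApF.copy(),
            tr.sweep_mV,
        )
        for tr in clean.traces
    ]
    return ReferenceDataset(
        genotype=Genotype.coerce(genotype),
        protocol=protocol,
        true_params=params,
        noiseless=clean,
        noisy_traces=noisy,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


def write_dataset(ds: ReferenceDataset, outdir) -> Path:
    """Write a dataset directory: protocol, truth, traces and a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.protocol.save(out / "protocol.json")
    ds.true_params.save(out / "params_true.json")
    traces_to_csv(ds.noiseless.traces, out / "traces_noiseless.csv")
    traces_to_csv(ds.noisy_traces, out / "traces_noisy.csv")
    manifest = {
        "genotype": ds.genotype.value,
        "noise_sd_pApF": ds.noise_sd,
        "seed": ds.seed,
        "files": {
            "protocol": "protocol.json",
            "params_true": "params_true.json",
            "traces_noiseless": "traces_noiseless.csv",
            "traces_noisy": "traces_noisy.csv",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_dataset(indir) -> ReferenceDataset:
    """Reload a dataset directory written by :func:`write_dataset`."""
    src = Path(indir)
    manifest = json.loads((src / "manifest.json").read_text())
    protocol = ClampProtocol.load(src / manifest["files"]["protocol"])
    params = MCParams.load(src / manifest["files"]["params_true"])
    clean = run_voltage_clamp(params, protocol)
    noisy = traces_from_csv(src / manifest["files"]["traces_noisy"])
    return ReferenceDataset(
        genotype=Genotype.coerce(manifest["genotype"]),
        protocol=protocol,
        true_params=params,
        noiseless=clean,
        noisy_traces=noisy,
        noise_sd=float(manifest["noise_sd_pApF"]),
        seed=int(manifest["seed"]),
    )
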