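"""Shared fixtures: generator truths, one session-wide fit, strand summaries.

Expensive artifacts (the calibration fit, per-genotype strand runs) are
computed once per session and reused by unit and acceptance tests alike;
single-cell steady-state pacing is cached inside cell_tnnp.
"""

from __future__ import annotations

import numpy as np
import pytest

from herglqt.cell_tnnp import CellConfig, steady_state_cell
from herglqt.ikr_markov import MCParams
from herglqt.mc_fitting import fit, perturbed_init
from herglqt.synthetic_clamp import (
    HET_CONDUCTANCE_FACTOR,
    default_true_params,
    generate_dataset,
    standard_protocol,
)
from herglqt import strand1d

GENOTYPES = ("WT", "HET", "HOM")


@pytest.fixture(scope="session")
def wt_true() -> MCParams:
    return default_true_params("WT")


@pytest.fixture(scope="session")
def wt_dataset():
    """Noiseless synthetic WT clamp dataset (the calibration reference)."""
    return generate_dataset("WT", standard_protocol(), noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def wt_fit(wt_dataset):
    """The session fit: WT Markov model recovered from noiseless traces,
    starting from a x2/÷2 perturbation of the generator truth."""
    init = perturbed_init(default_true_params("WT"), seed=0)
    return fit(wt_dataset.noiseless.traces, wt_dataset.protocol, init,
               max_iter=120, n_restarts=8, seed=0)


def genotype_params(base: MCParams, genotype: str) -> MCParams:
    """Derive HET/HOM parameter sets from a WT (fitted or true) set."""
    if genotype == "WT":
        return base
    if genotype == "HET":
        return MCParams(a=base.a, b=base.b, g_kr=base.g_kr * HET_CONDUCTANCE_FACTOR,
                        genotype="HET")
    return MCParams(a=base.a, b=base.b, g_kr=0.0, genotype="HOM")


@pytest.fixture(scope="session")
def steady_apd():
    """APD90 at 1 Hz steady state, (cell_type, genotype) -> ms, generator truths."""
    out = {}
    for ct in ("ENDO", "MIDDLE", "EPI"):
        for gt in GENOTYPES:
            cfg = CellConfig(cell_type=ct, genotype=gt, mc_params=default_true_params(gt))
            _, hist = steady_state_cell(cfg)
            out[(ct, gt)] = hist[-1].apd90
    return out


@pytest.fixture(scope="session")
def strand_runs():
    """One paced strand beat per genotype: (history, ECG trace)."""
    out = {}
    for gt in GENOTYPES:
        cfg = strand1d.StrandConfig(genotype=gt, mc_params=default_true_params(gt))
        S = strand1d.conditioned_state(cfg)
        h = strand1d.simulate_strand(cfg, [strand1d.Stimulus(0.0, 0, 4)], 900.0,
                                     rec_every_ms=0.5, S0=S)
        out[gt] = (h, strand1d.pseudo_ecg(h))
    return out
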