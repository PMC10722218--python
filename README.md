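# herglqt

Multiscale simulation of hERG (Kv11.1 / *KCNH2*) loss of function in human
ventricles.  Loss-of-function variants of the hERG channel reduce the rapid
delayed rectifier current I_Kr, delay ventricular repolarization and
underlie long-QT syndrome type 2 (LQT2).  This package chains the models
needed to take such a variant from patch-clamp current to tissue-level
arrhythmia markers:

1. **Channel** — a five-state Markov chain of I_Kr,
   `C3 <-> C2 <-> C1 <-> O <-> I`, with mono-exponential transition rates
   `r_k(V) = a_k exp(b_k V)` and current
   `I_Kr = g_Kr * sqrt(Ko/5.4) * [O] * (V - E_K)`.
2. **Calibration** — least-squares fitting of the rate coefficients to
   voltage-clamp current traces (BFGS in log-parameter space with a
   Gauss-Newton polish), plus a synthetic-data generator that emulates a
   HEK-cell activation/tail I-V protocol for wild-type (WT), heterozygous
   (HET, conductance x 0.36) and homozygous (HOM, no current) channels.
3. **Cell** — the ten Tusscher 2004 human ventricular myocyte model with
   its Hodgkin-Huxley I_Kr replaced by the Markov chain; transmural cell
   types ENDO / MIDDLE / EPI with a G_Kr density ratio 1.0 : 0.8 : 1.3;
   pacing, APD90, S1-S2 restitution and alternans analysis.
4. **Tissue** — monodomain reaction-diffusion
   `dV/dt = D lap(V) - I_ion` solved explicitly: a 21 mm transmural strand
   (140 nodes, dx 0.15 mm, D 0.18 mm^2/ms) for pseudo-ECG QT intervals,
   conduction velocity and vulnerable-window (unidirectional-block) scans;
   and a 2D sheet with cross-field S1-S2 spiral initiation,
   phase-singularity (rotor) tracking, breakup time, dominant frequency and
   tip-meander area.

It is aimed at cardiac electrophysiology modellers who want a compact,
fully scripted in-silico assay of a repolarization-reserve mutation.

## Worked example

```python
from herglqt import default_true_params
from herglqt.cell_tnnp import CellConfig, steady_state_cell

for gt in ("WT", "HET", "HOM"):
    cfg = CellConfig(cell_type="EPI", genotype=gt, mc_params=default_true_params(gt))
    _, hist = steady_state_cell(cfg)   # 1 Hz pacing to steady state
    print(gt, round(hist[-1].apd90, 1), "ms")
```

prints

```
WT 274.1 ms
HET 297.1 ms
HOM 312.6 ms
```

— the epicardial action-potential duration (APD90) at 1 Hz: losing 64% of
I_Kr (HET) prolongs the AP by ~23 ms and losing all of it (HOM) by ~39 ms,
the cellular signature of LQT2.  The same objects drive the tissue level:

```python
from herglqt.strand1d import (StrandConfig, Stimulus, conditioned_state,
                              simulate_strand, pseudo_ecg, measure_qt)

cfg = StrandConfig(genotype="HOM")
S = conditioned_state(cfg)
h = simulate_strand(cfg, [Stimulus(0.0, 0, 4)], 900.0, S0=S)
print(round(measure_qt(pseudo_ecg(h)).qt_ms, 1), "ms QT")   # -> 374.5 ms QT
```

A `herglqt` command-line tool exposes the same stages
(`synthclamp | fit | cell | restitution | strand | spiral2d | pipeline`)
with JSON/YAML configs, fixed seeds and per-stage run manifests.

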