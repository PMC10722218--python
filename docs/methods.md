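# Methods

This note records the models implemented in `herglqt`, their assumptions,
the default parameters and the numerical choices, in the order the pipeline
runs them.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Markov-chain I_Kr model

The rapid delayed rectifier current is described by a linear five-state
chain

```
C3 <-> C2 <-> C1 <-> O <-> I
```

(three closed states, one open, one inactivated).  Every directed
transition `k` has a mono-exponential rate `r_k(V) = a_k exp(b_k V)` with
amplitude `a_k > 0` (1/ms) and slope `b_k` (1/mV).  The membrane current is

```
I_Kr = g_Kr * sqrt(Ko / 5.4) * [O] * (V - E_K)      (pA/pF)
```

keeping the square-root external-potassium factor of the host ventricular
model so the Markov formulation is a drop-in replacement for its
Hodgkin-Huxley I_Kr.  A homozygous loss-of-function genotype is modelled as
an identically zero current (not merely `g_Kr = 0`); the two are verified
to produce numerically identical voltage trajectories.

Wild-type reference coefficients (order C3→C2, C2→C3, C2→C1, C1→C2, C1→O,
O→C1, O→I, I→O):

| a (1/ms)  | b (1/mV) | role |
|-----------|----------|------|
| 0.005     |  +0.05   | slow voltage-dependent activation |
| 0.0084638 |  −0.05   | deactivation |
| 0.05      |   0      | voltage-insensitive intermediate step |
| 0.05      |   0      | |
| 0.0274    |  +0.0382 | final opening |
| 0.001378  |  −0.0418 | slow closing (sets the deactivating tail) |
| 0.090821  |  +0.0234 | fast inactivation (inward rectification) |
| 0.006497  |  −0.0327 | recovery from inactivation |

`g_Kr = 0.03116 nS/pF`.  The structure follows established five-state hERG
Markov models: activation is slow (hundreds of ms in the plateau range, the
hallmark of hERG gating), inactivation is fast with a midpoint near −47 mV
so the end-pulse I−V rectifies inward above 0 mV, and closing from O is
slow so repolarisation produces the characteristic resurgent tail current.
The two free equilibria (C3↔C2, C1↔O) are centred so the simulated
peak-tail I−V of the standard 2-s step protocol is half-maximal at −20 mV,
and `g_Kr` is set so the epicardial cell model paced at 1 Hz repolarises
with APD90 = 274.1 ms (the wild-type reference value).  Both calibrations
were done once, against those two anchors only.

**Limitation.**  With a single shared kinetic scheme scaled by the regional
conductance ratio (below), the transmural APD-prolongation pattern upon
I_Kr elimination saturates near EPI ≈ MIDDLE in relative terms; reference
patterns in which the MIDDLE cell prolongs twice as strongly as EPI are not
reachable in this host model by any shared-kinetics I_Kr we probed (from
instantly-open to very slow two-stage activation).  Quantities downstream
of the MIDDLE-cell wild-type APD (its prolongation percentage, absolute QT
intervals, vulnerable-window widths) inherit this; orderings across
genotypes are unaffected.

## Synthetic voltage-clamp data

Real recordings of the mutant channel are not redistributable, so a
generator emulates them: the standard activation/tail protocol (hold
−80 mV, 100 ms pre-segment, 2 s steps −40…+60 mV in 10 mV increments, 4 s
tail at −40 mV, 1 kHz sampling), genotype truths (WT as above; HET = WT
kinetics with conductance × 0.36, which reduces peak I_Kr during the 1 Hz
action potential by ≈ 64%; HOM = zero current), and additive homoscedastic
Gaussian recording noise (default sd 0.05 pA/pF) drawn from a seeded
generator.  The generator does **not** emulate leak or capacitance
artifacts, cell-to-cell conductance variability, series-resistance error or
kinetic shifts of the mutant; passing recovery tests therefore demonstrates
correctness of the estimation machinery on an idealised recording, not
robustness to those experimental confounds.

## Fitting

The objective is the unweighted sum of squared residuals between simulated
and observed current samples over all sweeps.  Voltage-clamp simulation
exploits the piecewise-constant command: within a segment the occupancy
evolves as `pi(t) = pi0 expm(Q t)`, evaluated in closed form from the
eigendecomposition of the generator (eigenvalues clipped to `Re ≤ 0`
against round-off), so one objective evaluation costs milliseconds.

Optimisation runs in `x = [log a, b, log g]` (positivity without
constraints) with BFGS, followed by a trust-region least-squares
(Gauss-Newton) polish per start — finite-difference BFGS alone stalls in
line-search precision loss about an order of magnitude above the residual
floor.  A deterministic multi-start (default 8; log-uniform perturbations
from a seeded generator) guards against local minima and stops early at the
noiseless floor.  Because the rate constants of a chain fitted to
macroscopic current are not identifiable, recovery is judged on currents:
the fitted model's I−V (normalised to its own maximum) against the
reference.

## Ventricular cell model

Host: the ten Tusscher 2004 human ventricular formulation (all currents,
gates, calcium buffering and concentration dynamics), with its
Hodgkin-Huxley I_Kr replaced by the Markov chain.  Transmural types ENDO,
MIDDLE, EPI differ in G_to, G_Ks and the s-gate as in the host model;
regional I_Kr density is ENDO : MIDDLE : EPI = 1.0 : 0.8 : 1.3 applied as a
conductance multiplier.  The host's native HH I_Kr is retained behind
`ikr_formulation="hh"` for reference runs.  Only the 2004 variant is
implemented; `model_variant="TP2006"` is rejected with a clear error.

Numerics: Rush-Larsen exponential updates for HH gates, forward Euler for
concentrations (instantaneous-buffer quadratics for Ca), and for the Markov
occupancies a truncated-Taylor evaluation (order 4) of `expm(Q dt)` applied
to the occupancy vector — at `rate × dt < 1e-2` this is the matrix
exponential to machine precision and conserves total occupancy exactly.
All voltage-dependent quantities are tabulated on a 0.01 mV grid
(nearest-node lookup); fCa/g gate targets on a Cai grid; the inward
rectifier on a (V − E_K) grid.  Nernst potentials are refreshed every step
in single-cell runs and every 5 (strand) or 10 (sheet) steps in tissue —
the concentrations they depend on drift orders of magnitude more slowly.
Default dt = 0.02 ms; halving it moves steady-state APD90 by ≈ 0.14 ms.

Protocols: stimulus −52 pA/pF for 1 ms (cell) or 2 ms (tissue); pacing at
BCL 1000 ms until consecutive APD90 differ by < 0.1 ms (max 200 beats).
APD90 is measured from the maximum-dV/dt instant to the first downward
crossing of `V_rest + 0.1 (V_peak − V_rest)`, with `V_rest` the
pre-stimulus potential of that beat and sub-sample interpolation.

Restitution: after the steady S1 train and one further S1, two S2 stimuli
are delivered at the coupling interval SI (stimulus onset to stimulus
onset — the SI axis convention chosen here); both S2-evoked APD90 values
are registered, and a point is flagged as alternans (bifurcation) when they
differ by more than 1 ms — above numerical noise, below physiological
alternans.  Capture requires a regenerative overshoot (V > 0 mV persisting
beyond the stimulus artifact); decremental responses count as no capture.
The maximal restitution slope is the largest centred difference
dAPD90/dSI on the single-valued branch.

## 1D strand

21 mm, dx 0.15 mm → 140 nodes; ENDO nodes 0-41, MIDDLE 42-96, EPI 97-139
(largest-remainder rounding of 1 : 1.3 : 1, ties to EPI, ENDO at the
stimulated end).  Explicit 3-point Laplacian, no-flux ends, D = 0.18
mm²/ms, dt = 0.02 ms (stability requires D dt/dx² ≤ 1/2; configurations
violating it are rejected).  Nodes start from their cell type's 1 Hz
steady state and one conditioning beat precedes measured beats.

Pseudo-ECG: unipolar electrode on the fibre axis 20 mm beyond the EPI end,
`Phi(t) = −Σ_i (dV/dx)_i d(1/r)/dx|_i dx`.  QT runs from QRS onset (first
crossing of 5% of the QRS peak) to T-wave end (last crossing of 5% of the
T peak after the T peak); the 5% threshold is deterministic and robust on
noiseless traces.  Note that in an electrotonically coupled strand the
T wave ends near the (coupling-shortened) MIDDLE-region repolarisation, so
the QT can sit *below* the longest isolated single-cell APD90.

Conduction velocity: `(x75 − x25)/(t75 − t25)` from max-dV/dt activation
times at the 25% and 75% strand positions.  At the default discretisation
this estimator reads 0.775 m/s, consistent with the host model's published
planar velocity scaled to D = 0.18 (≈ 0.76 m/s); grid refinement raises it
further (the explicit scheme is not yet asymptotic at dx 0.15), and an
end-to-end transit measure including stimulus latency would read ≈ 0.70.

Vulnerable window: after S1 from the ENDO end, S2 on nodes 4-14 at a
scanned delay (default 200-420 ms, 1 ms steps; the scan advances one
S1-only simulation incrementally and branches a 200 ms S2 run per delay).
Antegrade/retrograde conduction is a fresh upward −20 mV crossing at
sentinel nodes on either side of the S2 segment (nodes 1 and 30) within
200 ms; the VW width is the number of unidirectional delays × step.  In
this implementation the scan shows **two** unidirectional bands: a narrow
local-refractory band at the earliest conducting delays, and a wide band in
which antegrade conduction fails at the still-refractory MIDDLE region —
the latter's width tracks the strand's transmural APD dispersion.  Reported
widths count both (the stated definition); genotype ordering
WT < HET < HOM holds.

## 2D sheet

Isotropic monodomain, 5-point Laplacian, no-flux boundaries, same D/dt;
transmural bands along the S1 axis with the strand's ratio.  Cross-field
initiation: S1 on the left edge; S2 over the top half fired automatically
when the S1 wave-back (V recovering through −60 mV, median of the midline
column) crosses the domain midline.  The protocol contains no randomness.

Phase analysis: time-delay embedding
`phi = atan2(V(t) − V*, V(t−τ) − V*)` with `V* = −40 mV`, `τ = 2 ms`;
phase singularities are 2×2 plaquettes whose closed-loop winding is ±2π,
with the winding sign as topological charge.  Rotor metrics: count per
frame; breakup = first time the count exceeds 2 sustained for 100 ms;
dominant frequency = spectral peak (Hann-windowed FFT, 0.5-15 Hz) of a
probe AP trace; meander area = convex hull of the pre-breakup tip
trajectory.

**Scale.**  Full-scale sheets (7.5 × 7.5 cm², 500 × 500 nodes, 8 s) are
cluster-class in this implementation (~10⁻⁷ s per node-step on one core).
The test suite therefore exercises the 2D machinery on closed-form spiral
fixtures (exact tip counts, charges and rotation rates) plus
reduced-domain simulations.  On domains of ≈ 4 cm the initiated spiral
self-terminates within roughly one rotation — the model's wavelength at
these kinetics exceeds such domains — so genotype comparisons of breakup
time and dominant frequency are not expected to be meaningful below the
full domain size, and the corresponding reduced-scale checks document this
limitation rather than reproduce full-scale behaviour.

## Reproducibility

Every stochastic element (recording noise, optimiser restarts) draws from
`numpy.random.default_rng` seeded explicitly; pipeline stages write
manifests (config snapshot, seed, package version, wall time) and are
skipped when re-run unchanged, making full runs byte-reproducible.
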