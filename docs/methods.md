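# Methods

## Scope and model summary

`m1beta` is a deliberately reduced re-creation of an in-silico
experiment: take a data-constrained model of the mouse M1 microcircuit,
change nothing except the intrinsic excitability of the PT5B
(corticospinal) population the way 6-OHDA dopamine depletion changes it
in vitro, and measure what happens to network oscillations.  The
original experiment used morphologically detailed neurons (hundreds of
compartments) and ~10,000 cells on a supercomputer; this package keeps
the architecture of that experiment — cell classes, laminar column,
distance-dependent wiring, afferent drive, LFP forward model, analysis
battery — at a scale that runs on one CPU in minutes.  Quantities that
depend on the full-scale connectome (absolute firing-rate tables,
duty-cycle percentages, coincidence fractions) are treated as
directional references, not numeric targets; the single-cell
excitability calibration is the one quantity reproduced exactly.

## Cell models

Five classes: PT5B, IT (intratelencephalic), CT (corticothalamic)
pyramids with soma, axon, basal and two-to-three apical compartments
(5–6 total), and PV / SOM interneurons with the classic 3-compartment
(soma, axon, dendrite) layout.  Channels: transient Na⁺ and
delayed-rectifier K⁺ (Pospischil-style kinetics with a per-class
threshold shift `vt`), leak, a reduced BK conductance, and — in PT5B
only — an HCN (Ih) current (E = −30 mV, V½ = −82 mV, τ = 50 ms).

The BK current is modeled without an explicit calcium pool: a single
voltage-gated gate (V½ = −30 mV, k = 7 mV, τ = 15 ms).  The slow time
constant makes it integrate over successive spikes, so it supplies the
medium AHP that grades the f–I curve, and its small resting window
current hyperpolarizes the cell when its density is raised — the two
effects the parkinsonian phenotype needs.  This is the package's main
cellular simplification; it trades calcium dynamics (explicitly out of
scope) for a two-parameter knob with the right signs.

Geometry, densities (mS/cm²) and passive parameters live in
`src/m1beta/data/cells/*.json`, one file per (class, condition).  They
were tuned once so that control cells land in plausible ranges for
their types (PT5B: V_rest ≈ −67 mV with Ih, rheobase ≈ 0.12 nA,
steady-state firing up to ~60 Hz at twice rheobase; interneurons more
excitable, PV fast-spiking).  Integration is exponential-Euler with
tabulated gate kinetics, dt = 0.025 ms; spikes are upward 0 mV
crossings at the soma with a 2 ms refractory.

### Parkinsonian calibration

`calibrate_parkinsonian` reproduces the in-vitro lesion as a two-step
search mirroring its physiology: (1) bisect a BK multiplier until the
mean spike-count reduction across 1 s somatic steps (8 amplitudes,
rheobase → 2× rheobase) reaches the 64% target; (2) raise NaT in small
steps (re-bisecting BK each time) until the variant's f–I slope is at
least `(1 − target) ×` the control slope — the floor implied by
proportional count scaling; (3) nudge BK up if any single step
out-fires control (monotone suppression).  Spike counts are integers,
so the reduction moves in discrete jumps; the search accepts whichever
bisection bracket end is closest to the target and verifies the ±5
percentage-point tolerance.  The shipped variant: BK × 1.38,
NaT × 1.05, reduction 63.2%.

The exact conductance values are data (`PT5B_parkinsonian.json`), not
code, and are regenerated by rerunning the calibration.

## Circuit

A cylinder 300 µm across and 1350 µm deep, layers L1 (cell-free),
L2/3, L4, L5A, L5B, L6 as fixed depth fractions.  Population counts
derive from per-layer densities chosen to give 10,073 ± 1% neurons at
scale 1, with per-layer excitatory fractions 85–90%, IT:PT5B = 1:1 in
L5B, IT:CT = 1:1 in L6, PV:SOM = 2:1 (L4 interneurons pooled with L5A,
as in the reference architecture).

Connectivity: per ordered population pair, `p(d) = p_con e^{−d/λ}`
(λ = 100 µm, 3-D somatic distance) with strength `S_con = p_con ×
v_con`, where `v_con` is the unitary somatic PSP in mV.  The
`p_con`/`v_con` table (`data/network.json`) is an estimate at layer
resolution: canonical cortical motifs (strong L2/3→L5, L4→L2/3
feed-forward, within-layer recurrence), E→I and I→E strengths per
layer, and a deliberately strengthened L5B loop (PT5B↔PV5B/SOM5B,
PT5B recurrence, PT5B→L4/5A interneurons) that makes the PT5B
population a driver of its own phasic inhibition — the substrate
through which its excitability controls the network rhythm.  These
values are config, not claims; the tests that depend on them are the
scaled-down network-level checks.

**Border correction.**  In a finite cylinder, edge cells see less
kernel mass.  For each rule and each postsynaptic cell the connection
probability is multiplied by `S_axis(z) / S_here`, where `S` is the sum
of `e^{−d/λ}` over the realized presynaptic ensemble evaluated at the
cell's position and at the cylinder axis at the same depth.  This
equalizes expected in-degree across radius exactly (verified: outer
quartile within 5% of inner; ≥ 20% deficit with the correction off).

**Weights.**  An edge's conductance is calibrated, not assumed: for
each (postsynaptic class, dendritic zone, receptor kind) the package
finds the peak conductance whose single activation produces a 0.5 mV
somatic PSP (inhibitory kinds measured at −55 mV holding), then scales
linearly to the rule's `v_con`.  Synapse placement: PV→E within 50 µm
path distance of the soma, SOM→E on apical compartments, inputs to
interneurons on the dendrite, E→E uniform over dendritic length.
Delays are `2 ms + d/(0.5 m/s)` exactly.

**Sub-density scaling.**  At `scale < 1` the connection probability
(not the weight) is multiplied by `1/scale` (clipped at 1), preserving
expected in-degree while keeping single-synapse physiology; clipping
compresses in-degree variance for the nearest pairs, a known
approximation at small scales.

**Receptors.**  AMPA (0.05/5.3 ms), NMDA (15/150 ms, Mg²⁺ factor
`1/(1+0.28 e^{−0.062V})` at 1 mM, 1:1 with AMPA), fast GABA_A
(0.07/18.2 ms), slow GABA_A (2/100 ms), E_rev 0/−80 mV.  GABA_B is
reduced to a slow double-exponential K⁺ conductance (50/200 ms,
−95 mV) at a 10% share of SOM→E synapses, standing in for the
second-messenger GIRK cascade whose parameters are outside this
package's scope.

## Drive and states

Each of seven afferent regions is a bank of 1000 independent Poisson
generators with per-generator rates drawn uniformly from the region's
background range (VL/cM1/M2 0–2.5 Hz, VM/S1/S2/OC 0–5 Hz); each
generator contacts each cell of its target populations with probability
0.25, through AMPA+NMDA synapses on a dendritic compartment.  Relative
drive weights per class and population (config) were tuned once so the
control rest state has all excitatory populations active in the 1–15
spikes/s range with interneurons faster — the regime the reference
experiment reports.  The *activated* (movement) state changes exactly
two things: motor-thalamic (VM+VL) rates to 0–10 Hz uniform, and PT5B
Ih to 25% (applied idempotently).  Applying the override to both VM and
VL reflects the ambiguity of "motor thalamus"; nothing else changes.

## Engine

All compartments of all cells are flattened into global state arrays
advanced by a single numba kernel: exponential-Euler voltage update
with frozen-neighbor axial coupling, exact exponential gate updates
from per-class lookup tables, double-exponential synaptic states with a
circular delay buffer (one slot per dt), and per-cell spike detection.
Initial voltages get a seeded ±2 mV Gaussian jitter to break symmetry.
Per-compartment membrane currents are recovered from axial currents
(Kirchhoff), so each cell's currents sum to zero to machine precision —
the property the LFP forward model requires.  dt-halving changes
population rates by < 5% (weak convergence; spike-time chaos is
expected in recurrent spiking networks).

Three seed streams (connectivity, stimulation, location) are derived
from one master seed; identical configuration yields byte-identical
spike files.

## LFP and spectral analysis

Every compartment is a vertical line segment (apical toward the pia,
axon/basal deeper); the potential at an axis electrode is the
line-source solution `I/(4πσL)·[asinh((L−s₀)/r) − asinh(−s₀/r)]` with
σ = 0.3 mS/mm, summed over all segments (guard distance 10 µm).  Seven
electrodes sit at layer midpoints plus the L5B boundaries; analyses
default to the L5B-depth electrode.  The forward map is precomputed as
a transfer matrix and accumulated during integration, so full current
traces are only stored on request.

Spectrograms use complex Morlet wavelets (PyWavelets `cmor`,
bandwidth set for a 6-cycle envelope) on 1–50 Hz; band power is the
mean over the band × time rectangle; bursts are runs above 2× the
per-frequency median power lasting ≥ 2 cycles.

## Spike-pattern statistics

Spike-count histograms pool a population's spikes in 2 ms bins over the
analysis window (the last 2.3 s of 4.3 s; the first 2 s discard the
initialization transient).  The duty cycle smooths the SCH (3-bin
moving average by default), thresholds at (min+max)/2, interpolates
rising/falling crossings linearly, defines a period rising→rising and
ON rising→falling, and reports the mean ON/period.  This resolves the
ambiguity between "period = ON span" and "period = full cycle" in favor
of the full cycle; it is a definition choice, flagged here.  ISI CV is
per neuron with ≥ 3 spikes, classified regular at CV ≤ 0.5 (boundary
inclusive).  Rate comparisons use the two-sided Mann–Whitney rank-sum
test without multiple-comparison correction.

## Synchrony (unitary events)

A coincidence event is ≥ 2 spikes from distinct neurons within 1 ms,
with overlapping windows merged into maximal clusters; an event counts
once in the event list and in the %-coincident-spikes summary.  For
significance the package separates reporting from testing: within each
sliding 100 ms window (20 ms step) the test statistic is the number of
cross-neuron spike pairs in disjoint 1 ms bins, whose expectation under
independent Poisson firing at the window's empirical rates is the
pairwise product formula `N_bins · Σ_{i<j} p_i p_j`.  Statistic and
expectation have matched means by construction; significance is the
upper Poisson tail (joint surprise), epochs are maximal runs of
windows with p < α = 0.05, and each epoch's oscillation frequency is
the reciprocal *median* inter-event interval (robust to sporadic chance
coincidences).  The one-sided test is calibrated (type-I ≤ 0.07 at
α = 0.05 over 200 independent-Poisson replicates) and gains power when
many neurons join a volley — a cluster-counting statistic compared
against a pairwise expectation would be structurally powerless at
population rates, which is why the pair count is used.  Network-level
unitary-event analysis runs on a seeded 20-cell PT5B ensemble: the
framework targets small ensembles, and pooling hundreds of cells
saturates the 1 ms windows.

## Synthetic ground truth

`synthetic_data` exists so every analysis stage is testable without the
simulator: sinusoidally rate-modulated Poisson trains sampled by exact
thinning (known base rate, depth, frequency), injected coincidences
with a returned ground-truth list, and point/dipole/oscillating-dipole
current patterns with closed-form potentials.  These emulate the
*statistics* the analyses consume — oscillatory rates, millisecond
coincidences, compartmental current sources — not the biophysics of
real data: no refractoriness, no rate heterogeneity, no spatial
correlation structure.  Passing these tests validates the analysis
arithmetic, not the realism of the network model.

## Problem sizes and desk-scale expectations

Network experiments default to scale 0.1 (~1000 neurons, ~5000
compartments), 4.3 s simulated, analysis on the last 2.3 s — a single
run takes under a minute on one CPU.  At this scale the package
reproduces the *direction* of the parkinsonian rest-state contrast:
13–17 Hz LFP power at the L5B electrode increases for every tested
seed (ratios ~1.3–1.9 at the 64% calibration) and the seed-median
ratio grows with the calibrated excitability reduction (1.0 → ~1.7 →
~1.9 for 0/30/64%); PT5B firing becomes more regular (lower ISI CV).
The order-of-magnitude power increase and the paradoxical *increase*
in PT5B rate reported at full scale do not emerge in this reduction —
both depend on the detailed 100-µm-resolution connectome (in
particular its disinhibition loops) that the layer-resolution wiring
table only approximates.  The acceptance tests assert the directions;
where the desk-scale model cannot produce one, the test documents the
failure rather than weakening the check.

## Known limitations

* BK without calcium dynamics; no other Ca-dependent or dendritic
  nonlinear channels.
* Layer-resolution connectivity with estimated strengths; no axonal
  arbor geometry, gap junctions, or synapse-count multiplicity (all
  reduced cells use one synapse per connection).
* GABA_B as a fixed slow conductance.
* Exponential-Euler with frozen-neighbor axial coupling rather than an
  implicit branch solver; adequate at dt = 0.025 ms for these few-
  compartment cells (verified by dt-halving), not for long cables.
* The activated-state analyses are exercised by the pipeline but not
  tuned: desk-scale gamma-band claims are out of scope.
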