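# m1beta

Desk-scale simulation and analysis of how a cell-intrinsic parkinsonian
change — reduced excitability of layer-5B pyramidal-tract (PT5B)
neurons — reshapes oscillatory activity in a primary motor cortex (M1)
microcircuit.

In 6-OHDA (dopamine-depleted) mouse models, PT5B neurons fire ~64%
fewer spikes to somatic current injections, traced to increased BK
(large-conductance Ca-activated K⁺) and transient sodium (NaT)
currents.  `m1beta` embeds that single-cell lesion in an otherwise
unchanged conductance-based M1 column and quantifies the network-level
consequences: local field potential (LFP) beta-band power (13–30 Hz,
the electrophysiological signature of parkinsonism), spike-pattern
regularity, and millisecond-scale population synchrony.

The package is aimed at computational neuroscientists who want a
self-contained, reproducible, laptop-scale version of this in-silico
experiment: every stage (cell calibration, circuit wiring, network
integration, LFP forward model, spike statistics) is an importable
module with synthetic ground-truth generators for testing.

## What is inside

| module | contents |
| --- | --- |
| `m1beta.cells` | reduced-compartment Hodgkin–Huxley models (PT5B, IT, CT, PV, SOM); f–I protocols; calibration of the parkinsonian PT5B variant to a target excitability reduction |
| `m1beta.circuit` | 300 µm × 1350 µm cylindrical column, ~10,073 neurons at full density; distance-dependent wiring `p(d) = p_con e^{−d/λ}` (λ = 100 µm) with border correction; synaptic kinetics (AMPA/NMDA with Mg²⁺ unblock `1/(1+0.28 e^{−0.062V})`, fast/slow GABA_A, GABA_B); delay `2 ms + d / (0.5 m/s)` |
| `m1beta.drive` | seven afferent Poisson-generator banks (VM, VL, S1, S2, cM1, M2, OC); rest ↔ activated state switch (motor thalamus 0–10 Hz, PT5B Ih × 0.25) |
| `m1beta.engine` | numba-accelerated exponential-Euler network integrator (dt = 0.025 ms), exact synaptic delay queues, membrane-current bookkeeping |
| `m1beta.lfp` | line-source extracellular forward model (σ = 0.3 mS/mm), multi-depth electrodes, 6-cycle Morlet spectrograms, band power, burst detection |
| `m1beta.spike_analysis` | population spike-count histograms (2 ms bins), oscillation duty cycle, ISI-CV regularity classification (CV ≤ 0.5), rank-sum rate comparisons |
| `m1beta.synchrony` | 1 ms population coincidence detection and unitary-event (joint-surprise) significance epochs against rate-matched Poisson expectations |
| `m1beta.synthetic_data` | ground-truth generators: oscillatory Poisson trains (thinning), injected coincidences, current patterns with closed-form potentials |
| `m1beta.pipeline` / `m1beta.cli` | condition × state experiment grid, manifests, analysis-only path, `m1beta` command line |

## Worked example: the parkinsonian PT5B calibration

```python
import m1beta.cells as cells

control = cells.build_cell("PT5B", "control")
parkinsonian = cells.calibrate_parkinsonian(control)   # BK up, then NaT up
amps = cells.default_step_amplitudes(control)          # rheobase .. 2x rheobase
fi_c = cells.simulate_current_steps(control, amps, 1000.0)
fi_p = cells.simulate_current_steps(parkinsonian, amps, 1000.0)
for a, c, p in zip(amps, fi_c.spike_counts, fi_p.spike_counts):
    print(f"  {a:.3f} nA: control {c:3d}  parkinsonian {p:3d}")
red = cells.mean_spike_count_reduction(fi_c, fi_p)
print(f"mean spike-count reduction: {100*red:.1f}%")
print(f"f-I slope: {fi_c.slope():.0f} -> {fi_p.slope():.0f} Hz/nA")
```

prints

```
  0.123 nA: control   2  parkinsonian   0
  0.141 nA: control   2  parkinsonian   1
  0.158 nA: control   4  parkinsonian   1
  0.176 nA: control  30  parkinsonian   2
  0.193 nA: control  37  parkinsonian  17
  0.211 nA: control  43  parkinsonian  21
  0.229 nA: control  47  parkinsonian  24
  0.246 nA: control  63  parkinsonian  42
mean spike-count reduction: 63.2%
f-I slope: 526 -> 328 Hz/nA
```

The calibrated variant suppresses spiking at every step (63.2% mean
reduction against the 64% in-vitro target) while the NaT increase keeps
the f–I slope from collapsing — the two-step tuning that mirrors the
electrophysiology.

A full network experiment (both conditions, rest + activated states,
10% density column, 4.3 s each with the last 2.3 s analyzed):

```bash
m1beta experiment --out runs/demo --scale 0.1 --seed 1
```

writes per-run spikes, LFP traces, spectrograms, duty-cycle/CV/rate
tables, unitary-event epochs, and a manifest with the
parkinsonian/control beta-power ratios.

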