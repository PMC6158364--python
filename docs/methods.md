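# Methods

## Scope and model class

`dbsnet` is a *conceptual* circuit model, not a biophysical one. It asks how
the trans-synaptic propagation of three signal classes — the DBS pulses
themselves, endogenous "background" activity in the stimulated nucleus, and
the downstream responses to both — depends on stimulation frequency. It
deliberately omits everything not needed for that question: synaptic and
homeostatic plasticity, inhibitory output nuclei (e.g. pallidal
projections), electrode geometry and field spread, axon-versus-soma
activation, and conductance-based synapses are all out of scope.

## Neurons

All cells are two-variable Izhikevich neurons (quadratic voltage nonlinearity
`0.04v² + 5v + 140`, linear recovery variable, hard reset at +30 mV),
integrated by forward Euler with a single full step for `v` and `u` per
`dt = 0.1 ms`. The three presets are the canonical published sets:

| preset           | a    | b    | c   | d    | used for            |
|------------------|------|------|-----|------|---------------------|
| thalamocortical  | 0.02 | 0.25 | −65 | 0.05 | thalamic relay      |
| regular_spiking  | 0.02 | 0.2  | −65 | 8    | cortex_exc, motor_out |
| fast_spiking     | 0.1  | 0.2  | −65 | 2    | cortex_inh          |

Two derived quantities recur in the design. For a fixed recovery value `u`,
the subthreshold voltage equation has two roots; the lower is the
(momentary) rest, the upper the regenerative threshold. The gap between
them, `sep(u)`, is the instantaneous kick a synaptic event must deliver to
fire the cell, and it *grows* with `u`: the regular-spiking `d = 8`
increment therefore acts as a strong per-spike gate, while the
thalamocortical `d = 0.05` leaves the relay cells essentially
non-adapting. Near-threshold crossings of the quadratic are slow (a few
mV of margin costs 1–2 ms of "crawl" to the spike peak), which matters for
every latency argument below.

## Populations, connectivity, and weights

Four populations: thalamus (400, TC), cortex_exc (400, RS), cortex_inh
(100, FS), motor_out (400, RS). Topology: one-to-one thalamus→cortex_exc
and cortex_exc→motor_out; diffuse (all-to-all) cortex_inh→motor_out; sparse
random (Erdős–Rényi, p = 0.1, no self-edges) recurrence within every
population and for cortex_inh→cortex_exc; a denser random recruitment path
cortex_exc→cortex_inh at p = 0.25, so that even partial cortical volleys
reliably drive the interneurons while asynchronous baseline activity does
not.

Each synapse delivers a fixed *charge* per presynaptic spike. Base weights
are per connection type and roughly in-degree-normalized — a one-to-one
synapse carries a whole relay step on a single afferent and is strong; a
40-afferent recurrent synapse is weak:

| connection                 | base weight | role |
|----------------------------|------------:|------|
| thalamus→cortex_exc (1:1)  | 100  | fast, faithful relay: cortex follows every thalamic spike with sub-millisecond latency |
| cortex_exc→motor_out (1:1) | 80   | fast output relay; must outrun the feedforward inhibition by ~0.2 ms at low rates |
| cortex_exc→cortex_inh      | 1.0  | volley detector: ~100 coincident afferents fire an FS cell, asynchronous input does not |
| cortex_inh→motor_out (diffuse) | −40 | the coordinated inhibitory volley that gates the output |
| cortex_inh→cortex_exc / →cortex_inh | −2 / −1 | inhibitory recurrence throughout cortex |
| within-population recurrence | 0.01 (thalamus), 0.2 (RS pops) | sustained-activation substrate; thalamic value is kept below the TC threshold gap (~1.8 mV for a 40-edge volley) so the pacemaker population cannot phase-lock itself |

A global excitatory scale `g_E ∈ {1, 2, 4, 8}` and inhibitory scale
`g_I ∈ {1, 2, 4, 8, 16}` multiply all weights of the respective sign.
`calibrate_weights` picks the first pair (lexicographic order, deterministic
tie-break) satisfying two operational criteria: (i) *excitability* — a
single suprathreshold pulse to all thalamic cells at rest, drive off,
elicits ≥ 50 motor_out spikes within 50 ms; and (ii) *no sustained
oscillation* — with background drive switched off after 500 ms, every
population falls below 0.1 spikes/s/neuron within 200 ms. On the default
network the search selects (1, 1): the bases are normalized to the designed
operating point, so the grid acts as a safety check that the point is
feasible rather than as the primary tuning mechanism.

## Synapses

Excitatory charge is delivered as current over a single integration step —
an instantaneous voltage kick equal to the weight. Inhibitory charge feeds
an exponentially decaying synaptic current with `tau_inh = 10 ms`
(GABA-A-like). The asymmetry is load-bearing: in a quadratic-voltage neuron
a hyperpolarizing *kick* is forgotten within 1–2 ms (the voltage relaxes
back at the quadratic rate), so instantaneous inhibition could never gate
the motor output *between* pulses. With exponential inhibition, each
cortical volley deposits −4000 charge units on every output cell; the
residual current at the arrival of the *next* pulse's excitation grows with
pulse rate, and the crossover where it defeats the kick of 80 sits between
40 and 60 Hz. Below that, the output follows; at and above it, the output
is vetoed every cycle. Conduction delay is 0.4 ms for every connection
(grid-snapped); with the 3 ms attribution window and ~1–2 ms thalamic spike
latency, a longer delay would push the disynaptic cortical response outside
the window and misclassify it as background.

## Background drive and the propagation cutoff

Only the thalamus receives direct drive: per-neuron current
`bias + sigma·N(0,1)` each step, with `bias = 1.0` and `sigma = 0.15`
(model units; per-step at dt = 0.1 ms). This puts TC cells just above
rheobase (~1.02), where they fire as near-regular ~20 Hz pacemakers
(steady-state inter-spike interval ≈ 48 ms with ≈ 2–3 ms dispersion).
`calibrate_drive` reproduces this choice by grid search on an unconnected
population, targeting the interior of the 10–40 spikes/s/neuron operating
band.

The pacemaker character is the mechanism of the propagation cutoff. Each
DBS pulse fires and resets every thalamic cell, restarting its integration
toward the next natural spike. If the inter-pulse interval is shorter than
the cell's natural interval, no natural spike ever completes: thalamic
background activity is *exactly zero* above the intrinsic rate, and since
cortex only relays thalamus, nothing propagates downstream either. At or
below the intrinsic rate, natural spikes fit between pulses and propagate
normally. The cutoff therefore falls between the 20 Hz and 30 Hz points of
the sweep grid, and its gradual onset below 20 Hz comes from pulses
pre-empting natural spikes with increasing probability. A high-noise drive
(fluctuation-driven firing) cannot produce this sharp cutoff: its
inter-spike-interval distribution has a heavy short tail that keeps leaking
background spikes at 30+ Hz.

## DBS stimulus

Monophasic rectangular depolarizing pulses, 180 µs wide, applied as
identical synchronous current to all thalamic neurons (no spatial falloff —
the synchrony is what makes the stimulated volley "massively synchronous"
downstream). Pulses are rasterized onto the integration grid with exact
charge conservation (each step gets the amplitude scaled by its overlap
with the pulse), so delivered charge per pulse is independent of `dt` and
of onset alignment. The clinical amplitude has no defined mapping into
model current units; `calibrate_pulse_amplitude` defines "clinically
suprathreshold" as twice the minimal single-pulse amplitude (bisection to
1%) that fires a resting TC cell within 3 ms — 121 model units at the
defaults. A biphasic charge-balanced waveform is not modeled; the model has
no electrode interface for the balancing phase to act on.

## Spike attribution and sweep metrics

A spike at time `t` is stimulus-locked iff some onset `o` satisfies
`o ≤ t < o + window`, with `window = 3 ms` (configurable; must be shorter
than the inter-pulse interval). The window is sized to the disynaptic chain
latency: thalamic response ~1–2 ms, plus 0.4 ms conduction and a fast
cortical crawl. The trisynaptic output response (~2.5–3.5 ms) straddles the
boundary, so motor_out per-pulse numbers undercount at low frequency; the
output's total rate carries the complementary information.

Per-pulse metrics divide by — and count within — only pulses whose full
window fits inside the post-burn-in recording; a censored window would bias
the statistic. Background rates are background-labeled spikes per second of
analysis epoch, population-aggregated. For a zero-amplitude (sham) train,
the expected stimulus-locked count per pulse is the chance coincidence
level `R·w` (aggregate rate × window); the test suite verifies agreement
within 3σ over 10 seeds. A paired-run oracle (`excess_spikes`: same drive
seed, stimulation on minus off) ships as a validation-only alternative
attribution.

Qualitative regime labels operationalize the frequency bands of the
substitution hypothesis, evaluated against the DBS-off baseline with
configurable thresholds: `silent` (thalamic rate < 5% of baseline),
`blockade` (cortical background < 10% and output rate < 10%),
`substitution` (cortical background < 10% with stimulus-locked cortical
spikes), `additive` (background ≥ 50%), and `attenuated` for the region
between — the four-label scheme leaves that gap, and an honest in-between
label is preferable to forcing a boundary case.

## Numerical and reproducibility choices

- **Integration**: forward Euler, `dt = 0.1 ms` (the 180 µs pulse spans ≥ 1
  step); spike detection on the updated voltage, reset `v ← c` exact; the
  recovery update uses the pre-step voltage. Halving `dt` changes per-spike
  timing (first-spike latency, inter-spike intervals) by well under 1 ms
  against a `dt = 0.01 ms` reference; absolute spike times accumulate the
  usual first-order phase drift (~0.3 ms per spike at `dt = 0.1`).
- **Voltage floor** at −90 mV: the quadratic nonlinearity is unstable under
  deep hyperpolarization, so strong inhibitory volleys are shunting-limited
  there. A guard aborts the run if any pre-reset voltage exceeds 1000 mV in
  magnitude.
- **Initialization**: undriven populations start at their preset's resting
  state with ±1 mV uniform jitter. Tonically driven (pacemaker) populations
  start from stationary-state samples of the noisy single-cell cycle,
  obtained by sampling random time points of one long seeded reference
  trajectory. Rest-plus-jitter would start all pacemakers phase-clustered;
  the cluster disperses only by slow phase diffusion (~3 ms/cycle) and
  meanwhile produces a spurious population rhythm that aliases against the
  pulse grid and biases sham-control statistics by tens of percent.
- **RNG policy**: one master seed per run; initial conditions and
  background noise use separate child streams of a `SeedSequence`, and
  recording consumes no randomness, so adding or removing observers cannot
  perturb dynamics. Identical configurations produce byte-identical spike
  CSVs.
- **Spike-time convention**: a spike is stamped with the start time of the
  step on which the voltage crossed the peak; synaptic delivery occurs at
  the first grid step at or after `t + delay` (strictly after the spike).

## Problem sizes

The default analysis protocol — also used by the test suite and the
acceptance script — is 2 s of simulated time per condition with a 500 ms
burn-in, three seeds per sweep frequency, and the 12-point grid
{5, 10, 20, 30, 40, 60, 80, 100, 125, 150, 185, 250} Hz, which spans the
clinical range and contains the three raster frequencies (10, 60, 185 Hz).
These durations give ≥ 10⁴ spikes per population per condition at baseline
rates; the headline quantities (background cutoff frequency, per-pulse
entrainment, output gating) are stable to the third seed and second decimal
at these sizes.

## What the synthetic conditions do and do not show

The generator *is* the study system: all conclusions are about this
idealized circuit, not about recorded data. In particular (a) the thalamic
background is a homogeneous tonic pacemaker process — real dystonic firing
is bursty, correlated, and non-stationary, and a bursty background would
blur the sharp 20–30 Hz cutoff into a band; (b) relays are single-afferent
and suprathreshold, so background propagates losslessly below the cutoff —
real thalamocortical convergence would make low-frequency propagation
graded; (c) the exact cutoff location tracks the assumed intrinsic thalamic
rate, and the output-gating crossover tracks the inhibitory time constant
and volley charge; the qualitative ordering (additive → substitution →
blockade with rising frequency) is the robust prediction, the specific
hertz values are not; (d) no plasticity means the model says nothing about
habituation, washout, or chronic adaptation.

## Known limitations

Euler integration limits `dt` refinement claims to per-spike (not
accumulated-phase) accuracy. The inhibitory interneurons' own late
responses fall outside the 3 ms window at 185–250 Hz and are counted as
background for that population (cortex_exc and motor_out are unaffected).
The weight-calibration grid certifies feasibility at the designed operating
point rather than exploring the full weight space. All delays are equal, so
the model cannot express differential conduction timing between pathways.
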