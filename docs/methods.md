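# Methods

## Neuron and synapse model

Cortical cells are leaky integrate-and-fire point neurons,
`tau_m dV/dt = E_L - V + R_m I`, with an inclusive threshold (a spike fires
when V >= V_theta), reset to V_reset and an absolute refractory period
t_ref. The synaptic current I is the sum of two accumulators with
first-order kinetics, `tau_s dI/dt = -I`: one excitatory (tau_se, always
>= 0) and one inhibitory (tau_si, always <= 0). Each presynaptic spike adds
its synaptic weight to the matching accumulator as a discrete impulse, so
the charge carried by one postsynaptic current of amplitude w is exactly
w * tau_s.

Standard parameters (paired-recording estimates for the excitatory cells
of each layer; no separate interneuron physiology is available, so
inhibitory cells reuse their layer's constants):

| parameter | unit | L2/3 | L4  |
|-----------|------|------|-----|
| E_L       | mV   | -72  | -66 |
| V_reset   | mV   | -72  | -66 |
| V_theta   | mV   | -40  | -40 |
| tau_m     | ms   | 30   | 35  |
| R_m       | MOhm | 190  | 300 |
| tau_se    | ms   | 5    | 5   |
| tau_si    | ms   | 15   | 15  |
| t_ref     | ms   | 10   | 10  |

## Integration on a 1-ms clock

The engine advances all neurons on a fixed 1-ms grid. Per step, in a fixed
order: (1) spikes emitted at the previous step (and source spikes stamped
with the current step) are delivered into the accumulators; (2) the
membrane is advanced across the step; (3) the accumulators are decayed by
`exp(-dt/tau_s)`; (4) threshold and reset are applied. Every projection has
a one-step conduction delay, so no spike affects the network at its own
step.

The membrane advance uses the exact propagator of the coupled linear
system: with u = V - E_L and start-of-step accumulator values I_e, I_i,

    u' = alpha u + c_e I_e + c_i I_i,
    alpha = exp(-dt/tau_m),
    c_x   = R_m tau_sx / (tau_sx - tau_m) (exp(-dt/tau_sx) - alpha),

so the grid trajectory equals the continuous-time solution sampled at grid
points (the scheme exponential-current simulators such as NEST call exact
integration). The simpler alternative — holding I constant across the step
— systematically over-delivers each PSC's charge by the factor
(dt/tau_s)/(1 - e^(-dt/tau_s)) (about +10% at tau_s = 5 ms), which is an
order of magnitude outside the package's accuracy target of 0.1% of the
threshold distance against a dt = 0.001 ms reference integration; it is
kept only as the standalone `step_membrane` analysis helper.

Refractory bookkeeping: a spike at step t sets the timer to t_ref; on each
later step the timer is decremented first and the membrane is clamped at
V_reset only while the timer remains positive, with the accumulators
continuing to decay and collect input throughout. The earliest re-spike is
thus exactly t + t_ref and the maximum sustained rate 1000/t_ref = 100 Hz,
which is the saturation rate the hyperactive regime locks to.

Initial conditions are deterministic — V = E_L, zero currents — unless an
explicit initial-V vector is supplied. A consequence worth knowing: runs
without a rest period begin with a fluctuation-driven ignition delay of
tens of milliseconds before the network reaches its stationary regime, so
whole-run rate averages in the hyperactive regime under-count the
saturated rate by roughly t_ignite/T; saturation measurements therefore
use the steady-state second half of each run.

## Network construction

Populations per column: L2/3 4507/795, L4 3471/613 (excitatory/inhibitory),
285 thalamic relay cells. Connectivity is an independent Bernoulli draw per
ordered (pre, post) pair — self-pairs allowed, at most one synapse per pair
— with p = 0.25 thalamocortical (to both L4 populations) and p = 0.1 for
every intracortical projection, so a recurrent block of N cells realises
p N^2 synapses in expectation. Conduction delays are uniformly one step
(1 ms): the minimal causal choice for a 1-ms clocked system.

Excitatory weights are 0.1 nA; each layer's inhibitory weight comes from
the charge-balance rule `|w_i| tau_si = b w_e tau_se N_e/N_i` computed from
that layer's own counts (0.1887 nA in L4, 0.1890 nA in L2/3 at b = 1), and
the inhibitory-to-excitatory weight is additionally scaled by `i2e_scale`
(default 1.5) in **both** layers — the protocols that state the scaling for
one layer reuse the same balanced construction everywhere, and uniform
application is the simplest consistent reading. Interlayer projections
L4E -> {L2/3E, L2/3I} run at p = 0.1 and 0.2 nA; lateral projections
between adjacent columns connect the supragranular excitatory populations
in both directions at p = 0.1 and 0.1 nA, with no wraparound at the chain
ends. Only the bidirectional reading reproduces the ~4.9 * 10^7 total
synapse count of the five-column model (one direction alone gives
~4.1 * 10^7).

Every build is a pure function of one seed: the seed is split into one
child per projection (fixed order), so a model rebuilt with the same seed
is bit-identical, and rebuilding with a different balance coefficient
changes weights but not topology.

`--scale s` multiplies every population size by s (rounded, floor 1) with
probabilities unchanged and the balance rule recomputed from the scaled
counts. Scaled models are for plumbing and smoke tests; their dynamics are
not those of the full-size model (in-degrees shrink with s).

## Thalamocortical weight calibration

The thalamocortical weight is the minimum needed for 6-Hz Poisson thalamic
drive to elicit firing in a barrel stripped of intracortical projections.
"Elicit firing" is operationalised as a mean L4 excitatory rate of at
least 1 Hz over a 10-s run — the in-vivo-like spontaneous rate the model
is meant to sustain. The feed-forward rate rises extremely steeply with
the weight (about 0.1 Hz at 0.0245 nA, 1.5 Hz at 0.030 nA, 8 Hz at
0.041 nA), so criteria far below 1 Hz select a drive under which each cell
fires once per tens of seconds — indistinguishable from silence on the
one-second protocol scale — and, downstream, leave the recurrent barrel in
a degenerate all-or-none bursting state rather than balanced asynchronous
firing. The search brackets by factors of two and bisects to 1% relative
tolerance with connectivity and drive realisation held fixed, so the
criterion is monotone in the weight and the returned value (~0.029 nA at
full scale) is the smallest passing weight tested. It sits below the
mean-field bound of ~0.041 nA at which the average drive alone reaches
threshold: cortical firing at the calibrated weight is fluctuation-driven.

## Stimulus synthesis

Thalamic sources are independent Poisson processes realised by Bernoulli
thinning on the 1-ms grid (one spike per source per bin with probability
rate * dt). At the 30-Hz stimulus peak that probability is 0.03, so the
thinning bias relative to exact waiting times is under 3% and the spike
trains arrive exactly on the clock the engine uses. Deflection onsets are
triangular excursions 6 -> 30 Hz in 5 ms decaying back in 30 ms; offsets
are the mirrored triangle (30-ms rise, 5-ms fall) of equal amplitude. A
single-deflection battery is 500 ms of rest, an onset, and an offset
150 ms later; the multi-column battery replaces the pair with five
onset/offset repetitions at 10 Hz (offset 50 ms after its onset — the lag
within a repetition is not otherwise constrained, and half the period
interleaves the events evenly). Overlapping excursions would combine by
maximum, not summation; with the standard timings they never overlap. One
master seed is split into per-population and per-trial generator seeds, so
trials are independent and reproducible in any execution order.

What the generator emulates is the *rate structure* of whisker-evoked
thalamic firing; it does not model thalamic neuron dynamics, bursting,
adaptation, or cross-source correlations. Passing tests therefore certify
the network's response to rate-coded drive, not to the fine temporal
structure of real barreloid spike trains.

## Protocols and analysis conventions

All analysis windows are half-open [start, end) on 0-based millisecond
timestamps. PSTHs use 5-ms bins by default and are normalised per neuron,
per alignment and per second, so the PSTH integral times
(neurons * alignments) recovers the event count. Windowed count maps sum
spikes over [onset, onset + 25 ms) for every deflection onset. An "evoked
response" is a PSTH exceeding its pre-battery baseline mean by 3 baseline
standard deviations in at least two consecutive post-onset bins; the
two-bin requirement suppresses the ~12% single-bin false-positive rate a
100-bin null PSTH would otherwise carry, while genuine deflection
responses span seven or more bins.

- **Balance sweep**: for each b on a log grid (default 25 points on
  [0.1, 10]), rebuild the barrel with the same connectivity seed and
  i2e_scale = 1, run seeded 1-s trials under constant 6-Hz drive, and
  report mean and sd over trials of the whole-run L4E rate.
- **Response transformation**: independently built barrels at b = 1,
  i2e_scale = 1.5; each battery is an independent 800-ms run with a fresh
  stimulus seed (equivalent to concatenation thanks to the 500-ms rest).
  Spontaneous rates are measured on [100, 500) ms, skipping the initial
  transient; onset/offset peaks are the maximum PSTH bin within 60 ms of
  the event.
- **Chain**: five batteries of the multi-column schedule delivered to
  column 0's thalamus, all other barreloids held at 6 Hz; outputs are
  battery-aligned PSTHs per population and per-cell 25-ms post-onset
  count maps summed over all 25 deflections.

## Problem sizes used by the test suite

The always-run suite exercises full-size models with reduced repetition
counts: the sweep at b in {0.1, 0.5, 1, 2, 10} with 3 trials, the balanced
regime with 10 trials, the response transformation at its full 10 x 25
scale, and the chain protocol on the full five-column model with 5
batteries; single-neuron and statistics checks run on small synthetic
fixtures. These sizes were chosen so the whole suite completes in a few
minutes while every dynamical claim is still measured on the full-size
circuit.

## Known limitations

- **The supragranular layer has no asynchronous ~1 Hz state at the stated
  parameters.** The interlayer drive alone (in-degree 347 at 0.2 nA) holds
  every L2/3 cell far above threshold on average once L4 fires at ~1 Hz
  (R_m I ~ 66 mV against a 32-mV threshold gap), so L2/3 is an
  inhibition-stabilised network. Its low-rate fixed point exists in the
  mean-field sense but is unstable to synchronisation in a lossless,
  deterministic, identically-parameterised 1-ms simulation: the layer
  falls into all-or-none population avalanches, and in the multi-column
  model the lateral projections lock neighbouring columns into sustained
  mutual re-ignition at the refractory-limited rate. Randomised initial
  potentials re-synchronise within one burst, and faster inhibitory
  membranes silence the network without ever yielding the asynchronous
  state. Event-driven neuromorphic platforms running circuits of this
  class drop spikes when per-processor throughput is exceeded — precisely
  the coincident-avalanche condition — which can act as a desynchronising
  attenuation; this package deliberately models no spike loss, so the
  chain-propagation checks in the acceptance suite record the
  synchronised regime honestly rather than papering over it.
- Inhibitory neurons reuse their layer's excitatory constants; distinct
  fast-spiking physiology might change the stability picture above but is not
  constrained by the available measurements.
- All synapses within a projection share one weight and a one-step delay;
  no distance dependence, no weight distributions, no plasticity.
- The Bernoulli-thinned Poisson generator caps at one spike per source per
  millisecond (bias < 3% at the stimulus peak).
- Spike-loss, fixed-point arithmetic and other hardware-platform artefacts
  are intentionally out of scope; the engine is the lossless floating-point
  reference for the model.
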