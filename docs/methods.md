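# Methods

## Model

One neuron holds one kernel per input channel. A kernel is a ternary flag
*p* ∈ {−1, 0, 1}, an accumulator *r* ≥ 0 and a slope Δr. The update rules,
all integer:

* flag: *p(t)* = 1 if a spike arrives on an idle channel, or an up-ramp has
  not yet reached the peak *w*; −1 once the accumulator has reached *w*, or
  while a down-ramp is above zero; 0 otherwise. Spikes on a busy channel
  are no-ops, so only a burst's first spike matters.
* accumulator: *r(t)* = max(0, *r(t−1)* + *p(t)*·Δr(t−1)).
* soma: *s(t)* = 1 iff Σ<sub>i</sub> r<sub>i</sub>(t) > Θ(t−1). The
  membrane is not reset on spiking.
* slope: Δr(t) = clamp(Δr(t−1) + *p(t)*·ddr·*s(t)*, ddr, Δr<sub>max</sub>).
* threshold: +Θ<sub>rise</sub> on every spiking step; −Θ<sub>fall</sub>
  (clamped at 0) when the membrane returns to zero; else unchanged.

### Intra-step ordering

Within one Δt the signals cascade: flag → accumulator → soma → slope and
threshold feedback. Each block reads its *own* state from the previous
step, but downstream blocks see upstream values of the current step, as in
a combinational path between synchronous registers. This ordering is a
modelling commitment, fixed once for bit-exact reproducibility, and it is
the one under which the model's characteristic behaviours emerge: under
noiseless repetition the slopes grow to Δr<sub>max</sub> and the response
latency falls to ≈ *w*/Δr<sub>max</sub>; a kernel peaks in
[*w*, *w* + Δr) (the flag turns the step after the accumulator first
reaches *w*); the converged pulse width averages
Θ<sub>fall</sub>/Θ<sub>rise</sub>. A fully registered alternative — every
block reading only *t−1* values — was implemented and rejected: it drives
the slopes *down* to an equilibrium near *w*/latency and the latency up,
i.e. the neuron stops improving its response time, which defeats the
first-spike race the network relies on.

The competitive layer replaces the soma and threshold rules with their
gated forms: a neuron may initiate a pulse only while the shared inhibition
counter is zero (continuing an ongoing pulse is always allowed); its
threshold rises only when it actually spikes, and falls either at its own
pulse's falling edge or on membrane return to zero while inhibition is
inactive. The counter reloads to inh<sub>max</sub> on any output pulse
(peak detector — it holds for the pulse's whole duration) and decays by
inh<sub>decay</sub> per quiet step. Note the falling-edge term means a
*solitary* neuron simulated under the layer rules with inh<sub>max</sub> = 0
is not identical to the plain single-neuron rules: its threshold takes an
extra fall at each pulse end. The two rule sets are deliberately kept as
separate code paths.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| w | 10000 | kernel peak height (potential units); constant, shared by all synapses |
| ddr | 1 | slope change per feedback step; larger adapts faster, smaller is noise-robust |
| Δr_max | 400 | slope saturation; must satisfy Δr_max < w/PW so the first kernel outlives the pattern |
| Δr(0) | round(100·(1+U[0,1))) | per-kernel random initial slope; the heterogeneity that decorrelates neurons |
| Θ_rise / Θ_fall | 40·inputs / 100·inputs | threshold homeostasis; converged pulse width ≈ Θ_fall/Θ_rise = 2.5 Δt |
| Θ(0) | 0 | initial threshold: the first presentation always elicits output, so adaptation starts immediately |
| inh_max / inh_decay | 100 / 1 | inhibition hold-off ≈ 100 Δt; rule of thumb inh_max/inh_decay ≥ min Δr(0) |
| T | 400 Δt | presentation period; periods abut |
| PW | 20 Δt | maximal pattern width; offsets uniform on [0, PW] |

Δr has floor ddr: a slope of zero would freeze a kernel mid-ramp forever.
Θ is clamped at zero. No wall-clock value is assigned to Δt.

## Synthetic stimuli

The generators produce exactly the statistical structure the experiments
assume: random target patterns (one spike per channel, offsets i.i.d.
uniform on [0, PW]); i.i.d. pattern choice per presentation with
configurable mixture weights; Gaussian temporal jitter of std σ rounded to
the grid and clamped to the period (σ = 0 is the identity); Bernoulli
deletion of target spikes (keep probability P(signal)); and background
noise as a per-step Bernoulli process at rate noise_rate/T per channel —
exact on a discrete grid, and indistinguishable from a Poisson process at
these rates. With P(signal) + noise_rate = 1 the mean spike budget stays at
one spike per channel per period across the signal-to-noise axis. The
drifting-ISI generator emits two-channel pairs whose interval is
round(μ_k + σ_k·N(0,1)) per presentation.

What the generators do *not* emulate: real sensor front-ends, rate-coded
inputs, correlated noise across channels, or gaps between presentations.
Passing tests therefore show the model's behaviour under its own assumed
input statistics, not performance on recorded data.

All randomness flows from one master seed through named
`numpy.random.SeedSequence` sub-streams; identical seed and configuration
give bit-identical results, including across the pure-numpy reference
implementation and the numba-compiled engine (asserted in the test suite).

## Receptive-field probing

A probe freezes adaptation (ddr = Θ_rise = Θ_fall = 0 — the increments,
not the machinery), presents one pattern to a copy of the state, and
integrates Σ(membrane − Θ)·s over the presentation. Probing is
side-effect-free by construction (state hash checked in tests). For
two-input neurons the response curve over ISIs τ ∈ [−PW, PW] gives the
expected ISI (argmax; ties resolve to the smallest |τ|, negative first)
and the tolerated range (support boundaries). For wider patterns the
learnt-pattern error is operationalised as kernel-peak alignment: the RMS
of mean-centred first-peak times when the clean target is probed —
exhaustive RF evaluation over an (N−1)-dimensional ISI space would be
exponential, and the alignment reading is what the converged kernels
display directly.

## Experiments and problem sizes

Replicate counts are scaled for a desk run and configurable: selection
uses 200 simulations per probability (300-presentation sequences,
four-input neuron), classification 200–300 simulations of up to 800
presentations (simulations stop once the 20-consecutive-correct window is
met; detection over the full log is equivalent and cheaper than halting
the dynamics), and the noise sweep 8 replicates × 1000 presentations per
grid point. The whole test suite runs in well under a minute on one CPU;
`scripts/acceptance.py` in a few seconds.

Convergence of the classifier demands, within a 20-presentation window,
exactly one output pulse from exactly one neuron per presentation and a
label↔neuron map that is consistent and one-to-one over the pairs observed
in the window; a pattern that happens not to appear in a window is not
required to.

## Numerical and design notes

* Integer closure is a hard contract; the engine and the reference step
  functions are cross-checked bit-exactly on random inputs.
* Exact simultaneous threshold crossings make both neurons spike and adapt;
  no arbitration is attempted (heterogeneous initial slopes make organic
  ties rare after burn-in, and jitter dithers them away).
* The RF argmax of a converged neuron breathes by ±1 Δt with the threshold
  sawtooth; parameter-recovery checks therefore assert an exact hit within
  the first 50 presentations and a ±1 band thereafter. Small jitter
  (σ ≈ 0.5) dithers the quantisation and removes the bias — one concrete
  sense in which noise helps.
* `run_tracking` skips the RF probe (records NaN) if a kernel is still
  active at a period boundary, which can only happen in degenerate
  low-slope states; probing mid-pattern is undefined and refused.

## Known limitations

* With Θ(0) = 0 every neuron answers the very first presentations, so a
  competitive layer starts from simultaneous (tie-locked) responses and
  separates only as thresholds and slopes diverge; a minority of runs stay
  tied or mixed indefinitely. Convergence fractions plateau below 1
  accordingly, with near-identical pattern pairs the other irreducible
  residue.
* For patterns with widely spread offsets, the channel with the latest
  offset saturates at Δr_max while earlier channels equilibrate a step or
  two off perfect peak alignment; the learnt threshold margin shrinks
  correspondingly. Consequently a single neuron trained on a heavily
  skewed mixture can remain responsive to a rare pattern whose relative
  shape is close to the common one — the selection experiment reports such
  runs as selecting both patterns rather than hiding them.
* Wall-clock performance, not hardware resource usage, is in scope: the
  package makes no claims about register or logic-element counts.
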