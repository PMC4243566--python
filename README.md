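# skan — synapto-dendritic kernel adapting neurons

`skan` simulates a multiplier-free spiking neuron whose computation lives in
its *synapto-dendritic kernels*: per-channel triangular post-synaptic
potentials whose slopes adapt under the neuron's own back-propagating output
pulse. A single neuron performs unsupervised learning and statistical
inference over spatio-temporal spike patterns; a layer of them plus one
global inhibition bit becomes a competitive, unsupervised classifier. The
package is written for computational-neuroscience and neuromorphic-hardware
work: every state variable is an integer on a discrete time grid, so
trajectories are bit-exact and map directly onto digital hardware.

## The model

Time advances in unit steps Δt. Each input channel *i* carries a binary
spike train *u<sub>i</sub>(t)* and drives one kernel, a ramp-up/ramp-down
accumulator *r<sub>i</sub>* with slope Δr<sub>i</sub> controlled by a
ternary flag *p<sub>i</sub>*:

* a spike on an idle channel sets *p<sub>i</sub>* = 1; *r<sub>i</sub>*
  climbs by Δr<sub>i</sub> per step until it reaches the peak height *w*,
  then ramps down (*p<sub>i</sub>* = −1) to zero and rests. Spikes arriving
  mid-flight are ignored — the neuron trains on the first spike of a burst.
* the membrane potential is Σ<sub>i</sub> r<sub>i</sub>(t); it is never
  reset. The output bit is *s(t)* = 1 while the membrane exceeds the
  adaptive threshold Θ(t−1).
* during an output pulse, kernels still ramping up steepen
  (Δr<sub>i</sub> += ddr, they were late) and kernels already ramping down
  flatten (Δr<sub>i</sub> −= ddr, they peaked early), pulling all kernel
  peaks toward coincidence at the output time. Slopes live in
  [ddr, Δr<sub>max</sub>] with Δr<sub>max</sub> < w / PW for a pattern
  width PW.
* the threshold rises by Θ<sub>rise</sub> on every spiking step and falls
  by Θ<sub>fall</sub> when the membrane returns to zero, so the converged
  pulse width settles near Θ<sub>fall</sub>/Θ<sub>rise</sub> steps — a
  narrow pulse signals high certainty.

In a layer, neurons share inputs and a single decaying inhibition counter:
any output pulse reloads it to inh<sub>max</sub>, and while it is non-zero
no other neuron may *initiate* a pulse. Because the best-adapted neuron is
also the fastest to spike, this one bit decorrelates the layer: each neuron
claims, and thereby hides, its own pattern. Total wiring is
(inputs + 2) × neurons — linear, not combinatorial.

Defaults throughout are the reference parameter set: *w* = 10000, ddr = 1,
Δr<sub>max</sub> = 400, Δr(0) = round(100·(1+U[0,1))), Θ<sub>rise</sub> =
40·inputs, Θ<sub>fall</sub> = 100·inputs, inh<sub>max</sub> = 100,
inh<sub>decay</sub> = 1, presentation period T = 400 Δt, pattern width
PW = 20 Δt.

## A worked example

`examples/single_neuron_adaptation.py` trains a two-input neuron on one
repeated pattern:

```text
initial slopes: [126, 130]  (drawn from 100*(1+U[0,1)))
presentation   0: latency   0 dt, pulse width  99 dt
presentation  10: latency  48 dt, pulse width   3 dt
presentation  50: latency  39 dt, pulse width   3 dt
presentation 200: latency  23 dt, pulse width   2 dt
presentation 799: latency  24 dt, pulse width   3 dt
final slopes [399, 399] (saturation 400); minimum latency w/dr_max = 25 dt
mean converged pulse width 2.51 dt ~ theta_fall/theta_rise = 2.5
```

Early on the threshold is low, so the response is immediate and the pulse
wide (width 99 Δt: the neuron is certain of nothing). As the threshold
homeostat catches up and the slopes saturate, the response latency falls to
the kernel-geometry minimum w/Δr<sub>max</sub> ≈ 25 Δt and the pulse
narrows to the homeostatic width 2.5 Δt. The other scripts in `examples/`
demonstrate hidden-ISI tracking (`isi_tracking.py`), competitive
classification (`competitive_classification.py`) and learning under spike
deletion and background noise (`noise_robustness.py`); each prints the
quantities it computes and a line on what they mean.

## Command line

Every experiment is also reachable from a thin CLI that reads a flat YAML
config and writes result CSVs plus a JSON run manifest (config, seed,
output hashes — enough to reproduce the run bit-exactly):

```bash
skan simulate|select|classify|noise-sweep|track|rf \
     [--config cfg.yaml] --seed 1 --out results/ [--force]
```

A configuration violating the slope bound Δr<sub>max</sub> < w/PW is
refused unless `--force` is given.

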