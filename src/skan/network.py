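"""Competitive layer: neurons with shared inputs and one global decaying
inhibitory counter.

The only inter-neuron coupling is a single bit: whenever any neuron is
spiking the shared counter ``inh`` reloads to ``inh_max`` (a peak detector —
it holds for the whole pulse), then decays by ``inh_decay`` per quiet step.
While ``inh`` is non-zero no neuron may *initiate* an output pulse; a neuron
already spiking may continue.  Because the best-adapted neuron for a pattern
is also the fastest to spike, first-spike competition plus this one wire
suffices to decorrelate the layer: each neuron ends up answering only its
own pattern, hiding it from the others.

Threshold homeostasis is gated the same way: the threshold of a blocked
neuron neither rises (it never spikes) nor falls on membrane return to zero
while inhibition is active, so losers are untouched by patterns a rival has
claimed.  The winner's threshold takes its fall at its own pulse's falling
edge instead, since inhibition (which it raised itself) is still active when
its membrane later returns to zero.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .neuron import NeuronState, initial_slopes, kernel_flag_update
from .params import NetParams, SkanParams

__all__ = [
    "NetworkState",
    "init_network",
    "inhibition_update",
    "connection_count",
    "network_step",
    "run_reference_network",
]


@dataclass
class NetworkState:
    """Stacked per-neuron kernel arrays plus the shared inhibition counter."""

    p: np.ndarray      # int64, (n_neurons, n_inputs)
    r: np.ndarray      # int64, (n_neurons, n_inputs)
    dr: np.ndarray     # int64, (n_neurons, n_inputs)
    theta: np.ndarray  # int64, (n_neurons,)
    s: np.ndarray      # int64, (n_neurons,), in {0, 1}
    inh: int

    @property
    def n_neurons(self) -> int:
        return self.r.shape[0]

    @property
    def membrane(self) -> np.ndarray:
        return self.r.sum(axis=1)

    def neuron(self, n: int) -> NeuronState:
        """View of one neuron's state (copies the arrays)."""
        return NeuronState(self.p[n].copy(), self.r[n].copy(), self.dr[n].copy(),
                           int(self.theta[n]), int(self.s[n]))

    def copy(self) -> "NetworkState":
        return NetworkState(self.p.copy(), self.r.copy(), self.dr.copy(),
                            self.theta.copy(), self.s.copy(), int(self.inh))

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.p, self.r, self.dr, self.theta, self.s):
            h.update(np.ascontiguousarray(a, dtype=np.int64).tobytes())
        h.update(int(self.inh).to_bytes(8, "little"))
        return h.hexdigest()


def init_network(params: SkanParams, net: NetParams,
                 rng: np.random.Generator) -> NetworkState:
    """Fresh layer: every neuron gets independent random initial slopes."""
    shape = (net.n_neurons, params.n_inputs)
    dr = np.stack([initial_slopes(params.n_inputs, params, rng)
                   for _ in range(net.n_neurons)])
    return NetworkState(
        p=np.zeros(shape, dtype=np.int64),
        r=np.zeros(shape, dtype=np.int64),
        dr=dr.astype(np.int64),
        theta=np.full(net.n_neurons, params.theta_init, dtype=np.int64),
        s=np.zeros(net.n_neurons, dtype=np.int64),
        inh=0,
    )


def inhibition_update(inh_prev: int, any_spike: int, net: NetParams) -> int:
    """Shared counter: reload to ``inh_max`` while any neuron spikes, else
    decay toward the absorbing quiescent state at zero."""
    if any_spike:
        return net.inh_max
    if inh_prev > 0:
        return max(inh_prev - net.inh_decay, 0)
    return 0


def connection_count(n_inputs: int, n_neurons: int) -> int:
    """Total wiring of the layer: each neuron sees every input channel plus
    one inhibition line in and one spike line out — linear in the neuron
    count, not combinatorial."""
    if n_inputs < 0 or n_neurons < 0:
        raise ValueError("counts must be non-negative")
    return (n_inputs + 2) * n_neurons


def network_step(state: NetworkState, u, params: SkanParams,
                 net: NetParams) -> NetworkState:
    """One time step of the whole layer (pure; returns new state).

    Kernels advance exactly as in the single neuron; outputs and thresholds
    are gated by the shared inhibition read at its previous-step value, and
    the counter then updates from the union of this step's outputs.
    """
    u = np.asarray(u)
    if u.shape != (params.n_inputs,):
        raise ValueError(f"input vector shape {u.shape} != ({params.n_inputs},)")
    if state.r.shape[0] != net.n_neurons:
        raise ValueError("state/NetParams neuron count mismatch")

    s_prev = state.s
    mem_prev = state.r.sum(axis=1)
    p_new = kernel_flag_update(np.broadcast_to(u, state.p.shape), state.p,
                               state.r, params.w)
    r_new = np.maximum(state.r + p_new * state.dr, 0)
    mem = r_new.sum(axis=1)

    gate = (state.inh == 0) | (s_prev == 1)
    crossed = mem > state.theta
    s_new = (crossed & gate).astype(np.int64)
    dr_new = np.clip(state.dr + p_new * params.ddr * s_new[:, None],
                     params.dr_floor, params.dr_max)

    falling_edge = (s_new == 0) & (s_prev == 1)
    returned = (mem == 0) & (mem_prev > 0) & (state.inh == 0)
    theta_new = np.where(
        crossed & gate, state.theta + params.theta_rise,
        np.where(falling_edge | returned,
                 np.maximum(state.theta - params.theta_fall, 0),
                 state.theta),
    ).astype(np.int64)

    inh_new = inhibition_update(state.inh, int(s_new.any()), net)
    return NetworkState(p_new, r_new, dr_new, theta_new, s_new, inh_new)


def run_reference_network(state: NetworkState, raster: np.ndarray,
                          params: SkanParams, net: NetParams):
    """Step a layer through a dense raster; oracle for the jitted engine.

    Returns ``(final_state, s_trace (n_steps, n_neurons), inh_trace)``.
    """
    n_steps = raster.shape[0]
    s_out = np.zeros((n_steps, net.n_neurons), dtype=np.uint8)
    inh_out = np.zeros(n_steps, dtype=np.int64)
    for t in range(n_steps):
        state = network_step(state, raster[t], params, net)
        s_out[t] = state.s
        inh_out[t] = state.inh
    return state, s_out, inh_out
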