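"""Single-neuron dynamics: kernel flag state machine, slope adaptation,
soma comparison and threshold homeostasis.

This module is the readable reference implementation; :mod:`skan.engine`
provides a jitted step loop that reproduces these trajectories bit-exactly
(verified by the test suite).

The neuron holds one triangular kernel per input channel.  A spike on a
quiet channel flips the channel's flag ``p`` to +1; the accumulator ``r``
then ramps up by the channel's slope ``dr`` per step until it reaches the
peak height ``w``, ramps back down (``p`` = -1) and rests at zero
(``p`` = 0).  Spikes arriving while the kernel is in flight are ignored, so
the neuron trains on the first spike of a burst.  The membrane potential is
the sum of the accumulators; it is never reset.  While the membrane exceeds
the threshold the output bit ``s`` is 1 and the back-propagating pulse
steepens kernels still ramping up and flattens kernels already ramping
down, pulling all kernel peaks toward the moment of the output pulse.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .params import SkanParams

__all__ = [
    "KernelState",
    "NeuronState",
    "kernel_flag_update",
    "kernel_accumulate",
    "soma_compare",
    "threshold_update",
    "init_neuron",
    "initial_slopes",
    "neuron_step",
    "run_reference",
]


@dataclass
class KernelState:
    """State of one synapse/dendrite: ternary flag, accumulator, slope."""

    p: int
    r: int
    dr: int


@dataclass
class NeuronState:
    """Full neuron state: per-channel kernel arrays, threshold, output bit.

    The membrane potential is by definition ``r.sum()`` and is never stored
    separately.
    """

    p: np.ndarray   # int64, shape (n_inputs,), values in {-1, 0, 1}
    r: np.ndarray   # int64, shape (n_inputs,), >= 0
    dr: np.ndarray  # int64, shape (n_inputs,)
    theta: int
    s: int

    @property
    def membrane(self) -> int:
        return int(self.r.sum())

    @property
    def idle(self) -> bool:
        """True when every kernel has completed its cycle."""
        return bool(np.all(self.p == 0))

    def copy(self) -> "NeuronState":
        return NeuronState(self.p.copy(), self.r.copy(), self.dr.copy(),
                           int(self.theta), int(self.s))

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.p, self.r, self.dr):
            h.update(np.ascontiguousarray(a, dtype=np.int64).tobytes())
        h.update(int(self.theta).to_bytes(8, "little"))
        h.update(int(self.s).to_bytes(1, "little"))
        return h.hexdigest()


def _maybe_scalar(out: np.ndarray):
    return int(out) if out.ndim == 0 else out.astype(np.int64)


def kernel_flag_update(u, p_prev, r_prev, w: int):
    """Next value of the ternary kernel flag.

    ``+1`` (ramp up) if a spike arrives on a quiet kernel, or an up-ramp has
    not yet reached the peak ``w``; ``-1`` (ramp down) once the accumulator
    has reached ``w``, or while a down-ramp has not yet returned to zero;
    ``0`` otherwise.  Accepts scalars or aligned arrays.
    """
    u = np.asarray(u)
    p_prev = np.asarray(p_prev)
    r_prev = np.asarray(r_prev)
    if np.any((p_prev < -1) | (p_prev > 1)):
        raise ValueError("kernel flag outside {-1, 0, 1}")
    up = ((u == 1) & (p_prev == 0)) | ((p_prev == 1) & (r_prev < w))
    down = ((p_prev == 1) & (r_prev >= w)) | ((p_prev == -1) & (r_prev > 0))
    return _maybe_scalar(np.where(up, 1, np.where(down, -1, 0)))


def kernel_accumulate(r_prev, dr_prev, p_prev, s_prev, params: SkanParams):
    """Advance accumulator and slope one step under the previous flag and
    back-propagating output bit.

    ``r`` moves by ``p * dr`` and saturates at zero.  ``dr`` moves by
    ``p * ddr`` only during an output pulse (``s_prev`` = 1) and is clamped
    to ``[dr_floor, dr_max]``.  Pure function of its arguments.
    """
    r_prev = np.asarray(r_prev)
    dr_prev = np.asarray(dr_prev)
    p_prev = np.asarray(p_prev)
    r = np.maximum(r_prev + p_prev * dr_prev, 0)
    dr = np.clip(dr_prev + p_prev * params.ddr * int(s_prev),
                 params.dr_floor, params.dr_max)
    return _maybe_scalar(r), _maybe_scalar(dr)


def soma_compare(membrane: int, theta_prev: int) -> int:
    """Output bit: 1 iff the membrane strictly exceeds the previous-step
    threshold.  The membrane is not reset on spiking."""
    return 1 if membrane > theta_prev else 0


def threshold_update(theta_prev: int, membrane_now: int, membrane_prev: int,
                     params: SkanParams) -> int:
    """Homeostatic threshold: rises by ``theta_rise`` on every spiking step,
    falls by ``theta_fall`` when the membrane returns to zero, clamped at
    zero."""
    if membrane_now > theta_prev:
        return theta_prev + params.theta_rise
    if membrane_now == 0 and membrane_prev > 0:
        return max(theta_prev - params.theta_fall, 0)
    return theta_prev


def initial_slopes(n: int, params: SkanParams, rng: np.random.Generator) -> np.ndarray:
    """Randomised initial slopes ``round(lo + U[0,1) * (hi - lo))`` per
    kernel (the heterogeneity that lets different neurons win different
    patterns)."""
    u = rng.random(n)
    return np.rint(params.dr_init_lo + u * (params.dr_init_hi - params.dr_init_lo)).astype(np.int64)


def init_neuron(params: SkanParams, rng: np.random.Generator) -> NeuronState:
    """Fresh neuron: idle kernels, random slopes, threshold ``theta_init``."""
    n = params.n_inputs
    return NeuronState(
        p=np.zeros(n, dtype=np.int64),
        r=np.zeros(n, dtype=np.int64),
        dr=initial_slopes(n, params, rng),
        theta=params.theta_init,
        s=0,
    )


def neuron_step(state: NeuronState, u, params: SkanParams) -> NeuronState:
    """One discrete time step of the full neuron (pure; returns new state).

    Signals cascade through the neuron within the step, each block reading
    its *own* state from the previous step: (a) the flags observe the input
    spikes and the previous accumulators; (b) the accumulators follow the
    new flags (so a kernel turns the step after its accumulator first
    reaches ``w``, peaking in ``[w, w + dr)``); (c) the membrane is summed;
    (d) the output bit compares the new membrane to the previous threshold;
    (e) the slopes adapt under the new flag and output bit; (f) the
    threshold adapts.  This is the order under which the slope grows to
    ``dr_max`` under repeated presentations and the converged response
    latency approaches ``w / dr_max``.
    """
    u = np.asarray(u)
    if u.shape != (params.n_inputs,):
        raise ValueError(f"input vector shape {u.shape} != ({params.n_inputs},)")
    mem_prev = state.membrane
    p_new = kernel_flag_update(u, state.p, state.r, params.w)
    r_new, _ = kernel_accumulate(state.r, state.dr, p_new, 0, params)
    mem = int(r_new.sum())
    s_new = soma_compare(mem, state.theta)
    _, dr_new = kernel_accumulate(state.r, state.dr, p_new, s_new, params)
    theta_new = threshold_update(state.theta, mem, mem_prev, params)
    return NeuronState(p_new, r_new, dr_new, theta_new, s_new)


def run_reference(state: NeuronState, raster: np.ndarray, params: SkanParams):
    """Step a neuron through a dense spike raster ``(n_steps, n_inputs)``.

    Returns ``(final_state, s_trace, membrane_trace, theta_trace)``.  Python
    loop; intended for small inputs and as the oracle for the jitted engine.
    """
    n_steps = raster.shape[0]
    s_out = np.zeros(n_steps, dtype=np.uint8)
    mem_out = np.zeros(n_steps, dtype=np.int64)
    theta_out = np.zeros(n_steps, dtype=np.int64)
    for t in range(n_steps):
        state = neuron_step(state, raster[t], params)
        s_out[t] = state.s
        mem_out[t] = state.membrane
        theta_out[t] = state.theta
    return state, s_out, mem_out, theta_out
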