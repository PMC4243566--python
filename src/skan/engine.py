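"""Jitted step loops for long simulations.

The experiment suite runs millions of time steps; these numba kernels
reproduce the reference implementations in :mod:`skan.neuron` and
:mod:`skan.network` bit-exactly (asserted by the test suite — integer state,
same update order).  A single loop serves both the solitary neuron and the
competitive layer: with ``competitive=False`` the inhibition gates and the
falling-edge threshold term are absent, which is exactly the single-neuron
rule set.

All state arrays are updated in place; wrappers below shuttle the dataclass
states in and out.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .network import NetworkState
from .neuron import NeuronState
from .params import NetParams, SkanParams

__all__ = ["run_neuron", "run_network", "run_neuron_traced", "run_network_traced"]


@njit(cache=True)
def _step_loop(u, p, r, dr, theta, s, inh,
               w, ddr, dr_max, dr_floor, th_rise, th_fall,
               inh_max, inh_decay, competitive):
    n_steps, n_ch = u.shape
    n_neurons = r.shape[0]
    s_out = np.zeros((n_steps, n_neurons), dtype=np.uint8)
    for t in range(n_steps):
        any_spike = 0
        for n in range(n_neurons):
            s_old = s[n]
            mem_prev = 0
            mem = 0
            for i in range(n_ch):
                r_old = r[n, i]
                p_old = p[n, i]
                mem_prev += r_old
                if (u[t, i] == 1 and p_old == 0) or (p_old == 1 and r_old < w):
                    pn = 1
                elif (p_old == 1 and r_old >= w) or (p_old == -1 and r_old > 0):
                    pn = -1
                else:
                    pn = 0
                p[n, i] = pn
                rn = r_old + pn * dr[n, i]
                if rn < 0:
                    rn = 0
                r[n, i] = rn
                mem += rn
            crossed = mem > theta[n]
            if competitive:
                gate = inh == 0 or s_old == 1
                s_new = 1 if (crossed and gate) else 0
                if s_new == 1:
                    theta[n] += th_rise
                elif (mem == 0 and mem_prev > 0 and inh == 0) or (s_new == 0 and s_old == 1):
                    theta[n] -= th_fall
                    if theta[n] < 0:
                        theta[n] = 0
            else:
                s_new = 1 if crossed else 0
                if s_new == 1:
                    theta[n] += th_rise
                elif mem == 0 and mem_prev > 0:
                    theta[n] -= th_fall
                    if theta[n] < 0:
                        theta[n] = 0
            if s_new == 1:
                for i in range(n_ch):
                    pn = p[n, i]
                    if pn != 0:
                        d = dr[n, i] + pn * ddr
                        if d > dr_max:
                            d = dr_max
                        elif d < dr_floor:
                            d = dr_floor
                        dr[n, i] = d
            s[n] = s_new
            s_out[t, n] = s_new
            if s_new == 1:
                any_spike = 1
        if competitive:
            if any_spike:
                inh = inh_max
            elif inh > 0:
                inh -= inh_decay
                if inh < 0:
                    inh = 0
    return s_out, inh


@njit(cache=True)
def _step_loop_traced(u, p, r, dr, theta, s, inh,
                      w, ddr, dr_max, dr_floor, th_rise, th_fall,
                      inh_max, inh_decay, competitive):
    # identical dynamics to _step_loop, additionally recording per-step
    # membranes, thresholds, kernel values and the inhibition counter
    n_steps, n_ch = u.shape
    n_neurons = r.shape[0]
    s_out = np.zeros((n_steps, n_neurons), dtype=np.uint8)
    mem_out = np.zeros((n_steps, n_neurons), dtype=np.int64)
    theta_out = np.zeros((n_steps, n_neurons), dtype=np.int64)
    r_out = np.zeros((n_steps, n_neurons, n_ch), dtype=np.int64)
    inh_out = np.zeros(n_steps, dtype=np.int64)
    for t in range(n_steps):
        any_spike = 0
        for n in range(n_neurons):
            s_old = s[n]
            mem_prev = 0
            mem = 0
            for i in range(n_ch):
                r_old = r[n, i]
                p_old = p[n, i]
                mem_prev += r_old
                if (u[t, i] == 1 and p_old == 0) or (p_old == 1 and r_old < w):
                    pn = 1
                elif (p_old == 1 and r_old >= w) or (p_old == -1 and r_old > 0):
                    pn = -1
                else:
                    pn = 0
                p[n, i] = pn
                rn = r_old + pn * dr[n, i]
                if rn < 0:
                    rn = 0
                r[n, i] = rn
                r_out[t, n, i] = rn
                mem += rn
            crossed = mem > theta[n]
            if competitive:
                gate = inh == 0 or s_old == 1
                s_new = 1 if (crossed and gate) else 0
                if s_new == 1:
                    theta[n] += th_rise
                elif (mem == 0 and mem_prev > 0 and inh == 0) or (s_new == 0 and s_old == 1):
                    theta[n] -= th_fall
                    if theta[n] < 0:
                        theta[n] = 0
            else:
                s_new = 1 if crossed else 0
                if s_new == 1:
                    theta[n] += th_rise
                elif mem == 0 and mem_prev > 0:
                    theta[n] -= th_fall
                    if theta[n] < 0:
                        theta[n] = 0
            if s_new == 1:
                for i in range(n_ch):
                    pn = p[n, i]
                    if pn != 0:
                        d = dr[n, i] + pn * ddr
                        if d > dr_max:
                            d = dr_max
                        elif d < dr_floor:
                            d = dr_floor
                        dr[n, i] = d
            s[n] = s_new
            s_out[t, n] = s_new
            mem_out[t, n] = mem
            theta_out[t, n] = theta[n]
            if s_new == 1:
                any_spike = 1
        if competitive:
            if any_spike:
                inh = inh_max
            elif inh > 0:
                inh -= inh_decay
                if inh < 0:
                    inh = 0
        inh_out[t] = inh
    return s_out, mem_out, theta_out, r_out, inh_out


def _as_raster(raster: np.ndarray, n_inputs: int) -> np.ndarray:
    raster = np.ascontiguousarray(raster, dtype=np.uint8)
    if raster.ndim != 2 or raster.shape[1] != n_inputs:
        raise ValueError(f"raster shape {raster.shape} incompatible with {n_inputs} inputs")
    return raster


def run_neuron(state: NeuronState, raster: np.ndarray, params: SkanParams) -> np.ndarray:
    """Advance a single neuron through ``raster``; mutates ``state`` and
    returns the output-bit trace ``(n_steps,)``."""
    u = _as_raster(raster, params.n_inputs)
    p = state.p.reshape(1, -1)
    r = state.r.reshape(1, -1)
    dr = state.dr.reshape(1, -1)
    theta = np.array([state.theta], dtype=np.int64)
    s = np.array([state.s], dtype=np.int64)
    s_out, _ = _step_loop(u, p, r, dr, theta, s, 0,
                          params.w, params.ddr, params.dr_max, params.dr_floor,
                          params.theta_rise, params.theta_fall, 0, 1, False)
    state.theta = int(theta[0])
    state.s = int(s[0])
    return s_out[:, 0]


def run_neuron_traced(state: NeuronState, raster: np.ndarray, params: SkanParams):
    """As :func:`run_neuron` but also returns membrane, threshold and
    per-kernel traces: ``(s, mem, theta, r)``."""
    u = _as_raster(raster, params.n_inputs)
    p = state.p.reshape(1, -1)
    r = state.r.reshape(1, -1)
    dr = state.dr.reshape(1, -1)
    theta = np.array([state.theta], dtype=np.int64)
    s = np.array([state.s], dtype=np.int64)
    s_out, mem_out, theta_out, r_out, _ = _step_loop_traced(
        u, p, r, dr, theta, s, 0,
        params.w, params.ddr, params.dr_max, params.dr_floor,
        params.theta_rise, params.theta_fall, 0, 1, False)
    state.theta = int(theta[0])
    state.s = int(s[0])
    return s_out[:, 0], mem_out[:, 0], theta_out[:, 0], r_out[:, 0, :]


def run_network(state: NetworkState, raster: np.ndarray, params: SkanParams,
                net: NetParams) -> np.ndarray:
    """Advance a competitive layer through ``raster``; mutates ``state`` and
    returns the output traces ``(n_steps, n_neurons)``."""
    u = _as_raster(raster, params.n_inputs)
    if state.r.shape[0] != net.n_neurons:
        raise ValueError("state/NetParams neuron count mismatch")
    s_out, inh = _step_loop(u, state.p, state.r, state.dr, state.theta, state.s,
                            state.inh, params.w, params.ddr, params.dr_max,
                            params.dr_floor, params.theta_rise, params.theta_fall,
                            net.inh_max, net.inh_decay, True)
    state.inh = int(inh)
    return s_out


def run_network_traced(state: NetworkState, raster: np.ndarray,
                       params: SkanParams, net: NetParams):
    """As :func:`run_network` with full traces ``(s, mem, theta, r, inh)``."""
    u = _as_raster(raster, params.n_inputs)
    if state.r.shape[0] != net.n_neurons:
        raise ValueError("state/NetParams neuron count mismatch")
    s_out, mem_out, theta_out, r_out, inh_out = _step_loop_traced(
        u, state.p, state.r, state.dr, state.theta, state.s, state.inh,
        params.w, params.ddr, params.dr_max, params.dr_floor,
        params.theta_rise, params.theta_fall, net.inh_max, net.inh_decay, True)
    state.inh = int(inh_out[-1]) if len(inh_out) else state.inh
    return s_out, mem_out, theta_out, r_out, inh_out
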