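"""Probing a frozen neuron's temporal receptive field.

The receptive field value for a probe pattern is the summed amount by which
the membrane exceeds the threshold over the probe presentation,

    RF = sum_t (sum_i r_i(t) - theta) * s(t),

evaluated with all adaptation disabled: slopes and threshold are held
fixed, only the kernel state machine and the soma comparison run.  For a
two-input neuron the probe pattern is the one-dimensional inter-spike
interval tau, so sweeping tau over ``[-PW, PW]`` yields a response curve
whose argmax is the ISI the neuron expects and whose support is the range
of ISIs it tolerates.

Probes are pure: they operate on copies and a snapshot's hash is unchanged
afterwards.  Freezing is implemented by running the ordinary dynamics with
``ddr = theta_rise = theta_fall = 0`` — the adaptation increments, not the
machinery, are what the probe removes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import engine
from .neuron import NeuronState, init_neuron
from .params import SkanParams
from .seeding import spawn_rng
from .stimulus import NoiseSpec, SpikePattern, build_sequence, make_target_pattern

__all__ = [
    "ReceptiveField",
    "PeakAlignment",
    "probe_response",
    "rf_curve",
    "kernel_peak_alignment",
    "rms_vs_snr",
]


@dataclass(frozen=True)
class ReceptiveField:
    """Response values over the candidate ISI grid ``[-pw, pw]``."""

    taus: np.ndarray      # int64
    values: np.ndarray    # int64, >= 0
    argmax_tau: Optional[int]
    boundaries: tuple    # (smallest tau with RF > 0, largest) or (None, None)

    @property
    def mass(self) -> int:
        return int(self.values.sum())

    @property
    def support(self) -> np.ndarray:
        return self.taus[self.values > 0]


@dataclass(frozen=True)
class PeakAlignment:
    """Per-channel kernel peak times during a frozen probe of the clean
    target, and their spread.  ``rms == 0`` iff all peaks coincide."""

    peak_times: np.ndarray  # int64; -1 marks a channel whose kernel never triggered
    rms: float

    @property
    def included(self) -> np.ndarray:
        return self.peak_times >= 0


def _frozen_params(params: SkanParams) -> SkanParams:
    return dc_replace(params, ddr=0, theta_rise=0, theta_fall=0)


def _probe_steps(state: NeuronState, params: SkanParams,
                 offsets: np.ndarray) -> int:
    # a kernel triggered at offset o with slope d completes by o + 2*ceil(w/d)
    present = offsets >= 0
    ends = offsets[present] + 2 * np.ceil(params.w / state.dr[present]).astype(np.int64)
    return int(ends.max()) + 3 if ends.size else 1


def _frozen_run(state: NeuronState, params: SkanParams, pattern: SpikePattern):
    if pattern.n_channels != params.n_inputs:
        raise ValueError("pattern channel count != neuron inputs")
    if not state.idle:
        raise ValueError("probe requires an idle snapshot (taken between presentations)")
    offsets = pattern.offsets
    steps = _probe_steps(state, params, offsets)
    raster = np.zeros((steps, params.n_inputs), dtype=np.uint8)
    present = np.flatnonzero(offsets >= 0)
    raster[offsets[present], present] = 1
    probe_state = state.copy()
    s, mem, theta, r = engine.run_neuron_traced(probe_state, raster,
                                               _frozen_params(params))
    return s, mem, r, int(state.theta)


def probe_response(state: NeuronState, params: SkanParams,
                   pattern: SpikePattern) -> int:
    """Receptive-field value of one probe pattern; no side effects."""
    s, mem, _, theta = _frozen_run(state, params, pattern)
    return int(((mem - theta) * s).sum())


def _tau_pattern(tau: int, pw: int) -> SpikePattern:
    return SpikePattern(np.array([max(0, -tau), max(0, tau)], dtype=np.int64),
                        max(pw, abs(tau)))


def rf_curve(state: NeuronState, params: SkanParams, pw: int) -> ReceptiveField:
    """Sweep every integer ISI in ``[-pw, pw]`` (two-input neurons only).

    Argmax ties resolve to the smallest ``|tau|``, negative before positive;
    boundaries are the outermost taus with positive response.
    """
    if params.n_inputs != 2:
        raise ValueError("rf_curve is defined for two-input neurons; "
                         "use kernel_peak_alignment for higher dimensions")
    taus = np.arange(-pw, pw + 1, dtype=np.int64)
    values = np.array([probe_response(state, params, _tau_pattern(int(t), pw))
                       for t in taus], dtype=np.int64)
    if np.any(values > 0):
        vmax = values.max()
        order = sorted(range(len(taus)), key=lambda i: (abs(int(taus[i])), int(taus[i])))
        argmax = next(int(taus[i]) for i in order if values[i] == vmax)
        pos = taus[values > 0]
        bounds = (int(pos.min()), int(pos.max()))
    else:
        argmax, bounds = None, (None, None)
    return ReceptiveField(taus, values, argmax, bounds)


def kernel_peak_alignment(state: NeuronState, params: SkanParams,
                          target: SpikePattern) -> PeakAlignment:
    """Present the clean target once with adaptation frozen and measure how
    simultaneously the kernels peak: the RMS of mean-centred first-peak
    times.  Channels whose kernel never triggers (no spike in the target)
    are excluded with a warning."""
    _, _, r, _ = _frozen_run(state, params, target)
    n_ch = params.n_inputs
    peaks = np.full(n_ch, -1, dtype=np.int64)
    for i in range(n_ch):
        col = r[:, i]
        if col.max() > 0:
            peaks[i] = int(np.argmax(col))  # first time the maximum is attained
    included = peaks >= 0
    if not included.all():
        warnings.warn(
            f"channels {np.flatnonzero(~included).tolist()} never triggered "
            "during the probe; excluded from the alignment RMS", stacklevel=2)
    if included.sum() == 0:
        return PeakAlignment(peaks, float("nan"))
    pt = peaks[included].astype(float)
    rms = float(np.sqrt(np.mean((pt - pt.mean()) ** 2)))
    return PeakAlignment(peaks, rms)


def rms_vs_snr(snr_grid: Sequence[tuple] = ((1, 0), (1, 1), (1, 2)),
               n_channels_list: Sequence[int] = (2, 4, 8),
               n_replicates: int = 5,
               n_presentations: int = 1000,
               pw: int = 20,
               T: int = 400,
               seed: int = 0,
               params_for=None) -> pd.DataFrame:
    """Mean kernel-peak-alignment RMS error as a function of spike
    signal-to-noise ratio and input dimension.

    Each grid point ``(a, b)`` keeps target spikes with probability
    ``a / (a + b)`` and adds background spikes at rate ``b / (a + b)`` per
    channel per period, so the total mean spike count per channel per period
    stays at one.  A fresh neuron is trained per replicate on a random
    target, then probed with the clean target.  Returns a tidy frame with
    columns ``snr, dimension, mean_rms, n``.
    """
    if params_for is None:
        params_for = lambda n_ch: SkanParams(n_inputs=n_ch)
    rows = []
    for n_ch in n_channels_list:
        params = params_for(n_ch)
        for a, b in snr_grid:
            p_signal = a / (a + b)
            spec = NoiseSpec(sigma=0.0, p_signal=p_signal, noise_rate=1.0 - p_signal)
            rms_vals = []
            for rep in range(n_replicates):
                rng = spawn_rng(seed, "rms_vs_snr", n_ch, a, b, rep)
                target = make_target_pattern(n_ch, pw, rng)
                stream = build_sequence([target], (1.0,), n_presentations,
                                        spec, T, rng)
                state = init_neuron(params, rng)
                engine.run_neuron(state, stream.raster(), params)
                if not state.idle:  # kernel still in flight at stream end
                    state.p[:] = 0
                    state.r[:] = 0
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rms_vals.append(kernel_peak_alignment(state, params, target).rms)
            rms_arr = np.asarray(rms_vals, dtype=float)
            rows.append({"snr": f"{a}:{b}", "dimension": int(n_ch),
                         "mean_rms": float(np.nanmean(rms_arr)),
                         "n": int(np.sum(~np.isnan(rms_arr)))})
    return pd.DataFrame(rows)
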