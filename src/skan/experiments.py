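"""The characterisation experiment suite.

Four protocols, each a pure function of a configuration and a master seed:

* commonest-pattern selection — a single neuron shown a random mixture of
  two patterns selects the commoner one;
* 1-to-1 classification — a competitive layer with as many neurons as
  patterns converges to a stable bijection, detected as a window of
  consecutive correctly-classified presentations;
* hidden-ISI tracking — a two-input neuron's receptive field follows a
  drifting inter-spike-interval process and its variance;
* pulse-width statistics — the output pulse width as a certainty readout.

"Correct classification" of a presentation means exactly one neuron emits
exactly one output pulse; convergence requires ``window`` consecutive
correct presentations whose induced neuron<->pattern map is consistent and
one-to-one over the pairs observed in the window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import engine
from .neuron import init_neuron
from .network import init_network
from .params import NetParams, SkanParams
from .receptive_field import rf_curve
from .seeding import spawn_rng
from .stimulus import NoiseSpec, build_sequence, drifting_isi_stream, make_target_pattern

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "Verdict",
    "ConvergenceResult",
    "classify_presentation",
    "detect_convergence",
    "run_selection",
    "run_classification",
    "run_tracking",
    "pulse_width_stats",
    "pulse_widths_by_presentation",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared experiment configuration (defaults are the reference study
    conditions: pattern width 20, period 400, window of 20 consecutive
    correct presentations)."""

    n_simulations: int = 100
    n_presentations: int = 300
    n_neurons: int = 1
    n_channels: int = 2
    n_patterns: int = 2
    pw: int = 20
    T: int = 400
    sigma: float = 0.0
    p_signal: float = 1.0
    noise_rate: float = 0.0
    probabilities: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0)
    window: int = 20
    seed: int = 0
    inh_max: int = 100
    inh_decay: int = 1

    def __post_init__(self) -> None:
        for name in ("n_simulations", "n_presentations", "n_neurons",
                     "n_channels", "n_patterns", "pw", "T", "window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def noise(self) -> NoiseSpec:
        return NoiseSpec(sigma=self.sigma, p_signal=self.p_signal,
                         noise_rate=self.noise_rate)

    def skan_params(self) -> SkanParams:
        return SkanParams(n_inputs=self.n_channels)

    def net_params(self) -> NetParams:
        return NetParams(n_neurons=self.n_neurons, inh_max=self.inh_max,
                         inh_decay=self.inh_decay)


@dataclass(frozen=True)
class Verdict:
    """Outcome of one presentation: which neurons initiated pulses, and how
    many rising edges each emitted."""

    edge_counts: tuple

    @property
    def responders(self) -> frozenset:
        return frozenset(i for i, c in enumerate(self.edge_counts) if c > 0)

    @property
    def candidate_correct(self) -> bool:
        """Exactly one neuron responded, with exactly one pulse."""
        return sorted(self.edge_counts, reverse=True)[0] == 1 and \
            sum(c > 0 for c in self.edge_counts) == 1


def _edge_counts(s_out: np.ndarray, n_presentations: int, T: int,
                 s_before: Optional[np.ndarray] = None) -> np.ndarray:
    """Rising edges of each neuron's output, bucketed by presentation
    period.  ``s_out`` is ``(n_presentations * T, n_neurons)``."""
    s = np.asarray(s_out)
    if s.ndim == 1:
        s = s[:, None]
    prev = np.zeros_like(s[:1]) if s_before is None else np.asarray(s_before).reshape(1, -1)
    rising = (s == 1) & (np.vstack([prev, s[:-1]]) == 0)
    return rising.reshape(n_presentations, T, s.shape[1]).sum(axis=1)


def classify_presentation(spike_log: np.ndarray,
                          s_before: Optional[np.ndarray] = None) -> Verdict:
    """Verdict for one logged presentation period ``(T, n_neurons)``.
    ``s_before`` is each neuron's output bit on the step before the period
    (a pulse already in flight at the onset is not a new response)."""
    log = np.asarray(spike_log)
    if log.ndim == 1:
        log = log[:, None]
    counts = _edge_counts(log, 1, log.shape[0], s_before)[0]
    return Verdict(tuple(int(c) for c in counts))


def _detect_on_counts(counts: np.ndarray, labels: np.ndarray,
                      window: int) -> Optional[int]:
    n_pres, n_neurons = counts.shape
    single = (counts > 0).sum(axis=1) == 1
    once = counts.max(axis=1) == 1
    cc = single & once
    resp = np.where(cc, counts.argmax(axis=1), -1)
    run_start = 0
    for i in range(n_pres):
        if resp[i] < 0:
            run_start = i + 1
            continue
        if i - run_start + 1 < window:
            continue
        lo = i - window + 1
        lab2neu: dict = {}
        neu2lab: dict = {}
        ok = True
        for j in range(lo, i + 1):
            lab, neu = int(labels[j]), int(resp[j])
            if lab2neu.setdefault(lab, neu) != neu or neu2lab.setdefault(neu, lab) != lab:
                ok = False
                break
        if ok:
            return i
    return None


def detect_convergence(verdicts: Sequence[Verdict], labels: Sequence[int],
                       window: int = 20) -> Optional[int]:
    """Index of the first presentation ending ``window`` consecutive
    correct presentations with a consistent one-to-one neuron<->pattern
    map, or None.  A single incorrect presentation restarts the run; a
    mapping conflict merely slides the window."""
    if len(verdicts) != len(labels):
        raise ValueError("verdicts and labels must have equal length")
    if not verdicts:
        return None
    counts = np.array([v.edge_counts for v in verdicts], dtype=np.int64)
    return _detect_on_counts(counts, np.asarray(labels), window)


@dataclass(frozen=True)
class ConvergenceResult:
    """Per-simulation first-convergence indices (-1: never converged)."""

    first_idx: np.ndarray
    n_presentations: int
    window: int

    def fraction_converged(self, by_presentation: Optional[int] = None) -> float:
        by = self.n_presentations if by_presentation is None else by_presentation
        return float(np.mean((self.first_idx >= 0) & (self.first_idx < by)))

    def curve(self) -> np.ndarray:
        """Fraction converged as a function of presentations seen
        (non-decreasing, bounded by 1)."""
        out = np.zeros(self.n_presentations)
        idx = self.first_idx[self.first_idx >= 0]
        if idx.size:
            counts = np.bincount(idx, minlength=self.n_presentations)
            out = np.cumsum(counts) / len(self.first_idx)
        return out


def run_selection(config: ExperimentConfig) -> pd.DataFrame:
    """Commonest-pattern selection: a single neuron, two fresh random
    patterns per simulation, pattern ``x`` shown with probability ``P(x)``.

    The verdict uses the evaluation half of the sequence (presentations
    ``n/2 .. n``): outcome ``x`` if the neuron pulsed for at least one
    ``x`` presentation and none of ``y``; symmetrically ``y``; otherwise
    ``both`` / ``neither`` (both are logged — across full sweeps they
    should essentially never occur).  Returns one row per probability.
    """
    params = config.skan_params()
    rows = []
    for ip, p_x in enumerate(config.probabilities):
        tally = {"x": 0, "y": 0, "both": 0, "neither": 0}
        for sim in range(config.n_simulations):
            rng = spawn_rng(config.seed, "selection", ip, sim)
            x = make_target_pattern(config.n_channels, config.pw, rng)
            y = make_target_pattern(config.n_channels, config.pw, rng)
            stream = build_sequence([x, y], (p_x, 1.0 - p_x),
                                    config.n_presentations, config.noise,
                                    config.T, rng)
            state = init_neuron(params, rng)
            s_out = engine.run_neuron(state, stream.raster(), params)
            counts = _edge_counts(s_out, config.n_presentations, config.T)[:, 0]
            half = config.n_presentations // 2
            responded = counts[half:] > 0
            lab = stream.pattern_ids[half:]
            hit_x = bool(np.any(responded & (lab == 0)))
            hit_y = bool(np.any(responded & (lab == 1)))
            outcome = {(True, False): "x", (False, True): "y",
                       (True, True): "both", (False, False): "neither"}[(hit_x, hit_y)]
            if outcome in ("both", "neither"):
                logger.warning("selection P(x)=%.3g sim %d: outcome %r",
                               p_x, sim, outcome)
            tally[outcome] += 1
        n = config.n_simulations
        rows.append({"p_x": float(p_x), "n_sims": n,
                     "frac_x": tally["x"] / n, "frac_y": tally["y"] / n,
                     "frac_both": tally["both"] / n,
                     "frac_neither": tally["neither"] / n})
    return pd.DataFrame(rows)


def run_classification(config: ExperimentConfig,
                       chunk_presentations: int = 100) -> ConvergenceResult:
    """1-to-1 neuron/pattern allocation: ``n_neurons == n_patterns``
    equally likely patterns per simulation; a simulation stops as soon as
    the convergence window is met."""
    if config.n_neurons != config.n_patterns:
        raise ValueError("classification requires n_neurons == n_patterns")
    params = config.skan_params()
    net = config.net_params()
    probs = tuple(1.0 / config.n_patterns for _ in range(config.n_patterns))
    first = np.full(config.n_simulations, -1, dtype=np.int64)
    for sim in range(config.n_simulations):
        rng = spawn_rng(config.seed, "classification", sim)
        patterns = [make_target_pattern(config.n_channels, config.pw, rng)
                    for _ in range(config.n_patterns)]
        stream = build_sequence(patterns, probs, config.n_presentations,
                                config.noise, config.T, rng)
        raster = stream.raster()
        state = init_network(params, net, rng)
        counts = np.zeros((0, config.n_neurons), dtype=np.int64)
        done = 0
        while done < config.n_presentations:
            k = min(chunk_presentations, config.n_presentations - done)
            s_prev = state.s.copy()
            s_out = engine.run_network(
                state, raster[done * config.T:(done + k) * config.T], params, net)
            counts = np.vstack([counts,
                                _edge_counts(s_out, k, config.T, s_prev)])
            done += k
            hit = _detect_on_counts(counts, stream.pattern_ids[:done],
                                    config.window)
            if hit is not None:
                first[sim] = hit
                break
    return ConvergenceResult(first, config.n_presentations, config.window)


def run_tracking(mu_schedule: Sequence[float], sigma_schedule: Sequence[float],
                 pw: int = 20, T: int = 400, seed: int = 0,
                 params: Optional[SkanParams] = None) -> pd.DataFrame:
    """Hidden-ISI tracking: a two-input neuron follows a drifting ISI
    process; after every presentation the frozen receptive field is probed.

    Returns one row per presentation: hidden ``mu``/``sigma``, the observed
    ISI, the receptive-field argmax and boundaries, the threshold, and the
    output pulse width (0 marks a missed presentation).
    """
    if params is None:
        params = SkanParams(n_inputs=2)
    rng = spawn_rng(seed, "tracking")
    stream, isis = drifting_isi_stream(mu_schedule, sigma_schedule, T, rng)
    raster = stream.raster()
    state = init_neuron(params, rng)
    rows = []
    for k in range(stream.n_presentations):
        s_out = engine.run_neuron(state, raster[k * T:(k + 1) * T], params)
        widths, _ = pulse_width_stats(s_out)
        if state.idle:
            rf = rf_curve(state, params, pw)
            argmax, (lo, hi) = rf.argmax_tau, rf.boundaries
        else:  # kernel still in flight at the period boundary: probe undefined
            argmax, lo, hi = None, None, None
        rows.append({
            "presentation": k,
            "mu": float(mu_schedule[k]),
            "sigma": float(sigma_schedule[k]),
            "observed_isi": int(isis[k]),
            "rf_argmax": np.nan if argmax is None else float(argmax),
            "rf_lo": np.nan if lo is None else float(lo),
            "rf_hi": np.nan if hi is None else float(hi),
            "theta": int(state.theta),
            "pulse_width": int(widths[0]) if widths.size else 0,
            "n_pulses": int(widths.size),
        })
    return pd.DataFrame(rows)


def pulse_width_stats(bits: np.ndarray, window: int = 20):
    """Widths of maximal runs of 1s in a binary series, plus a trailing
    running average over ``window`` pulses.  Returns ``(widths, running)``,
    both empty for an all-zero series."""
    b = np.asarray(bits).astype(np.int8).ravel()
    padded = np.concatenate([[0], b, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    widths = (ends - starts).astype(np.int64)
    if widths.size == 0:
        return widths, np.zeros(0)
    running = np.array([widths[max(0, i - window + 1):i + 1].mean()
                        for i in range(widths.size)])
    return widths, running


def pulse_widths_by_presentation(s_out: np.ndarray, n_presentations: int,
                                 T: int) -> np.ndarray:
    """Per-presentation output pulse width: the width of the first pulse
    whose rising edge falls in the period, 0 for a missed presentation."""
    b = np.asarray(s_out).astype(np.int8).ravel()
    if b.size != n_presentations * T:
        raise ValueError("series length must equal n_presentations * T")
    padded = np.concatenate([[0], b, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    out = np.zeros(n_presentations, dtype=np.int64)
    for st, en in zip(starts, ends):
        k = st // T
        if out[k] == 0:
            out[k] = en - st
    return out
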