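"""Seeded spike-stream generators.

Every experiment consumes the same statistical structure: spatio-temporal
target patterns (one spike per channel, offsets uniform on ``[0, PW]``),
presented every ``T`` steps, optionally corrupted by Gaussian temporal
jitter (rounded back to the integer grid), Bernoulli deletion of target
spikes, and background noise spikes.  Background "Poisson" noise is a
per-step Bernoulli process at rate ``noise_rate / T`` per channel — exact
on a discrete grid and indistinguishable from a Poisson process at rates
far below one per step.  With ``p_signal + noise_rate = 1`` the mean total
spike count stays at one spike per channel per period regardless of the
signal-to-noise ratio.

All generators are pure functions of their ``numpy.random.Generator``
argument: same seed, same stream, bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpikePattern",
    "NoiseSpec",
    "StimulusStream",
    "make_target_pattern",
    "jitter_pattern",
    "corrupt_presentation",
    "build_sequence",
    "drifting_isi_stream",
]


@dataclass(frozen=True)
class SpikePattern:
    """One target pattern: per-channel spike offsets relative to onset.

    An offset of ``-1`` marks a channel with no spike (used for partial
    probe targets); the stream generators require full patterns.
    """

    offsets: np.ndarray  # int64, (n_channels,); -1 = no spike on channel
    pw: int              # maximal pattern width in steps

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=np.int64)
        object.__setattr__(self, "offsets", offsets)
        if offsets.ndim != 1 or offsets.size < 1:
            raise ValueError("offsets must be a non-empty 1-D array")
        if self.pw < 0:
            raise ValueError("pw must be non-negative")
        if np.any(offsets < -1):
            raise ValueError("offsets must be >= 0 (or -1 for an absent spike)")

    @property
    def n_channels(self) -> int:
        return int(self.offsets.size)

    @property
    def full(self) -> bool:
        return bool(np.all(self.offsets >= 0))


@dataclass(frozen=True)
class NoiseSpec:
    """Corruption model: jitter std ``sigma`` (steps), per-spike keep
    probability ``p_signal``, expected background spikes per channel per
    period ``noise_rate``."""

    sigma: float = 0.0
    p_signal: float = 1.0
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.p_signal <= 1.0:
            raise ValueError("p_signal must be in [0, 1]")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")

    @property
    def noiseless(self) -> bool:
        return self.sigma == 0 and self.p_signal == 1.0 and self.noise_rate == 0


NOISELESS = NoiseSpec()


@dataclass
class StimulusStream:
    """A generated spike stream plus its ground-truth presentation labels.

    ``events`` is ``(n, 2)`` int64 ``[time, channel]`` sorted by time;
    ``onsets``/``pattern_ids`` record which pattern was presented when (the
    learner is unsupervised — labels exist only for evaluation).
    """

    events: np.ndarray
    onsets: np.ndarray
    pattern_ids: np.ndarray
    T: Optional[int]
    duration: int
    n_channels: int

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.pattern_ids = np.asarray(self.pattern_ids, dtype=np.int64)
        if self.events.size and (self.events[:, 0].min() < 0
                                 or self.events[:, 0].max() >= self.duration):
            raise ValueError("event times must lie in [0, duration)")

    @property
    def n_presentations(self) -> int:
        return int(self.onsets.size)

    @property
    def labels(self) -> np.ndarray:
        return np.stack([self.onsets, self.pattern_ids], axis=1)

    def raster(self) -> np.ndarray:
        """Dense binary raster ``(duration, n_channels)``; coincident events
        collapse (inputs are binary)."""
        out = np.zeros((self.duration, self.n_channels), dtype=np.uint8)
        if self.events.size:
            out[self.events[:, 0], self.events[:, 1]] = 1
        return out


def _sorted_events(times: np.ndarray, channels: np.ndarray) -> np.ndarray:
    order = np.lexsort((channels, times))
    return np.stack([times[order], channels[order]], axis=1).astype(np.int64)


def make_target_pattern(n_channels: int, pw: int,
                        rng: np.random.Generator) -> SpikePattern:
    """Random target: one spike per channel, offsets i.i.d. uniform on the
    integers ``[0, pw]``."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if pw < 0:
        raise ValueError("pw must be >= 0")
    return SpikePattern(rng.integers(0, pw + 1, size=n_channels), pw)


def jitter_pattern(pattern: SpikePattern, sigma: float,
                   rng: np.random.Generator,
                   t_max: Optional[int] = None) -> SpikePattern:
    """Perturb each offset by a normal deviate of std ``sigma``, rounded to
    the grid and clamped to ``[0, t_max - 1]`` (lower bound only when
    ``t_max`` is None).  ``sigma = 0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return pattern
    offs = np.rint(pattern.offsets + rng.normal(0.0, sigma, pattern.n_channels))
    offs = np.maximum(offs, 0)
    if t_max is not None:
        offs = np.minimum(offs, t_max - 1)
    offs = offs.astype(np.int64)
    return SpikePattern(offs, max(pattern.pw, int(offs.max(initial=0))))


def corrupt_presentation(pattern: SpikePattern, spec: NoiseSpec, T: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Events for one presentation period ``[0, T)``: each target spike kept
    with probability ``p_signal``; independently each channel receives
    background spikes from a per-step Bernoulli process with total expected
    count ``noise_rate``.  Returns ``(n, 2)`` int64 sorted by time.

    Jitter is not applied here (see :func:`build_sequence`): deletion and
    background noise are the signal-to-noise axis, jitter the temporal one.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not pattern.full:
        raise ValueError("stream generation requires one spike per channel")
    n_ch = pattern.n_channels
    keep = rng.random(n_ch) < spec.p_signal
    times = [np.minimum(pattern.offsets[keep], T - 1)]
    chans = [np.flatnonzero(keep)]
    if spec.noise_rate > 0:
        p_step = spec.noise_rate / T
        for ch in range(n_ch):
            k = rng.binomial(T, p_step)
            if k:
                times.append(rng.choice(T, size=k, replace=False).astype(np.int64))
                chans.append(np.full(k, ch, dtype=np.int64))
    t = np.concatenate(times)
    c = np.concatenate(chans)
    return _sorted_events(t, c)


def build_sequence(patterns: Sequence[SpikePattern], probabilities: Sequence[float],
                   n_presentations: int, spec: NoiseSpec, T: int,
                   rng: np.random.Generator) -> StimulusStream:
    """Random presentation sequence: an i.i.d. pattern choice every ``T``
    steps, each presentation jittered, thinned and overlaid with background
    noise per ``spec``.  Presentations abut, so the stream lasts
    ``n_presentations * T`` steps."""
    patterns = list(patterns)
    if not patterns:
        raise ValueError("need at least one pattern")
    n_ch = patterns[0].n_channels
    if any(not p.full for p in patterns):
        raise ValueError("stream generation requires one spike per channel")
    pw = max(p.pw for p in patterns)
    if any(p.n_channels != n_ch for p in patterns):
        raise ValueError("all patterns must share a channel count")
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape != (len(patterns),) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("probabilities must be non-negative and sum to 1")
    if T <= pw:
        raise ValueError(f"T={T} must exceed the pattern width {pw}: presentations would overlap")
    if n_presentations < 1:
        raise ValueError("n_presentations must be >= 1")

    duration = n_presentations * T
    choices = rng.choice(len(patterns), size=n_presentations, p=probs)
    onsets = np.arange(n_presentations, dtype=np.int64) * T

    base = np.stack([p.offsets for p in patterns])          # (k, n_ch)
    offs = base[choices].astype(float)                      # (n_pres, n_ch)
    if spec.sigma > 0:
        offs = np.rint(offs + rng.normal(0.0, spec.sigma, offs.shape))
        offs = np.clip(offs, 0, T - 1)
    offs = offs.astype(np.int64)

    keep = (rng.random(offs.shape) < spec.p_signal
            if spec.p_signal < 1.0 else np.ones(offs.shape, dtype=bool))
    times = (onsets[:, None] + offs)[keep]
    chans = np.broadcast_to(np.arange(n_ch), offs.shape)[keep]

    if spec.noise_rate > 0:
        # periods abut, so per-period windows tile the whole stream
        noise = rng.random((duration, n_ch)) < spec.noise_rate / T
        nt, nc = np.nonzero(noise)
        times = np.concatenate([times, nt.astype(np.int64)])
        chans = np.concatenate([chans, nc.astype(np.int64)])

    return StimulusStream(_sorted_events(times, chans), onsets,
                          choices.astype(np.int64), T, duration, n_ch)


def drifting_isi_stream(mu_schedule: Sequence[float], sigma_schedule: Sequence[float],
                        T: int, rng: np.random.Generator):
    """Two-channel stream from a hidden inter-spike-interval process.

    For presentation ``k`` the observed ISI is
    ``round(mu_k + sigma_k * normal())``; channel 0 spikes at onset and
    channel 1 at ``onset + ISI`` (a negative ISI makes channel 1 lead, both
    spikes shifted so the earlier one sits at the onset).  Returns
    ``(stream, observed_isis)``.
    """
    mu = np.asarray(mu_schedule, dtype=float)
    sigma = np.asarray(sigma_schedule, dtype=float)
    if mu.shape != sigma.shape or mu.ndim != 1 or mu.size < 1:
        raise ValueError("schedules must be equal-length 1-D sequences")
    if np.any(sigma < 0):
        raise ValueError("sigma schedule must be non-negative")
    if np.any(np.abs(mu) + 4 * sigma >= T):
        raise ValueError("|mu| + 4*sigma must stay below T")
    n_pres = mu.size
    isis = np.rint(mu + rng.normal(0.0, 1.0, n_pres) * sigma).astype(np.int64)
    isis = np.clip(isis, -(T - 1), T - 1)  # tail deviates stay inside the period
    onsets = np.arange(n_pres, dtype=np.int64) * T
    t0 = onsets + np.maximum(0, -isis)
    t1 = onsets + np.maximum(0, isis)
    times = np.concatenate([t0, t1])
    chans = np.concatenate([np.zeros(n_pres, dtype=np.int64),
                            np.ones(n_pres, dtype=np.int64)])
    stream = StimulusStream(_sorted_events(times, chans), onsets,
                            np.zeros(n_pres, dtype=np.int64), T, n_pres * T, 2)
    return stream, isis
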