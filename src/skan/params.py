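"""Parameter containers and static validation.

All model quantities are non-negative integers on a discrete time grid of
unit ``dt``: potentials in arbitrary integer "potential units", times and
widths in time steps.  Integer closure is a hard contract — two runs with
the same seed and configuration are bit-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

#: default threshold rise per spiking step, per input channel
THETA_RISE_PER_INPUT = 40
#: default threshold fall on membrane return to zero, per input channel
THETA_FALL_PER_INPUT = 100


def _check_nonneg_int(name: str, value) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return int(value)


@dataclass(frozen=True)
class SkanParams:
    """Parameters of a single kernel-adapting neuron.

    Defaults follow the reference parameter set used throughout the
    characterisation experiments: kernel peak height ``w`` = 10000, slope
    increment ``ddr`` = 1, slope saturation ``dr_max`` = 400, initial slopes
    drawn as ``round(100 * (1 + U[0, 1)))`` and threshold steps scaled by
    the number of input channels (``40 * n`` rise, ``100 * n`` fall).
    """

    n_inputs: int
    w: int = 10_000
    ddr: int = 1
    dr_max: int = 400
    dr_floor: int = 1
    dr_init_lo: int = 100
    dr_init_hi: int = 200
    theta_rise: Optional[int] = None  # default: 40 * n_inputs
    theta_fall: Optional[int] = None  # default: 100 * n_inputs
    theta_init: int = 0

    def __post_init__(self) -> None:
        if self.theta_rise is None:
            object.__setattr__(self, "theta_rise", THETA_RISE_PER_INPUT * self.n_inputs)
        if self.theta_fall is None:
            object.__setattr__(self, "theta_fall", THETA_FALL_PER_INPUT * self.n_inputs)
        for name in (
            "n_inputs", "w", "ddr", "dr_max", "dr_floor", "dr_init_lo",
            "dr_init_hi", "theta_rise", "theta_fall", "theta_init",
        ):
            object.__setattr__(self, name, _check_nonneg_int(name, getattr(self, name)))
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.dr_floor < 1:
            raise ValueError("dr_floor must be >= 1 (a zero slope would freeze a kernel mid-ramp)")
        if not (self.dr_init_lo <= self.dr_init_hi <= self.dr_max <= self.w):
            raise ValueError(
                "require dr_init_lo <= dr_init_hi <= dr_max <= w, got "
                f"{self.dr_init_lo} <= {self.dr_init_hi} <= {self.dr_max} <= {self.w}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NetParams:
    """Parameters of the competitive layer's shared inhibitory counter.

    ``inh_max`` is the value the counter reloads to whenever any neuron is
    spiking; it decays by ``inh_decay`` per quiet step.  Rule of thumb:
    ``inh_max / inh_decay >= min(initial slope)`` so that inhibition outlasts
    any rival kernel still in flight.
    """

    n_neurons: int
    inh_max: int = 100
    inh_decay: int = 1

    def __post_init__(self) -> None:
        for name in ("n_neurons", "inh_max", "inh_decay"):
            object.__setattr__(self, name, _check_nonneg_int(name, getattr(self, name)))
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.inh_decay < 1:
            raise ValueError("inh_decay must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ParamIssue:
    severity: str  # "violation" | "warning"
    message: str


def validate_params(
    params: SkanParams,
    pw: int,
    net: Optional[NetParams] = None,
) -> list[ParamIssue]:
    """Check a parameter set against a target pattern width ``pw``.

    The slope saturation must satisfy ``dr_max < w / pw`` (strict): otherwise
    the kernel triggered by a pattern's first spike can complete before its
    last spike arrives, and the kernels can no longer converge under a common
    output pulse.  A degenerate ``pw`` of zero makes the bound vacuous.

    With network parameters supplied, warns when the inhibitory hold-off
    ``inh_max / inh_decay`` is shorter than the smallest initial slope
    (the decorrelation rule of thumb).
    """
    _check_nonneg_int("pw", pw)
    issues: list[ParamIssue] = []
    if pw > 0 and params.dr_max * pw >= params.w:
        issues.append(ParamIssue(
            "violation",
            f"dr_max={params.dr_max} must be < w/PW = {params.w}/{pw} "
            f"= {params.w / pw:g}: kernels complete before the pattern does",
        ))
    if net is not None and net.inh_max // net.inh_decay < params.dr_init_lo:
        issues.append(ParamIssue(
            "warning",
            f"inh_max/inh_decay = {net.inh_max}/{net.inh_decay} is below the smallest "
            f"initial slope {params.dr_init_lo}; inhibition may not outlast rival kernels",
        ))
    return issues


def violations(issues: list[ParamIssue]) -> list[ParamIssue]:
    return [i for i in issues if i.severity == "violation"]
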