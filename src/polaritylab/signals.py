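"""Spatial signal profiles on the discretised membrane and stimulation protocols.

The chemoattractant gradient is a truncated Gaussian laid around the
periodic membrane: on a window of N bins the profile is
``s(n) = s0 * exp(-0.5 (n / w)^2)`` with ``w = (N - 1) / (2 alpha)`` and
``n`` the (circular) bin offset from the bin nearest the requested centre
angle. ``alpha`` controls the spread: larger ``alpha``, narrower gradient.
The steepness of a gradient across the cell is summarised by the stimulus
difference ``sd = (s_{theta=pi} - s_{theta=0}) * 100`` (in percent), the
quantity dose-response scans are parameterised by.

Time dependence is expressed as protocols: lists of epochs during which a
gradient (plus an optional uniform offset) is switched on. Signals are
piecewise constant in time, which lets integrators restart cleanly at epoch
boundaries. Step protocols for the two-bin projection carry ``(sL, sR)``
amplitude pairs instead of spatial profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "GradientSpec",
    "GradientEpoch",
    "ProtocolSpec",
    "StepEpoch",
    "StepProtocol",
    "gaussian_profile",
    "signal_at",
    "stimulus_difference",
    "amplitude_for_sd",
    "sd_for_amplitude",
    "fwhm_bins",
    "single_transient",
    "sustained",
    "reversal",
    "simultaneous",
    "consecutive",
    "offset_gradient",
    "step_protocol",
]

DEFAULT_S0 = 0.02
DEFAULT_ALPHA = 2.0


@dataclass(frozen=True)
class GradientSpec:
    """A truncated-Gaussian gradient on an N-bin membrane.

    ``center`` is a continuous angle (radians) snapped to the nearest bin;
    the grid is coarse (N = 20 by default) and all analyses are bin-wise.
    """

    s0: float = DEFAULT_S0
    alpha: float = DEFAULT_ALPHA
    center: float = math.pi
    N: int = 20

    def __post_init__(self):
        if self.s0 < 0:
            raise DomainError(f"s0 must be >= 0, got {self.s0}")
        if not self.alpha > 0:
            raise DomainError(f"alpha must be > 0, got {self.alpha}")
        if self.N < 3:
            raise DomainError(f"N must be >= 3, got {self.N}")

    @property
    def w(self) -> float:
        """Gaussian width parameter ``(N - 1) / (2 alpha)`` in bins."""
        return (self.N - 1) / (2.0 * self.alpha)

    @property
    def center_bin(self) -> int:
        return int(round(self.center / (2.0 * math.pi / self.N))) % self.N


def gaussian_profile(spec: GradientSpec) -> np.ndarray:
    """Evaluate the gradient on the N bins of the membrane.

    Uses the circular bin distance to the centre bin, so the profile is
    symmetric about the centre on the ring, attains its maximum ``s0``
    exactly at the bin nearest ``center``, and has no seam discontinuity.
    """
    i = np.arange(spec.N)
    d = np.abs(i - spec.center_bin)
    d = np.minimum(d, spec.N - d)
    return spec.s0 * np.exp(-0.5 * (d / spec.w) ** 2)


def fwhm_bins(spec: GradientSpec) -> float:
    """Full width at half maximum of the profile, in bins (``2 w sqrt(2 ln 2)``)."""
    return 2.0 * spec.w * math.sqrt(2.0 * math.log(2.0))


def stimulus_difference(profile: np.ndarray) -> float:
    """``sd = (s_{theta=pi} - s_{theta=0}) * 100`` for a profile on N bins.

    Bin 0 sits at theta = 0; for even N bin N/2 sits exactly at theta = pi,
    otherwise the nearest bin is used.
    """
    N = len(profile)
    return float((profile[int(round(N / 2)) % N] - profile[0]) * 100.0)


def sd_for_amplitude(s0: float, alpha: float = DEFAULT_ALPHA, N: int = 20) -> float:
    """Stimulus difference produced by a gradient of amplitude ``s0`` centred at pi."""
    return stimulus_difference(gaussian_profile(GradientSpec(s0=s0, alpha=alpha, N=N)))


def amplitude_for_sd(sd: float, alpha: float = DEFAULT_ALPHA, N: int = 20) -> float:
    """Invert ``sd_for_amplitude``: the ``s0`` giving stimulus difference ``sd`` (%)."""
    unit = sd_for_amplitude(1.0, alpha=alpha, N=N)
    return sd / unit


@dataclass(frozen=True)
class GradientEpoch:
    gradient: GradientSpec
    t_on: float
    t_off: float
    offset: float = 0.0

    def __post_init__(self):
        if not self.t_on < self.t_off:
            raise ConfigurationError(f"epoch needs t_on < t_off, got [{self.t_on}, {self.t_off}]")
        if self.offset < 0:
            raise DomainError("offset must be >= 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """A stimulation protocol: gradient epochs on an N-bin membrane."""

    kind: str
    epochs: Tuple[GradientEpoch, ...]
    N: int = 20

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))
        for ep in self.epochs:
            if ep.gradient.N != self.N:
                raise ConfigurationError("gradient N differs from protocol N")
        if self.kind != "simultaneous":
            spans = sorted((ep.t_on, ep.t_off) for ep in self.epochs)
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ConfigurationError("overlapping epochs are only allowed for kind='simultaneous'")

    def boundaries(self, t_span: Tuple[float, float]) -> np.ndarray:
        """Sorted switch times inside ``t_span`` (for integrator restarts)."""
        ts = {t_span[0], t_span[1]}
        for ep in self.epochs:
            for t in (ep.t_on, ep.t_off):
                if t_span[0] < t < t_span[1]:
                    ts.add(t)
        return np.array(sorted(ts))

    def signal_at(self, t: float) -> np.ndarray:
        return signal_at(self, t)


def signal_at(protocol: ProtocolSpec, t: float) -> np.ndarray:
    """Assemble the signal vector at time ``t`` (zero outside every epoch).

    Active gradients are summed (relevant for simultaneous protocols) and
    uniform offsets are added on top.
    """
    out = np.zeros(protocol.N)
    for ep in protocol.epochs:
        if ep.t_on <= t < ep.t_off:
            out += gaussian_profile(ep.gradient) + ep.offset
    return out


# ---------------------------------------------------------------------------
# protocol constructors


def single_transient(s0=DEFAULT_S0, t_on=100.0, t_off=200.0, alpha=DEFAULT_ALPHA,
                     center=math.pi, N=20, offset=0.0) -> ProtocolSpec:
    """One gradient pulse; the workhorse for transient-response kymographs."""
    ep = GradientEpoch(GradientSpec(s0, alpha, center, N), t_on, t_off, offset)
    return ProtocolSpec("single_transient", (ep,), N)


def sustained(s0=DEFAULT_S0, t_on=0.0, t_off=1e9, alpha=DEFAULT_ALPHA,
              center=math.pi, N=20, offset=0.0) -> ProtocolSpec:
    """A gradient held on (dose-response and polarization-time experiments)."""
    ep = GradientEpoch(GradientSpec(s0, alpha, center, N), t_on, t_off, offset)
    return ProtocolSpec("single_transient", (ep,), N)


def reversal(s0_initial, s0_reversed, t_on=0.0, t_reverse=600.0, t_off=1e9,
             alpha=DEFAULT_ALPHA, center=math.pi, N=20) -> ProtocolSpec:
    """Gradient at ``center`` until ``t_reverse``, then at ``center + pi``."""
    first = GradientEpoch(GradientSpec(s0_initial, alpha, center, N), t_on, t_reverse)
    second = GradientEpoch(GradientSpec(s0_reversed, alpha, center + math.pi, N), t_reverse, t_off)
    return ProtocolSpec("reversal", (first, second), N)


def simultaneous(s0_strong, s0_weak, t_on=0.0, t_off=1e9, alpha=DEFAULT_ALPHA,
                 center_strong=math.pi, N=20) -> ProtocolSpec:
    """Two opposed gradients active at once; the stronger one at ``center_strong``."""
    a = GradientEpoch(GradientSpec(s0_strong, alpha, center_strong, N), t_on, t_off)
    b = GradientEpoch(GradientSpec(s0_weak, alpha, center_strong + math.pi, N), t_on, t_off)
    return ProtocolSpec("simultaneous", (a, b), N)


def consecutive(s0=DEFAULT_S0, n_pulses=3, t_first=100.0, duration=100.0, gap=100.0,
                alpha=DEFAULT_ALPHA, center=math.pi, N=20) -> ProtocolSpec:
    """Repeated transient pulses from the same direction (signal integration)."""
    eps = []
    t = t_first
    for _ in range(n_pulses):
        eps.append(GradientEpoch(GradientSpec(s0, alpha, center, N), t, t + duration))
        t += duration + gap
    return ProtocolSpec("consecutive", tuple(eps), N)


def offset_gradient(s0, offset, t_on=0.0, t_off=1e9, alpha=DEFAULT_ALPHA,
                    center=math.pi, N=20) -> ProtocolSpec:
    """A gradient riding on a uniform baseline (offset-response experiments)."""
    ep = GradientEpoch(GradientSpec(s0, alpha, center, N), t_on, t_off, offset)
    return ProtocolSpec("offset", (ep,), N)


# ---------------------------------------------------------------------------
# two-bin step protocols


@dataclass(frozen=True)
class StepEpoch:
    sL: float
    sR: float
    duration: float

    def __post_init__(self):
        if self.sL < 0 or self.sR < 0:
            raise DomainError("step amplitudes must be >= 0")
        if not self.duration > 0:
            raise ConfigurationError("epoch duration must be > 0")


@dataclass(frozen=True)
class StepProtocol:
    """Step-like ``(sL, sR)`` signal for the two-bin projection; ``sR`` is
    conventionally 0 (the signal addresses the left bin)."""

    epochs: Tuple[StepEpoch, ...]
    kind: str = "step_two_bin"

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))

    @property
    def total_time(self) -> float:
        return sum(ep.duration for ep in self.epochs)

    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([ep.duration for ep in self.epochs])])

    def signal_at(self, t: float) -> Tuple[float, float]:
        if t < 0:
            return (0.0, 0.0)
        acc = 0.0
        for ep in self.epochs:
            if t < acc + ep.duration:
                return (ep.sL, ep.sR)
            acc += ep.duration
        return (0.0, 0.0)


def step_protocol(steps: Sequence[Tuple[float, float, float]]) -> StepProtocol:
    """Build a :class:`StepProtocol` from ``(sL, sR, duration)`` triples."""
    return StepProtocol(tuple(StepEpoch(sL, sR, d) for sL, sR, d in steps))
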