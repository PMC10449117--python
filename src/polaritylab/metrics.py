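"""Standardized polarization quantifications for model comparison.

All quantities are computed from kymographs:

* polarization ratio ``u(theta=pi) / u(theta=0)`` (front over back, with the
  gradient maximum conventionally at pi);
* stimulus difference ``sd = (s_pi - s_0) * 100`` in percent, the
  dose-response abscissa;
* polarization time: the membrane-front trace is min-max normalised and the
  time of first entry into a +/- 1e-2 band around the mean of the last 100
  reported samples is taken ("plateau entry"); the plateau is only accepted
  when the variance of those samples is below (1e-2)^2;
* activation threshold ``sd_thresh``: the sd at which the mean plateau
  polarization ratio reaches 50% of its maximum over the scan (linear
  interpolation). Two related quantities are exposed: the interpolated
  crossing (``sd_thresh``) and the smallest scanned sd that actually
  achieves polarization (``sd_pol``, used as the stimulation amplitude for
  time measurements and for phase 1 of reversal protocols, where a
  polarized plateau must first be established);
* re-polarization / resolving time: plateau entry of the u trace at the
  new front, gated by a success check on the spatial contrast -- "stable
  reversed polarity" is a property of the front/back ratio, and without
  the gate a non-reversing model's settling transient would be mistaken
  for a re-polarization;
* signal integration index ``(T_{u>1/2} - T_signal) / t_max``;
* spurious activation: the fraction of random perturbations of the
  homogeneous state that polarize without any signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import models as _models
from . import rd_sim as _rd
from . import signals as _signals
from .errors import DomainError
from .models import ModelSpec
from .rd_sim import DomainSpec, Kymograph

__all__ = [
    "PolarizationMetrics",
    "SdThreshold",
    "polarization_ratio",
    "polarization_time",
    "estimate_sd_thresh",
    "repolarization_metrics",
    "resolving_metrics",
    "signal_integration_index",
    "spurious_activation",
    "MANUAL_SD_THRESH",
    "ACTIVATION_CUTOFF",
    "NOT_REACHED_CAP_S",
]

PLATEAU_WINDOW = 100         # reported samples defining the plateau
PLATEAU_BAND = 1e-2          # entry band around the plateau mean (normalised)
ACTIVATION_CUTOFF = 1.5      # ratio above which a run counts as polarized
NOT_REACHED_CAP_S = 1000.0   # observation cap for "did not reach" flags
MANUAL_SD_THRESH = {"legi": 0.5, "turing": 0.1}  # spurious-activation-prone models
EPS_RATIO = 1e-12


@dataclass
class PolarizationMetrics:
    """Scalar quantifications of one stimulation experiment."""

    model: str
    sd: float = math.nan
    polarization_ratio: float = math.nan
    polarization_time: float = math.nan
    polarization_reached: bool = False
    sd_thresh: float = math.nan
    repolarization_time: float = math.nan
    repolarization_reached: bool = False
    amplification: float = math.nan
    resolving_time: float = math.nan
    resolving_reached: bool = False
    integration_index: float = math.nan
    spurious_rate: float = math.nan


def _normalise(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-15:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def polarization_ratio(kym: Kymograph, t: Optional[float] = None) -> float:
    """u at the bin nearest pi over u at the bin nearest 0.

    At time ``t`` if given, otherwise averaged over the last
    ``PLATEAU_WINDOW`` reported samples. A denominator below the floor
    yields ``inf`` (flagged infinite ratio).
    """
    front = kym.trace_at(math.pi)
    back = kym.trace_at(0.0)
    if t is None:
        num, den = front[-PLATEAU_WINDOW:].mean(), back[-PLATEAU_WINDOW:].mean()
    else:
        i = int(np.argmin(np.abs(kym.times - t)))
        num, den = front[i], back[i]
    if den < EPS_RATIO:
        return math.inf
    return float(num / den)


def _entry_time(trace: np.ndarray, times: np.ndarray) -> Tuple[float, bool]:
    """Plateau-entry time of a (raw) trace; returns (time, plateau_valid)."""
    xn = _normalise(trace)
    tail = xn[-PLATEAU_WINDOW:]
    m = float(tail.mean())
    valid = float(tail.var()) < PLATEAU_BAND ** 2
    idx = np.nonzero(np.abs(xn - m) <= PLATEAU_BAND)[0]
    if len(idx) == 0:
        return math.nan, False
    return float(times[idx[0]]), valid


def polarization_time(kym: Kymograph, epoch: Optional[Tuple[float, float]] = None,
                      angle: float = math.pi) -> Tuple[float, bool]:
    """Time to stable polarization within a stimulation epoch.

    Returns ``(time_since_epoch_start, reached)``; ``reached`` is False
    when the plateau-stability check fails (no stable plateau within the
    epoch).

    Raises
    ------
    DomainError when the epoch holds fewer than ``PLATEAU_WINDOW`` samples.
    """
    t0, t1 = epoch if epoch is not None else (kym.times[0], kym.times[-1])
    sel = (kym.times >= t0) & (kym.times <= t1)
    if sel.sum() < PLATEAU_WINDOW:
        raise DomainError(f"epoch [{t0}, {t1}] holds fewer than {PLATEAU_WINDOW} reported samples")
    trace = kym.trace_at(angle)[sel]
    times = kym.times[sel] - t0
    t_entry, valid = _entry_time(trace, times)
    return t_entry, valid


@dataclass
class SdThreshold:
    """Result of a dose-response scan."""

    model: str
    sd_grid: np.ndarray
    ratios: np.ndarray           # mean plateau ratio per sd (over repeats)
    sd_thresh: float             # 50%-of-max crossing (interpolated); nan if never reached
    sd_pol: float                # smallest scanned sd achieving polarization
    estimable: bool
    manual_override: Optional[float] = None

    @property
    def effective(self) -> float:
        """The threshold used downstream (manual override when set)."""
        return self.manual_override if self.manual_override is not None else self.sd_thresh

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sd": self.sd_grid, "ratio": self.ratios})


def dose_response(model: ModelSpec, sd_grid: Sequence[float],
                  domain: Optional[DomainSpec] = None, T: float = NOT_REACHED_CAP_S,
                  repeats: int = 1, sigma: float = 0.0, seed: int = 0,
                  alpha: float = _signals.DEFAULT_ALPHA) -> np.ndarray:
    """Mean plateau polarization ratio for each stimulus difference.

    ``repeats > 1`` runs seeded stochastic simulations of intensity
    ``sigma`` and averages the plateau ratios; the default is a single
    deterministic run per sd.
    """
    domain = domain or DomainSpec()
    out = np.empty(len(sd_grid))
    for i, sd in enumerate(sd_grid):
        s0 = _signals.amplitude_for_sd(float(sd), alpha=alpha, N=domain.N)
        prot = _signals.sustained(s0=s0, t_off=T, alpha=alpha, N=domain.N)
        vals = []
        for rep in range(repeats):
            if repeats == 1 and sigma == 0.0:
                kym = _rd.simulate(model, domain, prot, t_span=(0.0, T))
            else:
                kym = _rd.simulate_sde(model, domain, prot, sigma=sigma,
                                       seed=seed * 1000 + rep, t_span=(0.0, T))
            vals.append(polarization_ratio(kym))
        out[i] = float(np.mean(vals))
    return out


def threshold_from_curve(sd_grid: np.ndarray, ratios: np.ndarray) -> Tuple[float, float, bool]:
    """50%-of-max interpolation on a dose-response curve.

    Returns ``(sd_thresh, sd_pol, estimable)``: the linearly interpolated
    sd at half the maximum ratio, the smallest grid sd at or above it, and
    whether the curve carries a threshold at all (a flat curve at ratio 1
    does not).
    """
    sd_grid = np.asarray(sd_grid, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    half = 0.5 * float(ratios.max())
    above = np.nonzero(ratios >= half)[0]
    if len(above) == 0 or ratios.max() <= 1.0 + 1e-9:
        return math.nan, math.nan, False
    i = int(above[0])
    sd_pol = float(sd_grid[i])
    if i == 0:
        th = float(sd_grid[0])
    else:
        x0, x1 = sd_grid[i - 1], sd_grid[i]
        y0, y1 = ratios[i - 1], ratios[i]
        th = float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
    return th, sd_pol, True


def estimate_sd_thresh(model: ModelSpec, sd_grid: Sequence[float],
                       domain: Optional[DomainSpec] = None, T: float = NOT_REACHED_CAP_S,
                       repeats: int = 1, sigma: float = 0.0, seed: int = 0,
                       apply_manual_override: bool = True) -> SdThreshold:
    """Activation threshold from the 50%-of-max dose-response procedure.

    For the LEGI and Turing-like models the dose-response curve has no
    threshold structure (they respond to arbitrarily small gradients), so
    their thresholds are set manually (0.5% and 0.1%) as in the source
    protocol; disable with ``apply_manual_override=False``.
    """
    sd_grid = np.asarray(list(sd_grid), dtype=float)
    ratios = dose_response(model, sd_grid, domain, T, repeats, sigma, seed)
    th, sd_pol, ok = threshold_from_curve(sd_grid, ratios)
    manual = MANUAL_SD_THRESH.get(model.name) if apply_manual_override else None
    return SdThreshold(model=model.name, sd_grid=sd_grid, ratios=ratios,
                       sd_thresh=th, sd_pol=sd_pol, estimable=ok, manual_override=manual)


def _ratio_trace(kym: Kymograph, front_angle: float) -> np.ndarray:
    front = kym.trace_at(front_angle)
    back = kym.trace_at(front_angle + math.pi)
    return front / np.maximum(back, EPS_RATIO)


def repolarization_metrics(kym: Kymograph, t_reverse: float,
                           new_front_angle: float = 0.0,
                           cap: float = NOT_REACHED_CAP_S) -> Tuple[float, bool, float]:
    """(re-polarization time, reached, amplification) after a gradient reversal.

    The re-polarization time is the plateau-entry time of the u trace at
    the new front within the reversal epoch (the same rule as the
    polarization time). The amplification is the plateau of the ratio
    ``u(new front) / u(old front)``. Re-polarization counts as reached
    only when the plateau is stable, actually reversed (amplification
    ``>= ACTIVATION_CUTOFF``) and entered within ``cap`` seconds;
    otherwise the time is reported as the cap with ``reached=False``.
    """
    sel = kym.times >= t_reverse
    if sel.sum() < PLATEAU_WINDOW:
        raise DomainError("reversal epoch holds fewer samples than the plateau window")
    times = kym.times[sel] - t_reverse
    trace = kym.trace_at(new_front_angle)[sel]
    r = _ratio_trace(kym, new_front_angle)[sel]
    amp = float(r[-PLATEAU_WINDOW:].mean())
    t_entry, valid = _entry_time(trace, times)
    reached = valid and amp >= ACTIVATION_CUTOFF and not math.isnan(t_entry) and t_entry <= cap
    return (t_entry if reached else cap), reached, amp


def resolving_metrics(kym: Kymograph, t_on: float = 0.0,
                      stronger_angle: float = math.pi,
                      cap: float = NOT_REACHED_CAP_S) -> Tuple[float, bool, float]:
    """(resolving time, resolved, amplification) under simultaneous stimuli.

    Two opposed gradients are active at once; a unique polarization axis is
    established when the ratio trace toward the stronger signal settles on
    a plateau above 1. With a single gradient this degenerates to the
    polarization time.
    """
    sel = kym.times >= t_on
    if sel.sum() < PLATEAU_WINDOW:
        raise DomainError("resolving epoch holds fewer samples than the plateau window")
    times = kym.times[sel] - t_on
    trace = kym.trace_at(stronger_angle)[sel]
    r = _ratio_trace(kym, stronger_angle)[sel]
    amp = float(r[-PLATEAU_WINDOW:].mean())
    t_entry, valid = _entry_time(trace, times)
    resolved = valid and amp > 1.0 and not math.isnan(t_entry) and t_entry <= cap
    return (t_entry if resolved else cap), resolved, amp


def signal_integration_index(u_trace: np.ndarray, signal_on: np.ndarray,
                             times: np.ndarray, t_max: Optional[float] = None,
                             threshold: float = 0.5) -> float:
    """``([T_{u > threshold}] - [T_signal]) / t_max``.

    ``u_trace`` is the (normalised) membrane-front trace and ``signal_on``
    a boolean (or signal-amplitude) array on the same time grid. Durations
    are accumulated per reporting interval, so the index is additive over
    disjoint supra-threshold intervals. Positive values measure memory
    beyond the stimulation; the index of a response confined to the signal
    epochs is 0, and a response that never crosses the threshold scores
    ``-T_signal / t_max``.
    """
    times = np.asarray(times, dtype=float)
    if t_max is None:
        t_max = float(times[-1] - times[0])
    if t_max <= 0:
        raise DomainError("t_max must be positive")
    dt = np.gradient(times)
    above = np.asarray(u_trace) > threshold
    on = np.asarray(signal_on).astype(bool)
    return float((dt[above].sum() - dt[on].sum()) / t_max)


def spurious_activation(model: ModelSpec, xi_per: float, n_reps: int = 10,
                        seed: int = 0, domain: Optional[DomainSpec] = None,
                        T: float = 600.0, cutoff: float = ACTIVATION_CUTOFF) -> float:
    """Fraction of random perturbations of the HSS that polarize at zero signal.

    Each repetition perturbs every bin as ``(u_s + xi r, v_s - xi r)`` with
    ``r ~ U[0, 1]`` drawn per bin (for LEGI the perturbation is also applied
    to ``w_s``), clips at zero and runs a deterministic zero-signal
    simulation. Since the perturbation has no preferred direction, a run
    counts as polarized when the plateau max/min contrast across bins
    exceeds ``cutoff``.
    """
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    if xi_per < 0:
        raise DomainError("xi_per must be >= 0")
    domain = domain or DomainSpec()
    rng = np.random.default_rng(seed)
    hss = _models.hss_state(model)
    n_pol = 0
    for _ in range(n_reps):
        y0 = np.repeat(hss[:, None], domain.N, axis=1)
        r = rng.uniform(0.0, 1.0, domain.N)
        iu = model.u_index
        y0[iu] += xi_per * r
        if model.conserved:
            y0[1] -= xi_per * r
        else:
            y0[0] += xi_per * rng.uniform(0.0, 1.0, domain.N)  # w for LEGI
        y0 = np.clip(y0, 0.0, None)
        kym = _rd.simulate(model, domain, None, t_span=(0.0, T), y0=y0)
        plateau = kym.u[-PLATEAU_WINDOW:].mean(axis=0)
        if plateau.min() < EPS_RATIO:
            contrast = math.inf if plateau.max() > EPS_RATIO else 0.0
        else:
            contrast = float(plateau.max() / plateau.min())
        if contrast >= cutoff:
            n_pol += 1
    return n_pol / n_reps
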