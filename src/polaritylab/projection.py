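"""Two-bin (left/right) ODE reductions of the membrane models.

The cell is collapsed to two exchanging compartments. For the conserved
models the four-variable system is

    duL/dt = G1 = f_u(uL, vL) - Du_t (uL - uR) + sL vL
    dvL/dt = G2 = f_v(uL, vL) - Dv_t (vL - vR) - sL vL
    duR/dt = G3 = f_u(uR, vR) - Du_t (uR - uL) + sR vR
    dvR/dt = G4 = f_v(uR, vR) - Dv_t (vR - vL) - sR vR

with diffusion-like exchange rates ``Du_t`` (slow, membrane) and ``Dv_t``
(fast, cytosol); total mass ``uL + vL + uR + vR = 2 c_total`` is conserved
for any signal. This is the system whose bifurcation diagram defines the
organisation regions, and whose (uL, uR) closure feeds the quasi-potential
landscapes.

For LEGI, the fast inhibitor ``v`` and the activator ``w`` are eliminated
by quasi-steady state, leaving two ODEs in (uL, uR) with the closures

    v_qss  = (kv / k_minus_v) (sL + sR) / 2
    wL_qss = kw / (2 Dw_t + k_minus_w) * (sL + Dw_t (sL + sR) / k_minus_w)
    wR_qss = (kw / k_minus_w)(sL + sR) - wL_qss

so that ``wL_qss + wR_qss = (kw / k_minus_w)(sL + sR)`` holds identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from . import models as _models
from .errors import ConfigurationError, DomainError, NumericalError
from .models import LegiParams, ModelSpec
from .signals import StepProtocol

__all__ = [
    "TwoBinState",
    "Trajectory",
    "DEFAULT_DU_TILDE",
    "DEFAULT_DV_TILDE",
    "two_bin_rhs",
    "legi_two_bin_rhs",
    "simulate_projection",
    "two_bin_reduced_drift",
    "two_bin_fixed_points",
    "symmetric_fixed_point",
]

DEFAULT_DU_TILDE = 0.01  # 1/s, slow membrane exchange
DEFAULT_DV_TILDE = 10.0  # 1/s, fast cytosolic exchange


@dataclass(frozen=True)
class TwoBinState:
    """State of the two-bin projection of a conserved model (uM)."""

    uL: float
    vL: float
    uR: float
    vR: float

    def __post_init__(self):
        if min(self.uL, self.vL, self.uR, self.vR) < 0:
            raise DomainError("two-bin concentrations must be nonnegative")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.uL, self.vL, self.uR, self.vR])

    @property
    def total(self) -> float:
        return self.uL + self.vL + self.uR + self.vR

    def swapped(self) -> "TwoBinState":
        """Mirror state with left and right bins exchanged."""
        return TwoBinState(self.uR, self.vR, self.uL, self.vL)

    @classmethod
    def from_hss(cls, model: ModelSpec) -> "TwoBinState":
        u, v = _models.hss_state(model)
        return cls(u, v, u, v)


def two_bin_rhs(state, model: ModelSpec, sL: float = 0.0, sR: float = 0.0,
                Du_tilde: float = DEFAULT_DU_TILDE, Dv_tilde: float = DEFAULT_DV_TILDE) -> np.ndarray:
    """G1..G4 of the two-bin system at ``state`` (array-like or TwoBinState)."""
    if Du_tilde < 0 or Dv_tilde < 0:
        raise DomainError("exchange rates must be >= 0")
    if not model.conserved:
        raise ConfigurationError("two_bin_rhs applies to the conserved models; use legi_two_bin_rhs for LEGI")
    uL, vL, uR, vR = state.vector if isinstance(state, TwoBinState) else np.asarray(state, dtype=float)
    p = model.params
    fL = p.f_u(uL, vL)
    fR = p.f_u(uR, vR)
    g1 = fL - Du_tilde * (uL - uR) + sL * vL
    g2 = -fL - Dv_tilde * (vL - vR) - sL * vL
    g3 = fR - Du_tilde * (uR - uL) + sR * vR
    g4 = -fR - Dv_tilde * (vR - vL) - sR * vR
    return np.array([g1, g2, g3, g4])


def legi_two_bin_rhs(state, params: LegiParams, sL: float = 0.0, sR: float = 0.0,
                     Du_tilde: float = DEFAULT_DU_TILDE,
                     Dw_tilde: float = DEFAULT_DU_TILDE) -> np.ndarray:
    """Derivatives of (uL, uR) for the quasi-steady-state LEGI reduction.

    ``Dw_tilde`` defaults to the slow membrane exchange rate (w is the slow
    membrane species); it only enters through the ``wL_qss`` closure.
    """
    if params.k_minus_v == 0 or params.k_minus_w == 0:
        raise DomainError("zero decay rates make the quasi-steady-state closure singular")
    uL, uR = np.asarray(state, dtype=float)
    v_qss, wL_qss, wR_qss = legi_qss_closure(params, sL, sR, Dw_tilde)
    duL = params.f_u(wL_qss, uL, v_qss) - Du_tilde * (uL - uR)
    duR = params.f_u(wR_qss, uR, v_qss) - Du_tilde * (uR - uL)
    return np.array([duL, duR])


def legi_qss_closure(params: LegiParams, sL: float, sR: float,
                     Dw_tilde: float = DEFAULT_DU_TILDE) -> Tuple[float, float, float]:
    """The printed quasi-steady-state values ``(v_qss, wL_qss, wR_qss)``."""
    v_qss = 0.5 * params.kv / params.k_minus_v * (sL + sR)
    wL_qss = params.kw / (2.0 * Dw_tilde + params.k_minus_w) * (sL + Dw_tilde * (sL + sR) / params.k_minus_w)
    wR_qss = params.kw / params.k_minus_w * (sL + sR) - wL_qss
    return v_qss, wL_qss, wR_qss


@dataclass
class Trajectory:
    """A two-bin trajectory with its stepped-signal epoch annotation."""

    times: np.ndarray
    states: np.ndarray          # (T, n_vars): (uL, vL, uR, vR) or (uL, uR) for LEGI
    signal: np.ndarray          # (T, 2): (sL, sR)
    epoch_bounds: np.ndarray    # absolute times of epoch switches, incl. 0 and T
    model: ModelSpec

    @property
    def uL(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def uR(self) -> np.ndarray:
        return self.states[:, 2 if self.states.shape[1] == 4 else 1]

    def epoch_slice(self, k: int) -> slice:
        a, b = self.epoch_bounds[k], self.epoch_bounds[k + 1]
        i0 = int(np.searchsorted(self.times, a, side="left"))
        i1 = int(np.searchsorted(self.times, b, side="right"))
        return slice(i0, i1)


def simulate_projection(model: ModelSpec, protocol: StepProtocol,
                        initial: Optional[TwoBinState] = None,
                        Du_tilde: float = DEFAULT_DU_TILDE, Dv_tilde: float = DEFAULT_DV_TILDE,
                        Dw_tilde: float = DEFAULT_DU_TILDE,
                        rtol: float = 1e-8, atol: float = 1e-10,
                        report_dt: float = 1.0) -> Trajectory:
    """Integrate the two-bin system under a stepped ``(sL, sR)`` protocol.

    Each epoch is integrated separately (the signal is constant within an
    epoch) and the trajectory is annotated with the epoch boundaries for
    phase-portrait overlays. The default initial condition is the model HSS
    replicated to both bins (u = 0 for LEGI).
    """
    if model.conserved:
        if initial is None:
            initial = TwoBinState.from_hss(model)
        y = initial.vector

        def make_rhs(sL, sR):
            return lambda t, x: two_bin_rhs(x, model, sL, sR, Du_tilde, Dv_tilde)
    else:
        y = np.zeros(2) if initial is None else np.asarray(initial, dtype=float)

        def make_rhs(sL, sR):
            return lambda t, x: legi_two_bin_rhs(x, model.params, sL, sR, Du_tilde, Dw_tilde)

    bounds = protocol.boundaries()
    times, states, sigs = [0.0], [y.copy()], [list(protocol.signal_at(0.0))]
    for a, b, ep in zip(bounds[:-1], bounds[1:], protocol.epochs):
        t_eval = np.arange(a, b + report_dt / 2, report_dt)[1:]
        if len(t_eval) == 0 or t_eval[-1] < b - 1e-9:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(make_rhs(ep.sL, ep.sR), (a, b), y, method="RK45",
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise NumericalError(f"projection integration failed on epoch [{a}, {b}]: {sol.message}")
        times.extend(sol.t.tolist())
        states.extend(sol.y.T)
        sigs.extend([[ep.sL, ep.sR]] * len(sol.t))
        y = sol.y[:, -1]
    return Trajectory(times=np.array(times), states=np.array(states),
                      signal=np.array(sigs), epoch_bounds=bounds, model=model)


# ---------------------------------------------------------------------------
# (uL, uR) closure used by the quasi-potential landscapes


def two_bin_reduced_drift(model: ModelSpec, sL: float = 0.0, sR: float = 0.0,
                          Du_tilde: float = DEFAULT_DU_TILDE,
                          Dw_tilde: float = DEFAULT_DU_TILDE) -> Callable:
    """Drift field ``(uL, uR) -> (G1, G3)`` on the 2-D projection plane.

    For conserved models the fast cytosolic exchange homogenises v, which
    conservation then fixes to ``v = c_total - (uL + uR)/2``; G1 and G3
    become functions of (uL, uR) alone. For LEGI the quasi-steady-state
    reduction already is two-dimensional.
    """
    if model.conserved:
        p = model.params
        c = p.c_total

        def drift(uL, uR):
            v = c - 0.5 * (np.asarray(uL) + np.asarray(uR))
            g1 = p.f_u(uL, v) - Du_tilde * (uL - uR) + sL * v
            g3 = p.f_u(uR, v) - Du_tilde * (uR - uL) + sR * v
            return g1, g3

        return drift

    params = model.params

    def drift(uL, uR):
        out = np.broadcast_arrays(np.asarray(uL, dtype=float), np.asarray(uR, dtype=float))
        a, b = out
        v_qss, wL, wR = legi_qss_closure(params, sL, sR, Dw_tilde)
        g1 = params.f_u(wL, a, v_qss) - Du_tilde * (a - b)
        g3 = params.f_u(wR, b, v_qss) - Du_tilde * (b - a)
        return g1, g3

    return drift


def symmetric_fixed_point(model: ModelSpec) -> TwoBinState:
    """The two-bin symmetric fixed point (equals the RD homogeneous state)."""
    return TwoBinState.from_hss(model)


def two_bin_fixed_points(model: ModelSpec, sL: float = 0.0, sR: float = 0.0,
                         Du_tilde: float = DEFAULT_DU_TILDE, Dv_tilde: float = DEFAULT_DV_TILDE,
                         n_starts: int = 14, tol: float = 1e-9) -> List[np.ndarray]:
    """Multi-start root search for fixed points of the conserved two-bin system.

    The conservation law is eliminated (vR = 2 c_total - uL - vL - uR) and
    roots of (G1, G2, G3) are collected from a grid of starting points and
    de-duplicated. Returns full (uL, vL, uR, vR) vectors sorted by uL.
    """
    if not model.conserved:
        raise ConfigurationError("fixed-point scan is defined for the conserved two-bin system")
    c = model.params.c_total
    total = 2.0 * c
    # evaluable also slightly outside the positive cone, as fsolve requires
    p = model.params

    def res(x):
        uL, vL, uR = x
        vR = total - uL - vL - uR
        fL = p.f_u(uL, vL)
        fR = p.f_u(uR, vR)
        g1 = fL - Du_tilde * (uL - uR) + sL * vL
        g2 = -fL - Dv_tilde * (vL - vR) - sL * vL
        g3 = fR - Du_tilde * (uR - uL) + sR * vR
        return [g1, g2, g3]

    found = []
    us = np.linspace(0.02 * c, 1.3 * c, n_starts)
    for a in us:
        for b in us:
            x0 = (a, c - 0.5 * (a + b), b)
            sol, info, ier, _ = fsolve(res, x0, full_output=True)
            if ier != 1:
                continue
            uL, vL, uR = sol
            vR = total - uL - vL - uR
            if min(uL, vL, uR, vR) < -1e-9:
                continue
            vec = np.array([uL, vL, uR, vR])
            if np.max(np.abs(res(sol))) > 1e-8:
                continue
            if not any(np.allclose(vec, f, atol=1e-6) for f in found):
                found.append(vec)
    return sorted(found, key=lambda v: v[0])
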