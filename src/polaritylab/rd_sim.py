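"""Reaction-diffusion integration on the 1-D periodic membrane.

Method of lines: the membrane (perimeter ``L = 2 pi R``) is discretised
into ``N`` uniform bins and the Laplacian is approximated by the centred
second difference with periodic wrap, ``(u_{i+1} - 2 u_i + u_{i-1}) / dtheta^2``
with ``dtheta = L / N`` in physical length units. The resulting ODE system
is integrated with the adaptive explicit Runge-Kutta 5(4) scheme
(``scipy.integrate.solve_ivp``), restarted at every signal switch time so
the piecewise-constant stimulus never crosses an integration step.

The cell radius ``R`` is not part of the kinetic parameter sets; it sets
the absolute diffusion time scale of every spatially resolved result and
the locations of the pattern-existence and symmetry-breaking boundaries
of the discretised system. The default ``R = 1.5 um`` (perimeter ~= 9.4
um, close to the canonical 10 um wave-pinning domain) is calibrated so
that on the default domain the four qualitative response regimes of the
wave-pinning family are all reproduced with the canonical c_total
presets: the polar pattern must not survive signal removal at
c_total = 2.21 but must at 2.26, and the homogeneous state must be
spatially unstable at 2.32. It is a deliberate, configurable choice --
see ``docs/methods.md``.

Stochastic runs use the Euler-Maruyama scheme with additive Gaussian white
noise of intensity ``sigma`` on every bin and component, at a fixed step
``dt`` (default 0.01 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels as _k
from . import models as _models
from .errors import ConfigurationError, DomainError, NumericalError
from .models import ModelSpec
from .signals import ProtocolSpec

__all__ = ["DomainSpec", "Kymograph", "discretize", "simulate", "simulate_sde", "default_initial_state"]

DEFAULT_RADIUS_UM = 1.5  # perimeter 2*pi*R ~= 9.4 um; see module docstring


@dataclass(frozen=True)
class DomainSpec:
    """Discretised periodic membrane: ``N`` bins on a circle of radius ``R`` (um)."""

    N: int = 20
    R: float = DEFAULT_RADIUS_UM

    def __post_init__(self):
        if self.N < 3:
            raise DomainError(f"N must be >= 3, got {self.N}")
        if not self.R > 0:
            raise DomainError(f"R must be > 0, got {self.R}")

    @property
    def L(self) -> float:
        """Perimeter length (um)."""
        return 2.0 * math.pi * self.R

    @property
    def dtheta(self) -> float:
        """Physical bin size ``L / N`` (um), used in the Laplacian."""
        return self.L / self.N

    @property
    def theta(self) -> np.ndarray:
        """Bin-centre angles (radians), bin 0 at theta = 0."""
        return 2.0 * math.pi * np.arange(self.N) / self.N


@dataclass
class Kymograph:
    """Space-time record of one simulation.

    ``fields`` has shape (n_components, n_times, N) ordered like the model
    state vector; ``signal_history`` (n_times, N) is the applied signal.
    """

    times: np.ndarray
    theta: np.ndarray
    fields: np.ndarray
    signal_history: np.ndarray
    model: ModelSpec
    domain: DomainSpec

    @property
    def u(self) -> np.ndarray:
        """Membrane response component u(t, theta)."""
        return self.fields[self.model.u_index]

    def component(self, name: str) -> np.ndarray:
        return self.fields[self.model.component_names.index(name)]

    def bin_nearest(self, angle: float) -> int:
        d = np.abs(np.angle(np.exp(1j * (self.theta - angle))))
        return int(np.argmin(d))

    def trace_at(self, angle: float) -> np.ndarray:
        """Time trace of u at the bin nearest ``angle``."""
        return self.u[:, self.bin_nearest(angle)]

    def conservation_drift(self) -> float:
        """Max relative drift of the bin-mean total mass (conserved models)."""
        total = self.fields.sum(axis=0).mean(axis=1)
        return float(np.max(np.abs(total - total[0])) / abs(total[0]))


def _laplacian(y: np.ndarray, dtheta2: float) -> np.ndarray:
    return (np.roll(y, -1, axis=-1) - 2.0 * y + np.roll(y, 1, axis=-1)) / dtheta2


def _signal_lookup(protocol: Optional[ProtocolSpec], N: int) -> Callable[[float], np.ndarray]:
    """Piecewise-constant signal as precomputed interval -> vector table."""
    zero = np.zeros(N)
    if protocol is None or not protocol.epochs:
        return lambda t: zero
    switches = np.unique([t for ep in protocol.epochs for t in (ep.t_on, ep.t_off)])
    mids = np.concatenate([[switches[0] - 1.0], (switches[:-1] + switches[1:]) / 2.0, [switches[-1] + 1.0]])
    table = np.stack([protocol.signal_at(tm) if tm >= 0 else zero for tm in mids])

    def lookup(t: float) -> np.ndarray:
        return table[int(np.searchsorted(switches, t, side="right"))]

    return lookup


def discretize(model: ModelSpec, domain: DomainSpec, protocol: Optional[ProtocolSpec]) -> Callable:
    """Method-of-lines right-hand side ``f(t, y_flat) -> dy_flat``.

    Diffusion uses the periodic centred stencil; the reaction part is the
    model kinetics with the bin-local signal (identical arithmetic to
    :func:`polaritylab.models.reaction_rates`). Uses compiled kernels when
    numba is available, a pure-numpy path otherwise.
    """
    if protocol is not None and protocol.N != domain.N:
        raise ConfigurationError(f"protocol N={protocol.N} does not match domain N={domain.N}")
    nc = model.n_components
    N = domain.N
    dtheta2 = domain.dtheta ** 2
    p = model.params
    signal = _signal_lookup(protocol, N)

    if _k.HAVE_NUMBA:
        if model.name == "legi":
            args = (p.ku, p.k_minus_u, p.kv, p.k_minus_v, p.kw, p.k_minus_w, p.u_total, p.Dw, p.Dv, p.Du)
            kern = _k.legi_rhs
        elif model.name == "turing":
            args = (p.a1, p.a2, p.Du, p.Dv)
            kern = _k.turing_rhs
        else:
            args = (p.k0, p.gamma, p.K, p.delta, float(p.hill), p.Du, p.Dv)
            kern = _k.wp_rhs

        def rhs(t, y):
            return kern(y, signal(t), N, dtheta2, *args)

        return rhs

    D = model.diffusivities[:, None]
    if model.name == "legi":
        def react(state, s):
            w, v, u = state
            return np.stack([p.f_w(w) + p.kw * s, p.f_v(v) + p.kv * s, p.f_u(w, u, v)])
    else:
        def react(state, s):
            u, v = state
            fu = p.f_u(u, v) + s * v
            return np.stack([fu, -fu])

    def rhs(t, y):
        state = y.reshape(nc, N)
        return (react(state, signal(t)) + D * _laplacian(state, dtheta2)).ravel()

    return rhs


def default_initial_state(model: ModelSpec, domain: DomainSpec, perturbation: float = 0.0) -> np.ndarray:
    """HSS replicated over the bins, optionally plus a conservation-preserving
    odd perturbation ``+eps*cos(theta - pi)`` on u (and ``-eps*...`` on v).

    The perturbation (default off; use ~1e-3) selects a definite branch
    deterministically when the HSS is unstable (region IV / Turing preset).
    """
    hss = _models.hss_state(model)
    y = np.repeat(hss[:, None], domain.N, axis=1)
    if perturbation:
        bump = perturbation * np.cos(domain.theta - math.pi)
        iu = model.u_index
        y[iu] += bump
        if model.conserved:
            y[1] -= bump
        y = np.clip(y, 0.0, None)
    return y


def _report_grid(t_span: Tuple[float, float], report_dt: float) -> np.ndarray:
    n = int(round((t_span[1] - t_span[0]) / report_dt))
    return t_span[0] + report_dt * np.arange(n + 1)


def simulate(model: ModelSpec, domain: DomainSpec, protocol: Optional[ProtocolSpec],
             t_span: Tuple[float, float] = (0.0, 1000.0), y0: Optional[np.ndarray] = None,
             rtol: float = 1e-6, atol: float = 1e-9, report_dt: float = 1.0,
             ic_perturbation: float = 0.0) -> Kymograph:
    """Deterministic RD simulation; returns a :class:`Kymograph`.

    The run is split at the protocol's switch times and each segment is
    integrated with RK45 at (``rtol``, ``atol``), sampled on a uniform
    ``report_dt`` grid. Identical inputs give identical output.
    """
    rhs = discretize(model, domain, protocol)
    if y0 is None:
        y0 = default_initial_state(model, domain, ic_perturbation)
    y = np.asarray(y0, dtype=float).reshape(model.n_components, domain.N).copy()

    t_report = _report_grid(t_span, report_dt)
    seg_bounds = protocol.boundaries(t_span) if protocol is not None else np.array(t_span)
    frames = [y.copy()]
    cur = y.ravel()
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        t_eval = t_report[(t_report > a + 1e-12) & (t_report <= b + 1e-12)]
        need_b = len(t_eval) == 0 or t_eval[-1] < b - 1e-12
        te = np.concatenate([t_eval, [b]]) if need_b else t_eval
        sol = solve_ivp(rhs, (a, b), cur, method="RK45", rtol=rtol, atol=atol, t_eval=te)
        if not sol.success:
            raise NumericalError(f"RK45 failed on [{a}, {b}]: {sol.message}",
                                 last_state=sol.y[:, -1] if sol.y.size else cur)
        n_report = len(t_eval)
        for k in range(n_report):
            frames.append(sol.y[:, k].reshape(model.n_components, domain.N))
        cur = sol.y[:, -1]

    if len(frames) != len(t_report):
        raise NumericalError(f"reporting grid mismatch: {len(frames)} frames for {len(t_report)} report times")
    fields = np.stack(frames, axis=1)  # (nc, T, N)
    if protocol is not None:
        sig = np.stack([protocol.signal_at(t) for t in t_report])
    else:
        sig = np.zeros((len(t_report), domain.N))
    return Kymograph(times=t_report, theta=domain.theta, fields=fields,
                     signal_history=sig, model=model, domain=domain)


def simulate_sde(model: ModelSpec, domain: DomainSpec, protocol: Optional[ProtocolSpec],
                 sigma: float, dt: float = 0.01, seed: int = 0,
                 t_span: Tuple[float, float] = (0.0, 1000.0), y0: Optional[np.ndarray] = None,
                 report_dt: float = 1.0, ic_perturbation: float = 0.0) -> Kymograph:
    """Euler-Maruyama integration with additive noise on every bin/component.

    ``y_{n+1} = y_n + f(t_n, y_n) dt + sigma sqrt(dt) xi``, ``xi ~ N(0, 1)``.
    Negative concentrations produced by the noise are clipped at 0 after
    each step. A fixed ``seed`` makes the trajectory bit-reproducible;
    ``sigma = 0`` reproduces the deterministic dynamics within the O(dt)
    global error of the Euler scheme.
    """
    if sigma < 0:
        raise DomainError(f"sigma must be >= 0, got {sigma}")
    rhs = discretize(model, domain, protocol)
    if y0 is None:
        y0 = default_initial_state(model, domain, ic_perturbation)
    y = np.asarray(y0, dtype=float).ravel().copy()
    rng = np.random.default_rng(seed)

    t_report = _report_grid(t_span, report_dt)
    stride = max(1, int(round(report_dt / dt)))
    n_steps = (len(t_report) - 1) * stride
    frames = np.empty((len(t_report), y.size))
    frames[0] = y
    t = t_span[0]
    sq = sigma * math.sqrt(dt)
    for n in range(1, n_steps + 1):
        y = y + rhs(t, y) * dt
        if sigma:
            y += sq * rng.standard_normal(y.size)
            np.clip(y, 0.0, None, out=y)
        t = t_span[0] + n * dt
        if n % stride == 0:
            frames[n // stride] = y

    fields = frames.T.reshape(model.n_components, domain.N, len(t_report)).transpose(0, 2, 1)
    if protocol is not None:
        sig = np.stack([protocol.signal_at(tk) for tk in t_report])
    else:
        sig = np.zeros((len(t_report), domain.N))
    return Kymograph(times=t_report, theta=domain.theta, fields=fields,
                     signal_history=sig, model=model, domain=domain)
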