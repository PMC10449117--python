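"""Reaction kinetics and canonical parameter presets of the polarity mechanisms.

Four membrane-polarity mechanisms are covered, all posed on the cell
membrane (1-D periodic domain) with concentrations in uM, time in s and
space in um:

* ``wavepinning`` / ``subpb`` -- the mass-conserved GTPase cycle with a
  Hill-type positive feedback,
  ``f_u(u, v) = (k0 + gamma u^h / (K^h + u^h)) v - delta u``, ``f_v = -f_u``.
  The two labels share the kinetics and differ only in the conserved total
  concentration ``c_total``: the SubPB preset sits just below the saddle-node
  that stabilises the subcritical pitchfork (criticality), the Wave-pinning
  preset inside the bistable window where polar and non-polar states coexist.
* ``turing`` -- a mass-conserved activator-depletion (Turing-like) kinetics
  ``f_u(u, v) = a1 (v - (u + v) / (a2 (u + v) + 1)^2)``, ``f_v = -f_u``.
* ``legi`` -- local excitation / global inhibition: membrane activator ``w``,
  cytosolic inhibitor ``v`` and response component ``u`` wired as an
  incoherent feed-forward loop; not mass conserved.

The external signal ``s`` couples as ``+s v`` on ``u`` and ``-s v`` on ``v``
for the conserved models (so conservation holds exactly in the presence of
a signal), and as production terms ``+k_w s`` on ``w`` and ``+k_v s`` on
``v`` for LEGI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError, NumericalError

__all__ = [
    "WavePinningParams",
    "LegiParams",
    "TuringParams",
    "ModelSpec",
    "reaction_rates",
    "homogeneous_steady_state",
    "hss_state",
    "preset",
    "PRESET_NAMES",
]


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise DomainError(f"{type(obj).__name__}.{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class WavePinningParams:
    """Parameters of the mass-conserved GTPase (wave-pinning / SubPB) kinetics.

    Attributes
    ----------
    k0 : basal GEF-mediated activation rate (1/s).
    gamma : maximal feedback conversion rate (1/s).
    K : feedback saturation concentration (uM).
    delta : GAP-mediated inactivation rate (1/s).
    c_total : conserved mean total concentration of active + inactive form (uM).
    Du, Dv : membrane/cytosolic diffusion constants (um^2/s); ``Dv > Du``.
    hill : Hill exponent of the positive feedback. Fixed to 2 in every
        preset; exposed for exploration only.
    """

    k0: float = 0.067
    gamma: float = 1.0
    K: float = 1.0
    delta: float = 1.0
    c_total: float = 2.26
    Du: float = 0.1
    Dv: float = 10.0
    hill: int = 2

    def __post_init__(self):
        _require_positive(self, ["k0", "gamma", "K", "delta", "c_total", "Du", "Dv", "hill"])
        if not self.Dv > self.Du:
            raise DomainError(f"requires Dv > Du, got Du={self.Du}, Dv={self.Dv}")

    def f_u(self, u, v):
        uh = np.asarray(u) ** self.hill
        return (self.k0 + self.gamma * uh / (self.K ** self.hill + uh)) * v - self.delta * u


@dataclass(frozen=True)
class LegiParams:
    """Parameters of the LEGI (local excitation, global inhibition) model.

    ``w`` is the membrane-bound activator, ``v`` the fast cytosolic
    inhibitor and ``u`` the membrane response component with total
    amount ``u_total``. The absolute scale of ``u_total`` is a modelling
    choice; the default of 1 uM makes ``u`` a fractional response in [0, 1].
    """

    ku: float = 2.0
    k_minus_u: float = 2.0
    kv: float = 1.0
    k_minus_v: float = 1.0
    kw: float = 1.0
    k_minus_w: float = 1.0
    u_total: float = 1.0
    Du: float = 0.5
    Dv: float = 10.0
    Dw: float = 0.5

    def __post_init__(self):
        _require_positive(
            self,
            ["ku", "k_minus_u", "kv", "k_minus_v", "kw", "k_minus_w", "u_total", "Du", "Dv", "Dw"],
        )

    def f_w(self, w):
        return -self.k_minus_w * w

    def f_v(self, v):
        return -self.k_minus_v * v

    def f_u(self, w, u, v):
        return self.ku * w * (self.u_total - u) - self.k_minus_u * v * u


@dataclass(frozen=True)
class TuringParams:
    """Parameters of the mass-conserved Turing-like (activator-depletion) kinetics.

    a1 sets the kinetic time scale (1/s), a2 the saturation (1/uM). In the
    local-perturbation reduction the homogeneous state loses stability at
    the transcritical point ``c_total = 1/a2``; on a finite domain the
    spatially resolved instability sets in later. The preset
    ``c_total = 2.5`` places the model clearly past the instability onset
    of the discretised system on the default membrane, where the polarised
    state is the only attractor (the canonical organisation of this model
    class).
    """

    a1: float = 2.5
    a2: float = 0.7
    c_total: float = 2.5
    Du: float = 0.1
    Dv: float = 10.0

    def __post_init__(self):
        _require_positive(self, ["a1", "a2", "c_total", "Du", "Dv"])
        if not self.Dv > self.Du:
            raise DomainError(f"requires Dv > Du, got Du={self.Du}, Dv={self.Dv}")

    def f_u(self, u, v):
        z = np.asarray(u) + v
        return self.a1 * (v - z / (self.a2 * z + 1.0) ** 2)


Params = Union[WavePinningParams, LegiParams, TuringParams]

_CONSERVED_NAMES = {"subpb", "wavepinning", "turing"}
_VALID_NAMES = _CONSERVED_NAMES | {"legi"}


@dataclass(frozen=True)
class ModelSpec:
    """A named reaction system usable by every integrator in the package.

    ``conserved`` marks mass conservation (``f_v = -f_u``); it is true for
    the wave-pinning family and the Turing-like model and false for LEGI.
    ``subpb`` and ``wavepinning`` share kinetics and differ only in the
    ``c_total`` preset.
    """

    name: str
    params: Params
    n_components: int
    conserved: bool

    def __post_init__(self):
        if self.name not in _VALID_NAMES:
            raise ConfigurationError(f"unknown model name {self.name!r}; expected one of {sorted(_VALID_NAMES)}")
        if self.conserved != (self.name in _CONSERVED_NAMES):
            raise ConfigurationError(f"model {self.name!r} must have conserved={self.name in _CONSERVED_NAMES}")
        if self.n_components != (3 if self.name == "legi" else 2):
            raise ConfigurationError(f"model {self.name!r} has the wrong number of components")

    @property
    def diffusivities(self) -> np.ndarray:
        """Per-component diffusion constants, ordered like the state vector."""
        p = self.params
        if self.name == "legi":
            return np.array([p.Dw, p.Dv, p.Du])
        return np.array([p.Du, p.Dv])

    @property
    def component_names(self):
        return ("w", "v", "u") if self.name == "legi" else ("u", "v")

    @property
    def u_index(self) -> int:
        """Index of the membrane response component in the state vector."""
        return 2 if self.name == "legi" else 0

    def with_params(self, **changes) -> "ModelSpec":
        return replace(self, params=replace(self.params, **changes))


def reaction_rates(model: ModelSpec, state, s=0.0) -> np.ndarray:
    """Reaction part of the time derivatives at local signal amplitude ``s``.

    Parameters
    ----------
    model : ModelSpec
    state : array of shape ``(n_components,) + extra``; components ordered
        ``(u, v)`` for conserved models and ``(w, v, u)`` for LEGI.
        Each component may itself be a vector of per-bin concentrations.
    s : scalar or per-bin signal amplitude, >= 0.

    Returns
    -------
    ndarray of the same shape as ``state``. For conserved models
    ``du/dt + dv/dt = 0`` holds exactly, including the signal terms.
    """
    state = np.asarray(state, dtype=float)
    if state.shape[0] != model.n_components:
        raise ConfigurationError(
            f"state has {state.shape[0]} components, model {model.name!r} needs {model.n_components}"
        )
    if np.any(state < 0):
        raise DomainError("negative concentration in state")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise DomainError("signal amplitude must be >= 0")
    p = model.params
    if model.name == "legi":
        w, v, u = state
        dw = p.f_w(w) + p.kw * s
        dv = p.f_v(v) + p.kv * s
        du = p.f_u(w, u, v)
        return np.stack(np.broadcast_arrays(dw, dv, du))
    u, v = state
    fu = p.f_u(u, v) + s * v
    return np.stack(np.broadcast_arrays(fu, -fu))


def homogeneous_steady_state(model: ModelSpec, s: float = 0.0) -> np.ndarray:
    """All homogeneous steady states under a spatially uniform signal.

    For conserved models the constraint ``u + v = c_total`` is imposed and
    the scalar equation ``f_u(u, c_total - u) + s (c_total - u) = 0`` is
    solved on ``[0, c_total]`` by bracketing every sign change of a dense
    scan. Roots are returned sorted by ``u``; the smallest-``u`` root is the
    non-polar HSS candidate.

    Returns
    -------
    ndarray of shape ``(n_roots, n_components)`` with rows ordered like the
    model's state vector.

    Raises
    ------
    NumericalError if no root exists in the admissible interval.
    """
    p = model.params
    if model.name == "legi":
        w = p.kw * s / p.k_minus_w
        v = p.kv * s / p.k_minus_v
        denom = p.ku * w + p.k_minus_u * v
        u = 0.0 if denom == 0.0 else p.ku * w * p.u_total / denom
        return np.array([[w, v, u]])

    c = p.c_total

    def g(u):
        return p.f_u(u, c - u) + s * (c - u)

    grid = np.linspace(0.0, c, 2001)
    vals = g(grid)
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # collapse near-duplicates from roots landing on grid nodes
    uniq = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-9:
            uniq.append(r)
    if not uniq:
        raise NumericalError(f"no homogeneous steady state in [0, {c}] for model {model.name!r} at s={s}")
    return np.array([[u, c - u] for u in uniq])


def hss_state(model: ModelSpec, s: float = 0.0) -> np.ndarray:
    """The non-polar HSS (smallest-``u`` root) as a single state vector."""
    return homogeneous_steady_state(model, s)[0]


def _wp_spec(c_total: float) -> ModelSpec:
    name = "subpb" if abs(c_total - 2.21) < 1e-12 else "wavepinning"
    return ModelSpec(name=name, params=WavePinningParams(c_total=c_total), n_components=2, conserved=True)


def preset(name: str) -> ModelSpec:
    """Canonical parameter preset by region or model label.

    Labels: ``region_I`` (c_total = 2.1), ``region_II`` / ``subpb`` (2.21),
    ``region_III`` / ``wavepinning`` (2.26), ``region_IV`` (2.32),
    ``legi`` and ``turing``. Wave-pinning-family rates are
    k0 = 0.067/s, gamma = 1/s, K = 1 uM, delta = 1/s, Du = 0.1, Dv = 10 um^2/s.
    """
    key = name.lower()
    if key == "region_i":
        spec = _wp_spec(2.1)
        return replace(spec, name="wavepinning")
    if key in ("region_ii", "subpb"):
        return _wp_spec(2.21)
    if key in ("region_iii", "wavepinning"):
        return _wp_spec(2.26)
    if key == "region_iv":
        spec = _wp_spec(2.32)
        return replace(spec, name="wavepinning")
    if key == "legi":
        return ModelSpec(name="legi", params=LegiParams(), n_components=3, conserved=False)
    if key == "turing":
        return ModelSpec(name="turing", params=TuringParams(), n_components=2, conserved=True)
    raise ConfigurationError(f"unknown preset {name!r}")


PRESET_NAMES = ("region_I", "region_II", "subpb", "region_III", "wavepinning", "region_IV", "legi", "turing")
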