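"""Bifurcation structure: continuation, PB condition, LPA reductions, regions.

The organisation regions of the wave-pinning family are read off the
two-bin system's diagram versus the total concentration ``c_total``:

* region I   -- only the homogeneous (non-polar) state, far from criticality;
* region II  -- criticality (SubPB): HSS only, but just below the saddle-node
  ``SN_PB`` that stabilises the subcritical pitchfork branches, so a "ghost"
  of the polar state shapes the transient dynamics;
* region III -- HSS and the inhomogeneous (polar) state coexist (the classic
  wave-pinning organisation);
* region IV  -- past the pitchfork ``PB``: the HSS is unstable and only the
  polar state remains (Turing-like organisation).

Steady states are continued natively with a secant-predictor /
Newton-corrector pseudo-arclength scheme; special points are flagged by
eigenvalue crossings plus branch geometry (symmetry-breaking crossing on a
symmetric branch -> PB, fold on an asymmetric branch -> SN_PB, stability
exchange without fold or symmetry breaking -> TC).

The local perturbation analysis (LPA) reduces a slow/fast RD system to
local/global ODEs: the global subsystem is exactly the well-mixed model,
while the local variable probes the response to a narrow zero-mass peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import projection as _proj
from .errors import ConfigurationError, DomainError, NumericalError
from .models import ModelSpec, homogeneous_steady_state, hss_state
from .projection import DEFAULT_DU_TILDE, DEFAULT_DV_TILDE

__all__ = [
    "Branch",
    "SpecialPoint",
    "BifurcationDiagram",
    "continue_branch",
    "two_bin_steady_system",
    "continue_two_bin",
    "pb_condition",
    "find_pb_from_condition",
    "unfolding_diagram",
    "lpa_reduce",
    "continue_lpa",
    "RegionBoundaries",
    "locate_region_boundaries",
    "classify_region",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Branch:
    params: np.ndarray       # (n_pts,)
    states: np.ndarray       # (n_pts, n)
    leading_re: np.ndarray   # max Re eigenvalue of the dynamics Jacobian
    stable: np.ndarray       # bool
    symmetric: bool = False


@dataclass
class SpecialPoint:
    kind: str                # "PB" | "SN_PB" | "SN" | "TC"
    param: float
    state: np.ndarray


@dataclass
class BifurcationDiagram:
    parameter: str
    branches: List[Branch]
    special_points: List[SpecialPoint] = field(default_factory=list)

    def points_of(self, kind: str) -> List[SpecialPoint]:
        return [sp for sp in self.special_points if sp.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, br in enumerate(self.branches):
            for p, x, lam, st in zip(br.params, br.states, br.leading_re, br.stable):
                rows.append({self.parameter: p, "branch": bi,
                             **{f"x{j}": v for j, v in enumerate(x)},
                             "re_lambda": lam, "stable": bool(st)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generic pseudo-arclength continuation


def _fd_jac(f, x, p, h=1e-7):
    n = len(x)
    fx = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        fx[:, j] = (np.asarray(f(x + e, p)) - np.asarray(f(x - e, p))) / (2 * h)
    fp = (np.asarray(f(x, p + h)) - np.asarray(f(x, p - h))) / (2 * h)
    return fx, fp


def _newton(f, x, p, tol=1e-11, max_iter=30):
    x = np.asarray(x, dtype=float).copy()
    for _ in range(max_iter):
        r = np.asarray(f(x, p))
        if np.max(np.abs(r)) < tol:
            return x, True
        fx, _ = _fd_jac(f, x, p)
        try:
            dx = np.linalg.solve(fx, -r)
        except np.linalg.LinAlgError:
            return x, False
        x = x + dx
        if np.max(np.abs(dx)) > 1e6:
            return x, False
    return x, np.max(np.abs(np.asarray(f(x, p)))) < 1e-8


def _tangent(f, x, p, prev=None):
    fx, fp = _fd_jac(f, x, p)
    A = np.hstack([fx, fp[:, None]])
    _, _, vt = np.linalg.svd(A)
    t = vt[-1]
    t = t / np.linalg.norm(t)
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    elif prev is None and t[-1] < 0:
        t = -t
    return t


def continue_branch(f: Callable, x0: np.ndarray, p0: float,
                    p_range: Tuple[float, float],
                    ds: float = 2e-3, ds_min: float = 1e-5, ds_max: float = 1e-2,
                    max_steps: int = 4000, direction: float = +1.0,
                    stop_outside_cone: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Trace one steady-state branch of ``f(x, p) = 0`` through ``(x0, p0)``.

    Secant/tangent predictor with a bordered-Newton corrector; the step is
    halved after corrector failures down to ``ds_min`` (branch truncated
    with the last converged point). Returns ``(params, states)`` along the
    branch in the direction of increasing arclength; call twice with
    ``direction=+1`` and ``-1`` to cover both sides.
    """
    x0 = np.asarray(x0, dtype=float)
    x, ok = _newton(f, x0, p0)
    if not ok:
        raise NumericalError(f"no converged steady state at the branch start p={p0}")
    n = len(x)
    t = _tangent(f, x, p0) * direction
    ps, xs = [p0], [x.copy()]
    p = p0
    h = ds
    for _ in range(max_steps):
        z_pred = np.concatenate([x, [p]]) + h * t
        xc, pc = z_pred[:n].copy(), float(z_pred[n])
        converged = False
        for _ in range(25):
            r = np.asarray(f(xc, pc))
            extra = np.dot(t, np.concatenate([xc, [pc]]) - z_pred)
            if np.max(np.abs(r)) < 1e-10 and abs(extra) < 1e-10:
                converged = True
                break
            fx, fp = _fd_jac(f, xc, pc)
            A = np.zeros((n + 1, n + 1))
            A[:n, :n] = fx
            A[:n, n] = fp
            A[n, :] = t
            try:
                dz = np.linalg.solve(A, -np.concatenate([r, [extra]]))
            except np.linalg.LinAlgError:
                break
            xc += dz[:n]
            pc += dz[n]
        if not converged:
            if h > ds_min:
                h = max(h / 2.0, ds_min)
                continue
            break
        if stop_outside_cone and np.min(xc) < -1e-6:
            break
        t_new = _tangent(f, xc, pc, prev=t)
        x, p, t = xc, pc, t_new
        ps.append(p)
        xs.append(x.copy())
        h = min(h * 1.3, ds_max)
        if p < p_range[0] - 1e-9 or p > p_range[1] + 1e-9:
            break
    return np.array(ps), np.array(xs)


def _leading_re(f, x, p):
    fx, _ = _fd_jac(f, x, p)
    return float(np.max(np.linalg.eigvals(fx).real))


def _crossing_eigvec(f, x, p):
    fx, _ = _fd_jac(f, x, p)
    w, v = np.linalg.eig(fx)
    j = int(np.argmin(np.abs(w.real)))
    return v[:, j].real


def _assemble_branch(f, ps, xs, is_symmetric=None) -> Branch:
    lead = np.array([_leading_re(f, x, p) for p, x in zip(ps, xs)])
    sym = bool(is_symmetric(xs[0], ps[0])) if is_symmetric is not None else False
    return Branch(params=ps, states=xs, leading_re=lead, stable=lead < 0, symmetric=sym)


def _detect_special_points(f, branch: Branch, is_symmetric=None, breaks_symmetry=None) -> List[SpecialPoint]:
    out = []
    fold_idx = []
    ps, xs, lead = branch.params, branch.states, branch.leading_re
    dp = np.diff(ps)
    for i in range(1, len(ps) - 1):
        # fold: parameter direction reverses
        if dp[i - 1] * dp[i] < 0:
            kind = "SN" if branch.symmetric else "SN_PB"
            # quadratic vertex through the three points around the fold
            p3 = ps[i - 1:i + 2]
            s3 = np.array([-1.0, 0.0, 1.0])
            coef = np.polyfit(s3, p3, 2)
            s_v = -coef[1] / (2 * coef[0]) if coef[0] != 0 else 0.0
            p_v = np.polyval(coef, np.clip(s_v, -1, 1))
            out.append(SpecialPoint(kind=kind, param=float(p_v), state=xs[i].copy()))
            fold_idx.append(i)
    for i in range(len(ps) - 1):
        if lead[i] * lead[i + 1] < 0:
            near_fold = any(abs(i - j) <= 5 for j in fold_idx) or any(
                abs(sp.param - ps[i]) < 2e-3 for sp in out if sp.kind in ("SN", "SN_PB"))
            if near_fold:
                continue
            # refine by secant in the parameter on the monitored eigenvalue
            pa, pb = ps[i], ps[i + 1]
            xa = xs[i]

            def g(p, seed=[xa]):
                frac = (p - pa) / (pb - pa) if pb != pa else 0.0
                x_guess = xs[i] * (1 - frac) + xs[i + 1] * frac
                x_sol, ok = _newton(f, x_guess, p)
                if ok:
                    seed[0] = x_sol
                return _leading_re(f, x_sol, p)

            try:
                p_star = brentq(g, min(pa, pb), max(pa, pb), xtol=1e-10) if pa != pb else pa
            except ValueError:
                p_star = 0.5 * (pa + pb)
            x_star, _ = _newton(f, 0.5 * (xs[i] + xs[i + 1]), p_star)
            kind = "TC"
            if branch.symmetric and breaks_symmetry is not None:
                vec = _crossing_eigvec(f, x_star, p_star)
                if breaks_symmetry(vec):
                    kind = "PB"
            out.append(SpecialPoint(kind=kind, param=float(p_star), state=x_star))
    return out


def _trace_both(f, x0, p0, p_range, **kw):
    p1, x1 = continue_branch(f, x0, p0, p_range, direction=+1.0, **kw)
    p2, x2 = continue_branch(f, x0, p0, p_range, direction=-1.0, **kw)
    ps = np.concatenate([p2[::-1], p1[1:]])
    xs = np.concatenate([x2[::-1], x1[1:]])
    return ps, xs


def _multi_seed_diagram(f, seeds_by_param, p_range, parameter,
                        is_symmetric=None, breaks_symmetry=None, **kw) -> BifurcationDiagram:
    """Continue from every seed not already covered by a traced branch."""
    branches: List[Branch] = []

    def covered(x, p):
        for br in branches:
            j = int(np.argmin(np.abs(br.params - p)))
            if abs(br.params[j] - p) < 2e-2 and np.linalg.norm(br.states[j] - x) < 2e-2:
                return True
        return False

    def duplicate(ps, xs):
        """True when >80% of the candidate branch is covered by existing ones."""
        if not branches:
            return False
        n_cov = 0
        for p, x in zip(ps[:: max(1, len(ps) // 25)], xs[:: max(1, len(ps) // 25)]):
            for br in branches:
                j = int(np.argmin(np.abs(br.params - p)))
                if abs(br.params[j] - p) < 1e-2 and np.linalg.norm(br.states[j] - x) < 1e-2:
                    n_cov += 1
                    break
        return n_cov > 0.8 * len(ps[:: max(1, len(ps) // 25)])

    for p0, seeds in seeds_by_param:
        for x0 in seeds:
            x_conv, ok = _newton(f, np.asarray(x0, dtype=float), p0)
            if not ok or covered(x_conv, p0):
                continue
            try:
                ps, xs = _trace_both(f, x_conv, p0, p_range, **kw)
            except NumericalError:
                continue
            if len(ps) < 3 or duplicate(ps, xs):
                continue
            branches.append(_assemble_branch(f, ps, xs, is_symmetric))

    diagram = BifurcationDiagram(parameter=parameter, branches=branches)
    seen = set()
    raw: List[SpecialPoint] = []
    for br in diagram.branches:
        for sp in _detect_special_points(f, br, is_symmetric, breaks_symmetry):
            key = (sp.kind, round(sp.param, 4), tuple(np.round(sp.state, 2)))
            if key not in seen:
                seen.add(key)
                raw.append(sp)
    # a fold detected exactly at a pitchfork junction (symmetric state) is an
    # artifact of the branch path passing through the PB, not a saddle-node
    pbs = [sp for sp in raw if sp.kind == "PB"]
    for sp in raw:
        if sp.kind in ("SN", "SN_PB"):
            at_pb = any(abs(sp.param - pb.param) < 2e-3
                        and np.linalg.norm(sp.state - pb.state) < 5e-2 for pb in pbs)
            if at_pb:
                continue
        diagram.special_points.append(sp)
    return diagram


# ---------------------------------------------------------------------------
# the conserved two-bin system vs c_total


def two_bin_steady_system(model: ModelSpec, sL: float = 0.0, sR: float = 0.0,
                          Du_tilde: float = DEFAULT_DU_TILDE,
                          Dv_tilde: float = DEFAULT_DV_TILDE) -> Callable:
    """Reduced steady-state map ``f(x, c_total)`` with x = (uL, vL, uR).

    The conservation law fixes ``vR = 2 c_total - uL - vL - uR``; the
    returned residuals (G1, G2, G3) are simultaneously the reduced
    dynamics on the invariant mass shell, so their Jacobian decides
    stability.
    """
    base = model.params

    def f(x, c):
        uL, vL, uR = x
        vR = 2.0 * c - uL - vL - uR
        fL = base.f_u(uL, vL)
        fR = base.f_u(uR, vR)
        return np.array([
            fL - Du_tilde * (uL - uR) + sL * vL,
            -fL - Dv_tilde * (vL - vR) - sL * vL,
            fR - Du_tilde * (uR - uL) + sR * vR,
        ])

    return f


def _two_bin_symmetric(x, c):
    uL, vL, uR = x
    vR = 2.0 * c - uL - vL - uR
    return abs(uL - uR) < 1e-6 and abs(vL - vR) < 1e-6


def _two_bin_breaks_symmetry(vec):
    # odd mode in reduced coordinates: delta uL ~= -delta uR
    a, b = vec[0], vec[2]
    return abs(a + b) < 0.2 * max(abs(a), abs(b), 1e-12)


def _two_bin_seeds(model: ModelSpec, c_values, sL=0.0, sR=0.0,
                   Du_tilde=DEFAULT_DU_TILDE, Dv_tilde=DEFAULT_DV_TILDE):
    from dataclasses import replace as _replace
    seeds = []
    for c in c_values:
        m = model.with_params(c_total=float(c))
        pts = _proj.two_bin_fixed_points(m, sL, sR, Du_tilde, Dv_tilde, n_starts=10)
        seeds.append((float(c), [p[:3] for p in pts]))
    return seeds


def continue_two_bin(model: ModelSpec, c_range: Tuple[float, float] = (2.0, 2.4),
                     sL: float = 0.0, sR: float = 0.0,
                     Du_tilde: float = DEFAULT_DU_TILDE, Dv_tilde: float = DEFAULT_DV_TILDE,
                     n_seed_sections: int = 5, **kw) -> BifurcationDiagram:
    """Bifurcation diagram of the two-bin system vs ``c_total``.

    Disconnected branches are caught by re-seeding from multi-start
    fixed-point scans at several sections across the range.
    """
    f = two_bin_steady_system(model, sL, sR, Du_tilde, Dv_tilde)
    c_values = np.linspace(c_range[0], c_range[1], n_seed_sections)
    seeds = _two_bin_seeds(model, c_values, sL, sR, Du_tilde, Dv_tilde)
    return _multi_seed_diagram(f, seeds, c_range, "c_total",
                               is_symmetric=_two_bin_symmetric,
                               breaks_symmetry=_two_bin_breaks_symmetry, **kw)


def unfolding_diagram(model: ModelSpec, amplitudes: Sequence[float],
                      c_range: Tuple[float, float] = (2.0, 2.4),
                      Du_tilde: float = DEFAULT_DU_TILDE, Dv_tilde: float = DEFAULT_DV_TILDE,
                      **kw) -> List[BifurcationDiagram]:
    """Diagrams vs c_total for a list of left-bin step amplitudes (sR = 0).

    At sL = 0 the symmetric pitchfork is present; any sL > 0 unfolds it: no
    exactly symmetric branch remains, a marginally asymmetric branch
    replaces the HSS and a detached polar branch coexists with it.
    """
    if any(a < 0 for a in amplitudes):
        raise DomainError("signal amplitudes must be >= 0")
    return [continue_two_bin(model, c_range, sL=float(a), sR=0.0,
                             Du_tilde=Du_tilde, Dv_tilde=Dv_tilde, **kw)
            for a in amplitudes]


# ---------------------------------------------------------------------------
# the analytic PB condition


def pb_condition(model: ModelSpec, hss: Optional[np.ndarray] = None,
                 Du_tilde: float = DEFAULT_DU_TILDE, Dv_tilde: float = DEFAULT_DV_TILDE,
                 h: float = 1e-7) -> float:
    """Determinant ``|F_lambda|`` of the odd-mode (symmetry-breaking) block.

    A linear perturbation of the symmetric two-bin state with the odd
    symmetry (duL = -duR, dvL = -dvR) closes on a 2x2 system; its matrix
    collects symmetric pairs of partial derivatives of G1..G4,

        F = [[(G1_uL + G3_uR) - (G1_uR + G3_uL),  G1_vL + G3_vR],
             [ G2_uL + G4_uR,                    (G2_vL + G4_vR) - (G2_vR + G4_vL)]]

    and ``|F| = 0`` locates the pitchfork along a parameter sweep. The sign
    convention: |F| > 0 on the stable HSS side (with exchange rates
    dominating), crossing to < 0 past the PB. With both exchange rates zero
    the determinant reduces to four times the single-bin Jacobian
    determinant.
    """
    if hss is None:
        u, v = hss_state(model)
    else:
        hss = np.asarray(hss, dtype=float)
        if hss.shape == (2,):
            u, v = hss
        elif hss.shape == (4,):
            if abs(hss[0] - hss[2]) > 1e-8 or abs(hss[1] - hss[3]) > 1e-8:
                raise DomainError("pb_condition requires a symmetric (homogeneous) state")
            u, v = hss[0], hss[1]
        else:
            raise DomainError("hss must be (u, v) or (uL, vL, uR, vR)")

    def G(uL, vL, uR, vR):
        fL = model.params.f_u(uL, vL)
        fR = model.params.f_u(uR, vR)
        return np.array([
            fL - Du_tilde * (uL - uR),
            -fL - Dv_tilde * (vL - vR),
            fR - Du_tilde * (uR - uL),
            -fR - Dv_tilde * (vR - vL),
        ])

    x0 = np.array([u, v, u, v])

    def d(i, j):
        e = np.zeros(4)
        e[j] = h
        return (G(*(x0 + e))[i] - G(*(x0 - e))[i]) / (2 * h)

    F = np.array([
        [(d(0, 0) + d(2, 2)) - (d(0, 2) + d(2, 0)), d(0, 1) + d(2, 3)],
        [d(1, 0) + d(3, 2), (d(1, 1) + d(3, 3)) - (d(1, 3) + d(3, 1))],
    ])
    return float(np.linalg.det(F))


def find_pb_from_condition(model: ModelSpec, c_range: Tuple[float, float] = (2.0, 2.45),
                           Du_tilde: float = DEFAULT_DU_TILDE,
                           Dv_tilde: float = DEFAULT_DV_TILDE, n_scan: int = 200) -> float:
    """c_total at which ``|F_lambda| = 0`` on the HSS branch (brentq on a scan)."""

    def g(c):
        m = model.with_params(c_total=float(c))
        return pb_condition(m, Du_tilde=Du_tilde, Dv_tilde=Dv_tilde)

    cs = np.linspace(c_range[0], c_range[1], n_scan)
    vals = [g(c) for c in cs]
    for a, b, va, vb in zip(cs, cs[1:], vals, vals[1:]):
        if va * vb < 0:
            return float(brentq(g, a, b, xtol=1e-12))
    raise NumericalError(f"|F_lambda| does not change sign on {c_range}")


# ---------------------------------------------------------------------------
# local perturbation analysis


@dataclass
class LpaSystem:
    """Local/global ODE reduction of a slow/fast RD model."""

    model: ModelSpec
    names: Tuple[str, ...]
    rhs: Callable              # rhs(x, param_value) -> dx/dt
    parameter: str

    def global_rhs(self, xg, param_value):
        """The well-mixed subsystem on its own (global variables only)."""
        raise NotImplementedError


def lpa_reduce(model: ModelSpec, s: float = 0.0, parameter: Optional[str] = None) -> LpaSystem:
    """LPA reduction: conserved models -> (u_local, u_global); LEGI -> 5 ODEs.

    Requires the slow/fast diffusivity separation ``Dv >= 10 Du``. For the
    conserved models the bifurcation parameter is ``c_total``; for LEGI a
    kinetic parameter name must be given (the diagram has a single branch
    regardless). A uniform signal ``s`` may be included for LEGI.
    """
    p = model.params
    if model.conserved:
        if not p.Dv >= 10 * p.Du:
            raise ConfigurationError("LPA requires Dv >= 10 Du (slow/fast separation)")
        parameter = parameter or "c_total"
        if parameter != "c_total":
            raise ConfigurationError("conserved-model LPA is parameterised by c_total")

        def rhs(x, c):
            ul, ug = x
            return np.array([p.f_u(ul, c - ug), p.f_u(ug, c - ug)])

        sys = LpaSystem(model=model, names=("u_local", "u_global"), rhs=rhs, parameter="c_total")
        sys.global_rhs = lambda xg, c: np.array([p.f_u(xg[0], c - xg[0])])
        return sys

    if model.name != "legi":
        raise ConfigurationError(f"no LPA reduction for model {model.name!r}")
    if not (p.Dv >= 10 * p.Dw and p.Dv >= 10 * p.Du):
        raise ConfigurationError("LEGI LPA requires the cytosolic inhibitor to be the fast species")
    if parameter is None:
        parameter = "ku"
    valid = {"ku", "k_minus_u", "kv", "k_minus_v", "kw", "k_minus_w", "u_total"}
    if parameter not in valid:
        raise ConfigurationError(f"unknown LEGI parameter {parameter!r}")

    def rhs(x, value):
        from dataclasses import replace as _replace
        q = _replace(p, **{parameter: float(value)})
        wl, wg, vg, ul, ug = x
        return np.array([
            q.f_w(wl) + q.kw * s,
            q.f_w(wg) + q.kw * s,
            q.f_v(vg) + q.kv * s,
            q.f_u(wl, ul, vg),
            q.f_u(wg, ug, vg),
        ])

    sys = LpaSystem(model=model, names=("w_local", "w_global", "v_global", "u_local", "u_global"),
                    rhs=rhs, parameter=parameter)

    def global_rhs(xg, value):
        from dataclasses import replace as _replace
        q = _replace(p, **{parameter: float(value)})
        wg, vg, ug = xg
        return np.array([q.f_w(wg) + q.kw * s, q.f_v(vg) + q.kv * s, q.f_u(wg, ug, vg)])

    sys.global_rhs = global_rhs
    return sys


def _lpa_seeds_conserved(model: ModelSpec, c_values):
    seeds = []
    for c in c_values:
        m = model.with_params(c_total=float(c))
        p = m.params
        roots_g = [row[0] for row in homogeneous_steady_state(m)]
        per_c = []
        for ug in roots_g:
            # local roots of f_u(u_local, c - u_global) at frozen global state
            v = c - ug
            grid = np.linspace(0.0, 2.0 * c, 400)
            vals = p.f_u(grid, v)
            for a, b, va, vb in zip(grid, grid[1:], vals, vals[1:]):
                if va * vb < 0:
                    ul = brentq(lambda u: p.f_u(u, v), a, b, xtol=1e-13)
                    per_c.append(np.array([ul, ug]))
        seeds.append((float(c), per_c))
    return seeds


def continue_lpa(model: ModelSpec, p_range: Tuple[float, float],
                 n_seed_sections: int = 5, **kw) -> BifurcationDiagram:
    """Bifurcation diagram of the LPA reduction over a parameter range.

    Conserved models: vs c_total, seeded from dense scalar root scans; the
    Turing-like kinetics shows a transcritical exchange of stability at
    ``c_total = 1/a2``, the wave-pinning kinetics a bistable local window.
    LEGI: a single branch with no special points.
    """
    sys = lpa_reduce(model)
    f = lambda x, p: sys.rhs(x, p)
    values = np.linspace(p_range[0], p_range[1], n_seed_sections)
    if model.conserved:
        seeds = _lpa_seeds_conserved(model, values)
        is_sym = lambda x, p: abs(x[0] - x[1]) < 1e-6
        # LPA branch points are exchanges along the local direction and are
        # reported as TC; PB/SN_PB classification lives in the two-bin diagram
        breaks = lambda v: False
    else:
        from dataclasses import replace as _replace
        seeds = []
        for val in values:
            q = _replace(model.params, **{sys.parameter: float(val)})
            mm = ModelSpec(name="legi", params=q, n_components=3, conserved=False)
            w, v, u = homogeneous_steady_state(mm)[0]
            seeds.append((float(val), [np.array([w, w, v, u, u])]))
        is_sym = lambda x, p: True
        breaks = lambda v: False
    return _multi_seed_diagram(f, seeds, p_range, sys.parameter,
                               is_symmetric=is_sym, breaks_symmetry=breaks, **kw)


# ---------------------------------------------------------------------------
# regions


@dataclass(frozen=True)
class RegionBoundaries:
    """Located special points bounding the four organisation regions.

    The I/II split is not a bifurcation: region II (criticality / SubPB)
    is the window of relative width ``criticality_window`` just below the
    saddle-node ``c_sn``.
    """

    c_sn: float
    c_pb: float
    criticality_window: float = 0.02

    @property
    def c_ii_low(self) -> float:
        return self.c_sn * (1.0 - self.criticality_window)


def locate_region_boundaries(model: ModelSpec, c_range: Tuple[float, float] = (2.0, 2.4),
                             Du_tilde: float = DEFAULT_DU_TILDE,
                             Dv_tilde: float = DEFAULT_DV_TILDE) -> RegionBoundaries:
    """Locate SN_PB and PB of the two-bin diagram and package the intervals."""
    diag = continue_two_bin(model, c_range, Du_tilde=Du_tilde, Dv_tilde=Dv_tilde)
    sns = diag.points_of("SN_PB")
    pbs = diag.points_of("PB")
    if not sns or not pbs:
        raise NumericalError("could not locate both SN_PB and PB in the given range")
    return RegionBoundaries(c_sn=min(sp.param for sp in sns), c_pb=pbs[0].param)


def classify_region(c_total: float, boundaries: RegionBoundaries) -> str:
    """Region label (I-IV) for a total concentration, by interval lookup."""
    if c_total >= boundaries.c_pb:
        return "IV"
    if c_total >= boundaries.c_sn:
        return "III"
    if c_total >= boundaries.c_ii_low:
        return "II"
    return "I"
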