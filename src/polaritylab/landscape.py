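"""Quasi-potential landscapes from the stationary Fokker-Planck equation.

For the two-bin projection with drift ``(G1, G3)`` on the (uL, uR) plane
and isotropic stochastic transitions of intensity ``D``, the probability
density obeys

    dP/dt = -d(G1 P)/duL - d(G3 P)/duR + D (d^2/duL^2 + d^2/duR^2) P.

The quasi-potential is ``Q = -ln(P_ss)`` of the stationary density.
Attractors are minima of Q; the "ghost" of a vanished saddle-node shows up
as a shallow-slope region that is not a well.

Wells are identified from the Gaussian curvature of the Q surface,

    K = (Qxx Qyy - Qxy^2) / (1 + Qx^2 + Qy^2)^2,

as connected regions with ``K > K_mean + 0.1 K_std`` whose slope
distributions are centred on zero in both directions; every other
positive-curvature region (e.g. the ghost shoulder) is flagged non-well.
A trajectory sample is asymptotic when it lies inside a well with
``Q <= Q_bound`` (the mean quasi-potential on the well's boundary), and
transient otherwise; the ghost dwell is the contiguous slow transient span
after signal removal.

The discretisation is a finite-volume scheme with Scharfetter-Gummel
(exponentially fitted) fluxes and reflecting (zero-flux) boundaries, which
conserves probability exactly and reproduces the Gibbs density of gradient
drifts; the stationary density is obtained directly as the null vector of
the discrete generator (sparse LU), with the pseudo-time path kept for
time-dependent checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Tuple

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .errors import DomainError, NumericalError

__all__ = [
    "QuasiPotentialSurface",
    "Well",
    "TrajectoryClassification",
    "solve_fokker_planck",
    "quasi_potential",
    "gaussian_curvature",
    "asymptotic_regions",
    "classify_trajectory",
    "surface_from_drift",
    "simulate_reduced_sde",
]

DEFAULT_D = 0.02
DEFAULT_H = 0.02
Q_FLOOR = 1e-12


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 - x[small] / 2.0
    xs = x[~small]
    with np.errstate(over="ignore"):
        out[~small] = np.where(xs > 500, 0.0, xs / np.expm1(xs))
    return out


def _generator(drift: Callable, x: np.ndarray, y: np.ndarray, D: float) -> sparse.csr_matrix:
    """Sparse FP generator A with dP/dt = A P, zero-flux boundaries.

    Scharfetter-Gummel face fluxes; every column of A sums to zero, so
    total probability is conserved exactly.
    """
    nx, ny = len(x), len(y)
    h = x[1] - x[0]
    X, Y = np.meshgrid(x, y, indexing="ij")
    gx, gy = drift(X, Y)
    gx = np.broadcast_to(np.asarray(gx, dtype=float), X.shape)
    gy = np.broadcast_to(np.asarray(gy, dtype=float), X.shape)

    # face velocities (midpoint average), Peclet numbers
    vx = 0.5 * (gx[1:, :] + gx[:-1, :]) * h / D      # (nx-1, ny)
    vy = 0.5 * (gy[:, 1:] + gy[:, :-1]) * h / D      # (nx, ny-1)
    # SG flux from cell i to i+1: (D/h) [B(-v) P_i - B(v) P_{i+1}]
    ax = D / h ** 2
    bxm = _bernoulli(-vx) * ax   # out of left cell
    bxp = _bernoulli(vx) * ax    # out of right cell
    bym = _bernoulli(-vy) * ax
    byp = _bernoulli(vy) * ax

    def idx(i, j):
        return i * ny + j

    n = nx * ny
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    I, J = np.meshgrid(np.arange(nx - 1), np.arange(ny), indexing="ij")
    for i, j, outL, outR in zip(I.ravel(), J.ravel(), bxm.ravel(), bxp.ravel()):
        a, b = idx(i, j), idx(i + 1, j)
        add(a, a, -outL); add(b, a, outL)
        add(b, b, -outR); add(a, b, outR)
    I, J = np.meshgrid(np.arange(nx), np.arange(ny - 1), indexing="ij")
    for i, j, outL, outR in zip(I.ravel(), J.ravel(), bym.ravel(), byp.ravel()):
        a, b = idx(i, j), idx(i, j + 1)
        add(a, a, -outL); add(b, a, outL)
        add(b, b, -outR); add(a, b, outR)

    A = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return A


def solve_fokker_planck(drift: Callable, D: float = DEFAULT_D,
                        extent: Tuple[Tuple[float, float], Tuple[float, float]] = ((0.0, 4.5), (0.0, 4.5)),
                        h: float = DEFAULT_H,
                        boundary_tol: float = 1e-8,
                        return_grid: bool = False):
    """Stationary density of the 2-D Fokker-Planck equation.

    Parameters
    ----------
    drift : callable ``(uL, uR) -> (g1, g3)`` accepting arrays.
    D : stochastic-transition intensity (default 0.02).
    extent, h : rectangular grid, spacing ``h`` (default 0.02).
    boundary_tol : maximum admissible probability mass on the outer
        (max-u) boundary cells; more mass raises a grid-extent error. The
        walls at the lower edges are physical (concentrations are
        nonnegative), so mass there is legitimate and not checked.

    Returns
    -------
    ``P_ss`` of shape (nx, ny) normalised so ``sum(P) h^2 = 1`` (plus the
    axes when ``return_grid``). Residual check: ``||A P||_inf`` of the
    discrete generator is verified below 1e-9.
    """
    (x0, x1), (y0, y1) = extent
    x = np.arange(x0, x1 + h / 2, h)
    y = np.arange(y0, y1 + h / 2, h)
    A = _generator(drift, x, y, D)
    n = A.shape[0]
    # replace one balance row by the normalisation to pin the null vector
    k = n // 2
    A_lil = A.tolil()
    A_lil[k, :] = 1.0
    rhs = np.zeros(n)
    rhs[k] = 1.0
    P = spsolve(A_lil.tocsr(), rhs)
    P = np.where(P > 0, P, 0.0)
    P = P / (P.sum() * h * h)
    res = np.max(np.abs(A @ P)) / max(P.max(), 1e-300)
    if res > 1e-7:
        raise NumericalError(f"stationary Fokker-Planck residual too large: {res:.2e}")
    Pg = P.reshape(len(x), len(y))
    edge = (Pg[-1, :].sum() + Pg[:, -1].sum()) * h * h
    if edge > boundary_tol:
        raise DomainError(f"probability mass {edge:.2e} on the boundary; enlarge the grid extent")
    if return_grid:
        return Pg, x, y
    return Pg


def evolve_fokker_planck(drift: Callable, P0: np.ndarray, t_end: float,
                         D: float = DEFAULT_D,
                         extent=((0.0, 4.5), (0.0, 4.5)), h: float = DEFAULT_H,
                         dt: float = 0.5) -> np.ndarray:
    """Pseudo-time integration of the FP equation (implicit Euler steps).

    Probability is conserved to solver accuracy at every step; useful for
    following the relaxation towards ``P_ss``.
    """
    (x0, x1), (y0, y1) = extent
    x = np.arange(x0, x1 + h / 2, h)
    y = np.arange(y0, y1 + h / 2, h)
    A = _generator(drift, x, y, D).tocsc()
    n = A.shape[0]
    M = sparse.identity(n, format="csc") - dt * A
    lu = sparse.linalg.splu(M)
    P = P0.ravel().astype(float).copy()
    t = 0.0
    while t < t_end - 1e-12:
        P = lu.solve(P)
        P = np.where(P > 0, P, 0.0)
        P /= P.sum() * h * h
        t += dt
    return P.reshape(len(x), len(y))


def quasi_potential(P_ss: np.ndarray, floor: float = Q_FLOOR) -> np.ndarray:
    """``Q = -ln(max(P_ss, floor))``; minima of Q are the maxima of P."""
    return -np.log(np.maximum(P_ss, floor))


def gaussian_curvature(Q: np.ndarray, h: float) -> np.ndarray:
    """Gaussian curvature of the surface z = Q(x, y) on a uniform grid.

    Centred differences in the interior, one-sided at the edges
    (``np.gradient`` convention).
    """
    if Q.shape[0] < 5 or Q.shape[1] < 5:
        raise DomainError("grid too small for curvature estimation (need >= 5x5)")
    Qx, Qy = np.gradient(Q, h, h)
    Qxx, Qxy = np.gradient(Qx, h, h)
    _, Qyy = np.gradient(Qy, h, h)
    return (Qxx * Qyy - Qxy ** 2) / (1.0 + Qx ** 2 + Qy ** 2) ** 2


@dataclass
class Well:
    label: int
    minimum: Tuple[float, float]     # (uL, uR) of the Q minimum inside
    Q_min: float
    Q_bound: float
    size: int


@dataclass
class QuasiPotentialSurface:
    """Stationary landscape with its curvature analysis."""

    uL: np.ndarray
    uR: np.ndarray
    P_ss: np.ndarray
    Q: np.ndarray
    K: np.ndarray
    Qx: np.ndarray
    Qy: np.ndarray
    masks: np.ndarray                 # labelled positive-curvature components
    wells: List[Well]
    non_wells: List[int]              # labels of flagged non-well components
    K_mean: float
    K_std: float

    @property
    def h(self) -> float:
        return float(self.uL[1] - self.uL[0])

    def locate(self, uL: float, uR: float) -> Tuple[int, int]:
        i = int(round((uL - self.uL[0]) / self.h))
        j = int(round((uR - self.uR[0]) / self.h))
        if not (0 <= i < len(self.uL) and 0 <= j < len(self.uR)):
            raise DomainError(f"point ({uL:.3f}, {uR:.3f}) outside the landscape grid")
        return i, j


def _contains_interior_minimum(Q: np.ndarray, comp: np.ndarray) -> bool:
    interior = ndimage.binary_erosion(comp)
    ii, jj = np.nonzero(interior)
    for i, j in zip(ii, jj):
        if 0 < i < Q.shape[0] - 1 and 0 < j < Q.shape[1] - 1:
            if Q[i, j] <= Q[i - 1:i + 2, j - 1:j + 2].min():
                return True
    return False


def asymptotic_regions(uL: np.ndarray, uR: np.ndarray, P_ss: np.ndarray,
                       slope_tol_factor: float = 1.5,
                       floor: float = Q_FLOOR) -> QuasiPotentialSurface:
    """Identify wells (asymptotic regions) of a quasi-potential landscape.

    Positive-curvature regions are ``K > K_mean + 0.1 K_std``; a connected
    component is a well iff the slopes inside it are distributed around
    zero in both directions. Operationally that requires (i) a strict local
    minimum of Q in the component's interior (the slope field changes sign
    through the component along both axes) and (ii) per-direction slope
    samples with ``|mean| <= slope_tol_factor * std`` within the component.
    One-sided-slope shoulders -- the "ghost" remnants -- fail (i)/(ii) and
    are flagged non-well. ``Q_bound`` of a well is the mean Q on the
    component's boundary layer. An empty result is legal (e.g. a monotone
    landscape) and returned with every component flagged non-well.

    All statistics are taken over the landscape's support (cells with
    ``P_ss`` above the floor): outside it Q saturates at the floor value
    and the saturation ring carries spurious curvature that would otherwise
    dominate the threshold.
    """
    h = float(uL[1] - uL[0])
    Q = quasi_potential(P_ss, floor)
    Qx, Qy = np.gradient(Q, h, h)
    K = gaussian_curvature(Q, h)
    support = P_ss > floor
    if not support.any():
        support = np.ones_like(P_ss, dtype=bool)
    K_mean, K_std = float(K[support].mean()), float(K[support].std())
    pos = (K > K_mean + 0.1 * K_std) & support
    labels, n_comp = ndimage.label(pos)
    wells: List[Well] = []
    non_wells: List[int] = []
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        rx = abs(float(Qx[comp].mean())) / max(float(Qx[comp].std()), 1e-12)
        ry = abs(float(Qy[comp].mean())) / max(float(Qy[comp].std()), 1e-12)
        if rx <= slope_tol_factor and ry <= slope_tol_factor and _contains_interior_minimum(Q, comp):
            interior = ndimage.binary_erosion(comp)
            ring = comp & ~interior
            if not ring.any():
                ring = comp
            qb = float(Q[ring].mean())
            i, j = np.unravel_index(np.argmin(np.where(comp, Q, np.inf)), Q.shape)
            wells.append(Well(label=lab, minimum=(float(uL[i]), float(uR[j])),
                              Q_min=float(Q[i, j]), Q_bound=qb, size=int(comp.sum())))
        else:
            non_wells.append(lab)
    return QuasiPotentialSurface(uL=uL, uR=uR, P_ss=P_ss, Q=Q, K=K, Qx=Qx, Qy=Qy,
                                 masks=labels, wells=wells, non_wells=non_wells,
                                 K_mean=K_mean, K_std=K_std)


def surface_from_drift(drift: Callable, D: float = DEFAULT_D,
                       extent=((0.0, 4.5), (0.0, 4.5)), h: float = DEFAULT_H,
                       slope_tol_factor: float = 1.5) -> QuasiPotentialSurface:
    """Convenience: stationary FP solve + curvature/well analysis."""
    P, x, y = solve_fokker_planck(drift, D=D, extent=extent, h=h, return_grid=True)
    return asymptotic_regions(x, y, P, slope_tol_factor=slope_tol_factor)


@dataclass
class TrajectoryClassification:
    """Per-sample asymptotic/transient labels for one signal epoch."""

    times: np.ndarray
    labels: np.ndarray               # "asymptotic" | "transient"
    well_index: np.ndarray           # index into surface.wells, -1 outside
    speed: np.ndarray
    ghost_dwell: float               # s, contiguous slow transient span
    dwell: Dict[str, float]


def classify_trajectory(times: np.ndarray, points: np.ndarray,
                        surface: QuasiPotentialSurface,
                        v_slow_factor: float = 0.1) -> TrajectoryClassification:
    """Label trajectory samples as asymptotic (inside a well, below its
    ``Q_bound``) or transient, and measure the ghost dwell.

    ``points`` is (T, 2) in the (uL, uR) plane, sampled at ``times`` within
    one signal epoch (the landscape must belong to that epoch). The ghost
    dwell is the longest contiguous transient span whose speed stays below
    ``v_slow_factor`` times the epoch's peak speed. (The peak, rather than
    the median, anchors the slowness scale: an epoch that ends at rest on
    an attractor has a near-zero median speed, which would make every
    threshold degenerate.)
    """
    times = np.asarray(times, dtype=float)
    points = np.asarray(points, dtype=float)
    T = len(times)
    labels = np.empty(T, dtype=object)
    well_index = np.full(T, -1, dtype=int)
    vel = np.gradient(points, times, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    for k in range(T):
        i, j = surface.locate(points[k, 0], points[k, 1])
        lab = surface.masks[i, j]
        asym = False
        for wi, w in enumerate(surface.wells):
            if lab == w.label and surface.Q[i, j] <= w.Q_bound + 1e-12:
                asym = True
                well_index[k] = wi
                break
        labels[k] = "asymptotic" if asym else "transient"

    v_slow = v_slow_factor * float(speed.max())
    ghost = 0.0
    run_start = None
    for k in range(T):
        if labels[k] == "transient" and speed[k] < v_slow:
            if run_start is None:
                run_start = times[k]
            ghost = max(ghost, times[k] - run_start)
        else:
            run_start = None
    dt = np.gradient(times)
    dwell = {
        "asymptotic": float(dt[labels == "asymptotic"].sum()),
        "transient": float(dt[labels == "transient"].sum()),
    }
    return TrajectoryClassification(times=times, labels=labels, well_index=well_index,
                                    speed=speed, ghost_dwell=float(ghost), dwell=dwell)


def simulate_reduced_sde(drift: Callable, D: float, x0: Tuple[float, float],
                         t_end: float, dt: float = 0.01, seed: int = 0,
                         clip_min: float = 0.0,
                         record_every: int = 10) -> np.ndarray:
    """Euler-Maruyama sample path of the 2-D SDE matching the FP equation,
    ``dx = g(x) dt + sqrt(2 D) dW`` (for histogram-vs-P_ss checks)."""
    rng = np.random.default_rng(seed)
    n = int(round(t_end / dt))
    out = np.empty((n // record_every + 1, 2))
    x = np.array(x0, dtype=float)
    out[0] = x
    amp = np.sqrt(2.0 * D * dt)
    m = 0
    for k in range(1, n + 1):
        g1, g3 = drift(x[0], x[1])
        x[0] += g1 * dt + amp * rng.standard_normal()
        x[1] += g3 * dt + amp * rng.standard_normal()
        np.clip(x, clip_min, None, out=x)
        if k % record_every == 0:
            m += 1
            out[m] = x
    return out[:m + 1]
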