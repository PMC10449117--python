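"""Compiled method-of-lines right-hand sides.

One kernel per kinetics family, compiled once per process with numba.
Each implements exactly the same arithmetic as the numpy path in
``rd_sim.discretize`` (centred periodic Laplacian + reaction + signal
coupling); ``rd_sim`` falls back to the numpy path when numba is absent.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def wp_rhs(y, s, N, dth2, k0, gamma, K, delta, hill, Du, Dv):
    out = np.empty_like(y)
    for i in range(N):
        ip = i + 1 if i + 1 < N else 0
        im = i - 1 if i > 0 else N - 1
        u = y[i]
        v = y[N + i]
        uh = u ** hill
        fu = (k0 + gamma * uh / (K ** hill + uh)) * v - delta * u + s[i] * v
        lap_u = (y[ip] - 2.0 * u + y[im]) / dth2
        lap_v = (y[N + ip] - 2.0 * v + y[N + im]) / dth2
        out[i] = fu + Du * lap_u
        out[N + i] = -fu + Dv * lap_v
    return out


@njit(cache=True)
def turing_rhs(y, s, N, dth2, a1, a2, Du, Dv):
    out = np.empty_like(y)
    for i in range(N):
        ip = i + 1 if i + 1 < N else 0
        im = i - 1 if i > 0 else N - 1
        u = y[i]
        v = y[N + i]
        z = u + v
        fu = a1 * (v - z / (a2 * z + 1.0) ** 2) + s[i] * v
        lap_u = (y[ip] - 2.0 * u + y[im]) / dth2
        lap_v = (y[N + ip] - 2.0 * v + y[N + im]) / dth2
        out[i] = fu + Du * lap_u
        out[N + i] = -fu + Dv * lap_v
    return out


@njit(cache=True)
def legi_rhs(y, s, N, dth2, ku, kmu, kv, kmv, kw, kmw, u_total, Dw, Dv, Du):
    # component order (w, v, u) matches ModelSpec.component_names
    out = np.empty_like(y)
    for i in range(N):
        ip = i + 1 if i + 1 < N else 0
        im = i - 1 if i > 0 else N - 1
        w = y[i]
        v = y[N + i]
        u = y[2 * N + i]
        out[i] = -kmw * w + kw * s[i] + Dw * (y[ip] - 2.0 * w + y[im]) / dth2
        out[N + i] = -kmv * v + kv * s[i] + Dv * (y[N + ip] - 2.0 * v + y[N + im]) / dth2
        out[2 * N + i] = ku * w * (u_total - u) - kmu * v * u + Du * (y[2 * N + ip] - 2.0 * u + y[2 * N + im]) / dth2
    return out
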