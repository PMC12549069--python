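"""Numba-compiled inner loops: deterministic RK4 probes of the planar fast
subsystem and the Euler-Maruyama integrator of the coupled fast-slow system.

Paths through parameter space are passed to the integrator as arrays
describing a sequence of circular arcs on the parameter sphere: arc ``j``
covers slow-variable values ``z`` in ``[arc_z0[j], arc_z1[j]]`` and maps
``z`` to the 3-vector ``C[j] + r[j]*(cos(a)*U[j] + sin(a)*V[j])`` with
``a = z - arc_z0[j]``; the vector axes are ``(mu2, -mu1, nu)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "rk4_fast_traj",
    "stable_rest_root",
    "em_loop",
]


@njit(cache=True)
def _cubic_real_roots_nb(mu1, mu2):
    """Real roots of x^3 - mu2*x - mu1, ascending.  Returns (roots[3], count)."""
    p = -mu2
    q = -mu1
    out = np.empty(3)
    disc = -4.0 * p * p * p - 27.0 * q * q
    if disc > 0.0:
        # three real roots (trigonometric form); requires p < 0
        m = 2.0 * np.sqrt(-p / 3.0)
        arg = 3.0 * q / (p * m)
        if arg > 1.0:
            arg = 1.0
        elif arg < -1.0:
            arg = -1.0
        theta = np.arccos(arg) / 3.0
        for k in range(3):
            out[k] = m * np.cos(theta - 2.0 * np.pi * k / 3.0)
        out.sort()
        return out, 3
    # single real root (Cardano)
    half_q = 0.5 * q
    rad = half_q * half_q + p * p * p / 27.0
    if rad < 0.0:
        rad = 0.0
    s = np.sqrt(rad)
    u = -half_q + s
    v = -half_q - s
    cu = np.sign(u) * np.abs(u) ** (1.0 / 3.0)
    cv = np.sign(v) * np.abs(v) ** (1.0 / 3.0)
    out[0] = cu + cv
    # one Newton polish
    for _ in range(2):
        f = out[0] ** 3 + p * out[0] + q
        fp = 3.0 * out[0] ** 2 + p
        if np.abs(fp) > 1e-12:
            out[0] -= f / fp
    return out, 1


@njit(cache=True)
def stable_rest_root(mu1, mu2, nu, x_prev):
    """x-location of the resting equilibrium used by the hysteresis drift.

    Picks the stable root (det > 0 and trace < 0) of the fixed-point cubic
    nearest to ``x_prev``; when no stable root exists (the rest state has
    been annihilated, e.g. past a saddle-node) the previous value is retained
    -- the drift keeps measuring distance from the ghost of the resting
    equilibrium.  Jumping the reference to the surviving (unstable) root
    instead would flip the drift sign the instant the fold is crossed and
    pin the slow variable on the onset curve before the fast escape from the
    saddle-node ghost can develop.
    """
    roots, n = _cubic_real_roots_nb(mu1, mu2)
    best = x_prev
    best_d = 1e300
    for i in range(n):
        x = roots[i]
        det = 3.0 * x * x - mu2
        tr = -(nu + x + x * x)
        if det > 0.0 and tr < 0.0:
            d = np.abs(x - x_prev)
            if d < best_d:
                best_d = d
                best = x
    return best


@njit(cache=True)
def rk4_fast_traj(mu1, mu2, nu, x0, y0, dt, n):
    """Deterministic RK4 trajectory of the planar fast subsystem (fixed
    parameters).  Used by the region/criticality probes."""
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    xs[0] = x0
    ys[0] = y0
    x = x0
    y = y0
    for i in range(n):
        k1x = -y
        k1y = x**3 - mu2 * x - mu1 - y * (nu + x + x * x)
        x2 = x + 0.5 * dt * k1x
        y2 = y + 0.5 * dt * k1y
        k2x = -y2
        k2y = x2**3 - mu2 * x2 - mu1 - y2 * (nu + x2 + x2 * x2)
        x3 = x + 0.5 * dt * k2x
        y3 = y + 0.5 * dt * k2y
        k3x = -y3
        k3y = x3**3 - mu2 * x3 - mu1 - y3 * (nu + x3 + x3 * x3)
        x4 = x + dt * k3x
        y4 = y + dt * k3y
        k4x = -y4
        k4y = x4**3 - mu2 * x4 - mu1 - y4 * (nu + x4 + x4 * x4)
        x = x + dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        y = y + dt * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
        if np.abs(x) > 1e3 or np.abs(y) > 1e3:
            xs[i + 1 :] = x
            ys[i + 1 :] = y
            return xs, ys
        xs[i + 1] = x
        ys[i + 1] = y
    return xs, ys


@njit(cache=True)
def _path_params(zz, arc_z0, arc_z1, C, U, V, r, closed, period):
    """Evaluate (mu1, mu2, nu) on the arc sequence at slow value ``zz``."""
    if closed:
        zz = arc_z0[0] + ((zz - arc_z0[0]) % period)
    else:
        if zz < arc_z0[0]:
            zz = arc_z0[0]
        elif zz > arc_z1[-1]:
            zz = arc_z1[-1]
    j = 0
    for k in range(arc_z0.shape[0]):
        if zz <= arc_z1[k] or k == arc_z0.shape[0] - 1:
            j = k
            break
    a = zz - arc_z0[j]
    ca = np.cos(a)
    sa = np.sin(a)
    px = C[j, 0] + r[j] * (ca * U[j, 0] + sa * V[j, 0])
    py = C[j, 1] + r[j] * (ca * U[j, 1] + sa * V[j, 1])
    pz = C[j, 2] + r[j] * (ca * U[j, 2] + sa * V[j, 2])
    # axes are (mu2, -mu1, nu)
    return -py, px, pz


@njit(cache=True)
def em_loop(
    x0,
    y0,
    z0,
    n,
    tstep,
    k_fast,
    arc_z0,
    arc_z1,
    C,
    U,
    V,
    r,
    closed,
    period,
    slow_kind,  # 0 hysteresis, 1 slow wave, 2 piecewise
    c_slow,
    dstar,
    k_slow,
    t_breaks,  # piecewise: segment end times (ascending); speeds per segment
    seg_speeds,
    noise,  # sigma-scaled pink-noise increments, length n
):
    """Euler-Maruyama integration of the coupled fast-slow system.

    Per step: ``state += tstep*drift + tstep*(noise, 0, 0)`` -- the stochastic
    term enters the fast variable x only and is scaled by ``tstep`` exactly as
    in the model's printed update rule.  Returns ``(x, y, z, err)`` where
    ``err`` is -1 on success or the step index at which |x| or |y| exceeded
    the blow-up bound 1e3.
    """
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    zs = np.empty(n + 1)
    xs[0] = x0
    ys[0] = y0
    zs[0] = z0
    track_x = x0
    if slow_kind == 0:
        mu1, mu2, nu = _path_params(z0, arc_z0, arc_z1, C, U, V, r, closed, period)
        track_x = stable_rest_root(mu1, mu2, nu, x0)
    seg = 0
    for i in range(n):
        x = xs[i]
        y = ys[i]
        z = zs[i]
        mu1, mu2, nu = _path_params(z, arc_z0, arc_z1, C, U, V, r, closed, period)
        dx = k_fast * (-y)
        dy = k_fast * (x**3 - mu2 * x - mu1 - y * (nu + x + x * x))
        if slow_kind == 0:
            xr = stable_rest_root(mu1, mu2, nu, track_x)
            track_x = xr
            dist = np.sqrt((x - xr) ** 2 + y * y)
            dz = -c_slow * (dist - dstar)
        elif slow_kind == 1:
            dz = k_slow
        else:
            t = i * tstep
            while seg < t_breaks.shape[0] - 1 and t >= t_breaks[seg]:
                seg += 1
            dz = seg_speeds[seg] if t < t_breaks[seg] else 0.0
        xs[i + 1] = x + tstep * dx + tstep * noise[i]
        ys[i + 1] = y + tstep * dy
        zs[i + 1] = z + tstep * dz
        if np.abs(xs[i + 1]) > 1e3 or np.abs(ys[i + 1]) > 1e3:
            return xs[: i + 2], ys[: i + 2], zs[: i + 2], i
    return xs, ys, zs, -1
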