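"""Planar fast subsystem of the fast-slow seizure burster.

The fast subsystem is a Liénard-type planar vector field

    dx/dt = -y
    dy/dt = x^3 - mu2*x - mu1 - y*(nu + x + x^2)

whose fixed points lie on ``y = 0`` at the real roots of the cubic
``x^3 - mu2*x - mu1``.  The three parameters ``(mu1, mu2, nu)`` select the
local phase portrait: depending on their values the subsystem has one to
three equilibria and may support a stable limit cycle (the bursting /
"seizure" state).  Local bifurcations of equilibria are a saddle-node
(double root of the cubic, discriminant ``4*mu2^3 - 27*mu1^2 = 0``) and a
Hopf (Jacobian trace ``-(nu + x + x^2)`` crossing zero at an equilibrium
with positive determinant ``3*x^2 - mu2``).

Everything in this module is pure computation on a single parameter point;
the spherical parameter map and the slow dynamics live in
:mod:`dynamotypes.sphere` and :mod:`dynamotypes.paths`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "FastState",
    "PlanarParams",
    "FixedPointInfo",
    "rhs_fast",
    "jacobian",
    "fixed_points",
    "sn_residual",
    "hopf_points",
    "hopf_criticality",
    "first_lyapunov_sign",
]

#: roots of the fixed-point cubic closer than this are merged and the merged
#: point is reported as non-hyperbolic (it sits at/near a saddle-node).  The
#: companion-matrix solver splits an exact double root by ~sqrt(machine eps),
#: so the merge window must sit above that.
ROOT_MERGE_TOL = 1e-7

#: |trace| or |det| below this at a fixed point marks it non-hyperbolic.
HYPERBOLICITY_TOL = 1e-9


@dataclass(frozen=True)
class FastState:
    """State of the fast subsystem: ``x`` is the voltage-like variable that is
    exported as the simulated EEG trace, ``y`` the recovery variable."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite fast state ({self.x}, {self.y})")


@dataclass(frozen=True)
class PlanarParams:
    """A point ``(mu1, mu2, nu)`` in the fast-subsystem parameter space."""

    mu1: float
    mu2: float
    nu: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.mu1, self.mu2, self.nu))):
            raise ValueError(
                f"non-finite parameters ({self.mu1}, {self.mu2}, {self.nu})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.nu], dtype=float)


@dataclass(frozen=True)
class FixedPointInfo:
    """A classified equilibrium of the fast subsystem.

    ``kind`` is one of ``stable node``, ``stable spiral``, ``unstable node``,
    ``unstable spiral``, ``saddle`` or ``non-hyperbolic``.  Non-hyperbolic
    points (zero-real-part eigenvalue, or a merged near-double root) mark
    bifurcations and are never silently folded into the stable/unstable kinds.
    """

    location: FastState
    eigenvalues: tuple[complex, complex]
    kind: str

    @property
    def is_stable(self) -> bool:
        return self.kind in ("stable node", "stable spiral")

    @property
    def is_saddle(self) -> bool:
        return self.kind == "saddle"


def rhs_fast(
    state: FastState, params: PlanarParams, k_fast: float = 1.0
) -> tuple[float, float]:
    """Time derivatives ``(dx/dt, dy/dt)`` of the fast subsystem.

    ``k_fast`` multiplies both equations uniformly -- a pure rescaling of the
    fast clock that preserves all bifurcation structure; ``k_fast = 1``
    reproduces the model literally.
    """
    if not (math.isfinite(k_fast) and k_fast > 0):
        raise ValueError(f"k_fast must be a positive finite rate, got {k_fast}")
    x, y = state.x, state.y
    dx = -y
    dy = x**3 - params.mu2 * x - params.mu1 - y * (params.nu + x + x**2)
    return (k_fast * dx, k_fast * dy)


def jacobian(state: FastState, params: PlanarParams) -> np.ndarray:
    """Jacobian of the fast vector field at an arbitrary state."""
    x, y = state.x, state.y
    return np.array(
        [
            [0.0, -1.0],
            [3.0 * x**2 - params.mu2 - y * (1.0 + 2.0 * x),
             -(params.nu + x + x**2)],
        ]
    )


def sn_residual(params: PlanarParams) -> float:
    """Signed discriminant ``4*mu2^3 - 27*mu1^2`` of the fixed-point cubic.

    Zero iff the cubic has a repeated root, i.e. the parameters sit on the
    saddle-node locus of equilibria.
    """
    return 4.0 * params.mu2**3 - 27.0 * params.mu1**2


def _cubic_real_roots(mu1: float, mu2: float) -> np.ndarray:
    """Real roots of ``x^3 - mu2*x - mu1`` via the companion matrix, polished
    by one Newton step and merged when closer than ``ROOT_MERGE_TOL``.

    Returns ``(roots, merged_flags)`` where merged roots are near-double.
    """
    roots = np.roots([1.0, 0.0, -mu2, -mu1])
    real = np.sort(roots[np.abs(roots.imag) < 1e-7].real)
    if len(real) == 3 and np.min(np.diff(real)) < ROOT_MERGE_TOL:
        # near-double root: use the exact factorization x^3 - mu2 x - mu1 =
        # (x - xd)^2 (x + 2 xd) with xd = cbrt(-mu1/2) (root sum is zero)
        xd = float(np.cbrt(-mu1 / 2.0))
        return np.sort(np.array([xd, xd, -2.0 * xd]))
    # Newton polish (guarded: skip where derivative is tiny, i.e. near-double)
    for _ in range(2):
        f = real**3 - mu2 * real - mu1
        fp = 3.0 * real**2 - mu2
        mask = np.abs(fp) > 1e-6
        real[mask] -= f[mask] / fp[mask]
    return np.sort(real)


def _classify_eigenvalues(eig: np.ndarray, degenerate: bool) -> str:
    re = eig.real
    im = eig.imag
    if degenerate or np.any(np.abs(re) < HYPERBOLICITY_TOL):
        return "non-hyperbolic"
    spiral = np.any(np.abs(im) > HYPERBOLICITY_TOL)
    if np.all(re < 0):
        return "stable spiral" if spiral else "stable node"
    if np.all(re > 0):
        return "unstable spiral" if spiral else "unstable node"
    return "saddle"


def fixed_points(params: PlanarParams) -> list[FixedPointInfo]:
    """All equilibria of the fast subsystem at ``params``.

    Returns one to three entries, each at ``y = 0`` on a real root of the
    cubic, classified by the eigenvalues of the Jacobian.  Roots closer than
    ``ROOT_MERGE_TOL`` are merged and reported as a single non-hyperbolic
    point (a saddle-node of equilibria).
    """
    roots = _cubic_real_roots(params.mu1, params.mu2)
    out: list[FixedPointInfo] = []
    i = 0
    while i < len(roots):
        j = i
        while j + 1 < len(roots) and roots[j + 1] - roots[j] < ROOT_MERGE_TOL:
            j += 1
        x = float(np.mean(roots[i : j + 1]))
        degenerate = j > i
        loc = FastState(x, 0.0)
        eig = np.linalg.eigvals(jacobian(loc, params))
        kind = _classify_eigenvalues(eig, degenerate)
        out.append(FixedPointInfo(loc, (complex(eig[0]), complex(eig[1])), kind))
        i = j + 1
    return out


def _hopf_test_fn(params: PlanarParams) -> list[tuple[float, float]]:
    """Per fixed point with det > 0, the trace value (Hopf test function).

    Returns ``(x, trace)`` pairs; a Hopf occurs where the trace crosses zero.
    """
    out = []
    for fp in fixed_points(params):
        x = fp.location.x
        det = 3.0 * x**2 - params.mu2
        if det > HYPERBOLICITY_TOL:
            out.append((x, -(params.nu + x + x**2)))
    return out


def _post_hopf_amplitude(
    params: PlanarParams,
    x_hopf: float,
    d: np.ndarray,
    delta: float,
    dt: float,
    horizon: float,
) -> float:
    """Asymptotic oscillation amplitude a distance ``delta`` past a Hopf
    crossing along unit direction ``d`` (raises if the perturbation decays,
    i.e. the direction does not point to the unstable side)."""
    from ._kernels import rk4_fast_traj  # local import to avoid cycles

    p = PlanarParams(
        params.mu1 + delta * d[0],
        params.mu2 + delta * d[1],
        params.nu + delta * d[2],
    )
    roots = _cubic_real_roots(p.mu1, p.mu2)
    x0 = float(roots[np.argmin(np.abs(roots - x_hopf))])
    n = int(horizon / dt)
    xs, _ = rk4_fast_traj(p.mu1, p.mu2, p.nu, x0 + 1e-3, 0.0, dt, n)
    tail = xs[int(0.75 * n) :]
    amp = float(tail.max() - tail.min())
    if amp < 1e-5:
        raise ValueError("criticality probe decayed; direction not unstable side")
    return amp


def hopf_criticality(
    params: PlanarParams,
    x_hopf: float,
    direction: Sequence[float],
    delta: float = 1e-2,
    dt: float = 1e-2,
    horizon: float = 12000.0,
    ratio_threshold: float = 1.5,
) -> int:
    """Numerically probe whether a Hopf crossing is super- or subcritical.

    Steps the parameters past the crossing along ``direction`` (which must
    point to the unstable side, i.e. trace > 0) at two distances, ``delta``
    and ``delta/4``, integrates from a small perturbation of the equilibrium
    and compares the asymptotic oscillation amplitudes.  At a supercritical
    Hopf the stable cycle's amplitude scales as the square root of the
    distance past the crossing, so the amplitude ratio approaches 2; at a
    subcritical Hopf the trajectory escapes to a pre-existing finite-
    amplitude attractor whose size barely changes, giving a ratio near 1.
    Returns -1 (supercritical) when the ratio exceeds ``ratio_threshold``,
    else +1 (subcritical).

    The probe is deterministic; it avoids any symbolic Lyapunov-coefficient
    derivation and is itself cross-checked in the test suite against the
    closed-form first Lyapunov quantity of this vector field.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    amp_far = _post_hopf_amplitude(params, x_hopf, d, delta, dt, horizon)
    amp_near = _post_hopf_amplitude(params, x_hopf, d, delta / 4, dt, horizon)
    return -1 if amp_far / amp_near > ratio_threshold else +1


def first_lyapunov_sign(params: PlanarParams, x_hopf: float) -> int:
    """Closed-form sign of the first Lyapunov quantity at a Hopf point of
    this vector field: ``sign(6*x0*(1+2*x0)/omega^2 - 2)`` with
    ``omega^2 = 3*x0^2 - mu2`` (negative = supercritical).  Exposed as an
    independent cross-check of :func:`hopf_criticality`."""
    omega2 = 3.0 * x_hopf**2 - params.mu2
    if omega2 <= 0:
        raise ValueError("not a Hopf point: nonpositive determinant")
    a = 6.0 * x_hopf * (1.0 + 2.0 * x_hopf) / omega2 - 2.0
    return -1 if a < 0 else +1


def hopf_points(
    params_slice: Callable[[float], PlanarParams] | Iterable[PlanarParams],
    s_grid: Sequence[float] | None = None,
    refine_tol: float = 1e-10,
    classify: bool = True,
) -> list[tuple[FixedPointInfo, int]]:
    """Locate Hopf bifurcations along a one-parameter slice.

    ``params_slice`` is either a callable ``s -> PlanarParams`` (with
    ``s_grid`` the scan grid) or a finite sequence of parameter points (scanned
    with ``s`` the index).  A Hopf is reported where the Jacobian trace at a
    determinant-positive fixed point crosses zero; the crossing is refined by
    bisection in ``s``.  The second tuple element is the sign of the first
    Lyapunov quantity from the numerical probe (-1 supercritical,
    +1 subcritical, 0 when ``classify`` is off or the probe is inconclusive).

    Returns an empty list when no crossing occurs on the slice.
    """
    if callable(params_slice):
        if s_grid is None:
            raise ValueError("s_grid required with a callable slice")
        fn = params_slice
        grid = list(map(float, s_grid))
    else:
        pts = list(params_slice)
        fn = lambda s: pts[int(round(s))]  # noqa: E731
        grid = list(range(len(pts)))

    found: list[tuple[FixedPointInfo, int]] = []
    prev = _hopf_test_fn(fn(grid[0]))
    for s0, s1 in zip(grid[:-1], grid[1:]):
        cur = _hopf_test_fn(fn(s1))
        for x_p, tr_p in prev:
            # match fixed points between grid steps by continuity in x
            if not cur:
                continue
            k = int(np.argmin([abs(x_c - x_p) for x_c, _ in cur]))
            x_c, tr_c = cur[k]
            if abs(x_c - x_p) > 0.5 or tr_p == 0.0 or tr_p * tr_c > 0:
                continue
            lo, hi = s0, s1
            tr_lo = tr_p
            x_ref = x_p
            for _ in range(200):
                if hi - lo < refine_tol:
                    break
                mid = 0.5 * (lo + hi)
                cand = _hopf_test_fn(fn(mid))
                if not cand:
                    break
                kk = int(np.argmin([abs(x - x_ref) for x, _ in cand]))
                x_ref, tr_mid = cand[kk]
                if tr_lo * tr_mid <= 0:
                    hi = mid
                else:
                    lo, tr_lo = mid, tr_mid
            s_star = 0.5 * (lo + hi)
            p_star = fn(s_star)
            fps = fixed_points(p_star)
            fp = min(fps, key=lambda f: abs(f.location.x - x_ref))
            sign = 0
            if classify:
                # unstable side of the crossing: where the trace is positive
                unstable_s = s1 if tr_c > 0 else s0
                d = fn(unstable_s).as_array() - p_star.as_array()
                if np.linalg.norm(d) > 0:
                    try:
                        sign = hopf_criticality(p_star, fp.location.x, d)
                    except ValueError:
                        sign = 0
            found.append((fp, sign))
        prev = cur
    return found
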