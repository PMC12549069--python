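"""Spherical parameter-space map of the fast subsystem.

Without loss of generality the three fast-subsystem parameters are restricted
to a sphere of small radius ``R`` with Cartesian axes ``(mu2, -mu1, nu)``.
Bifurcation curves partition the spherical surface into regions where the
fast subsystem is at rest (stable equilibrium only), bursting (stable limit
cycle only) or bistable (both).  This module locates those curves:

* local curves semi-analytically -- the saddle-node (SN) locus is the zero
  set of the cubic discriminant ``4*mu2^3 - 27*mu1^2`` and the Hopf locus the
  zero set of the Jacobian trace at a determinant-positive equilibrium, both
  restricted to the sphere;
* global curves (SNIC, SH, FLC) by deterministic simulation probes and
  bisection of the limit-cycle existence boundary, since they involve global
  objects (invariant circles, homoclinic orbits, folds of cycles) with no
  closed-form test function.

Because the global search is expensive, located curve sets are cached as
plain-text tables (CSV + JSON sidecar); a prebuilt cache for the default
sphere ships with the package.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

from ._kernels import rk4_fast_traj
from .model import (
    PlanarParams,
    fixed_points,
    hopf_criticality,
    sn_residual,
)

__all__ = [
    "SpherePoint",
    "RegionLabel",
    "ProbeSettings",
    "UnclassifiedRegionError",
    "BifurcationCurve",
    "CurveSet",
    "embed",
    "unembed",
    "classify_region",
    "probe_attractors",
    "locate_local_curves",
    "locate_global_curves",
    "build_curve_set",
    "sample_anchor",
    "load_packaged_curves",
]

DEFAULT_RADIUS = 0.4
DEFAULT_RESOLUTION = 0.05  # radians of central angle between adjacent samples

_DATA_DIR = Path(__file__).parent / "data"


# --------------------------------------------------------------------------
# sphere geometry


@dataclass(frozen=True)
class SpherePoint:
    """A point on the parameter sphere in colatitude/longitude coordinates.

    ``theta`` is the colatitude from the ``+nu`` pole (radians), ``phi`` the
    longitude from the ``+mu2`` axis toward the ``-mu1`` axis, and ``R`` the
    sphere radius.
    """

    theta: float
    phi: float
    R: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if not (math.isfinite(self.R) and self.R > 0):
            raise ValueError(f"sphere radius must be positive, got {self.R}")

    def vector(self) -> np.ndarray:
        """Cartesian embedding on axes ``(mu2, -mu1, nu)``."""
        st = math.sin(self.theta)
        return self.R * np.array(
            [st * math.cos(self.phi), st * math.sin(self.phi), math.cos(self.theta)]
        )

    def params(self) -> PlanarParams:
        x, y, z = self.vector()
        return PlanarParams(mu1=-y, mu2=x, nu=z)

    @staticmethod
    def from_vector(vec: np.ndarray, R: float | None = None) -> "SpherePoint":
        v = np.asarray(vec, dtype=float)
        r = float(np.linalg.norm(v)) if R is None else R
        return SpherePoint(
            theta=float(np.arccos(np.clip(v[2] / r, -1.0, 1.0))),
            phi=float(np.arctan2(v[1], v[0]) % (2 * np.pi)),
            R=r,
        )

    @staticmethod
    def from_params(params: PlanarParams) -> "SpherePoint":
        return SpherePoint.from_vector(
            np.array([params.mu2, -params.mu1, params.nu])
        )

    def angle_to(self, other: "SpherePoint") -> float:
        """Central angle (radians) between two points on the same sphere."""
        a = self.vector() / self.R
        b = other.vector() / other.R
        return float(np.arccos(np.clip(a @ b, -1.0, 1.0)))


def embed(point: SpherePoint) -> PlanarParams:
    """Spherical-to-Cartesian embedding of a sphere point onto the parameter
    axes ``(mu2, -mu1, nu)``."""
    return point.params()


def unembed(params: PlanarParams) -> SpherePoint:
    """Inverse of :func:`embed` (undefined at the poles' longitude)."""
    return SpherePoint.from_params(params)


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation between Cartesian vectors of equal norm."""
    r = np.linalg.norm(a)
    ua, ub = a / r, b / np.linalg.norm(b)
    omega = np.arccos(np.clip(ua @ ub, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return r * (
        np.sin((1 - t) * omega) * ua + np.sin(t * omega) * ub
    ) / np.sin(omega)


# --------------------------------------------------------------------------
# attractor probes


class RegionLabel(str, Enum):
    REST = "rest"
    BURSTING = "bursting"
    BISTABLE = "bistable"


class UnclassifiedRegionError(RuntimeError):
    """Raised when the deterministic probe finds no attractor within its
    horizon: the caller must not silently guess a region label."""


@dataclass(frozen=True)
class ProbeSettings:
    """Deterministic attractor-probe protocol.

    A probe integrates the fast subsystem with RK4 from a fixed set of
    initial conditions: one near each unstable equilibrium (which spirals out
    to a limit cycle when one exists) plus two fixed outer states that fall
    inward onto any large cycle.  The first half of each trajectory is
    discarded as transient; a sustained oscillation in the remainder counts
    as a stable limit cycle.
    """

    dt: float = 0.01
    n_steps: int = 30_000
    outer_ics: tuple[tuple[float, float], ...] = ((1.5, 0.0), (-1.5, 0.0))
    fp_perturbation: float = 0.01
    amp_tol: float = 1e-3

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "n_steps": self.n_steps,
            "outer_ics": [list(ic) for ic in self.outer_ics],
            "fp_perturbation": self.fp_perturbation,
            "amp_tol": self.amp_tol,
        }


DEFAULT_PROBE = ProbeSettings()


@dataclass(frozen=True)
class LimitCycleStats:
    amplitude: float
    period: float
    x_min: float
    x_max: float
    min_saddle_distance: float  # inf when no saddle exists


@dataclass(frozen=True)
class AttractorProbe:
    rest_possible: bool
    limit_cycle: LimitCycleStats | None

    @property
    def lc_possible(self) -> bool:
        return self.limit_cycle is not None


def probe_attractors(
    params: PlanarParams, settings: ProbeSettings = DEFAULT_PROBE
) -> AttractorProbe:
    """Run the deterministic attractor probe at one parameter point."""
    fps = fixed_points(params)
    stable = [f for f in fps if f.is_stable]
    saddles = [f for f in fps if f.is_saddle]
    unstable = [f for f in fps if f.kind.startswith("unstable")]
    ics = [(f.location.x + settings.fp_perturbation, 0.0) for f in unstable]
    ics += list(settings.outer_ics)
    n = settings.n_steps
    lc: LimitCycleStats | None = None
    for x0, y0 in ics:
        xs, ys = rk4_fast_traj(
            params.mu1, params.mu2, params.nu, x0, y0, settings.dt, n
        )
        w1 = xs[n // 2 : 3 * n // 4]
        w2 = xs[3 * n // 4 :]
        a1 = w1.max() - w1.min()
        a2 = w2.max() - w2.min()
        sustained = a2 > settings.amp_tol and (a1 < 1e-12 or 0.6 < a2 / a1 < 1.4)
        if not sustained:
            continue
        mid = 0.5 * (w2.max() + w2.min())
        up = np.flatnonzero((w2[:-1] < mid) & (w2[1:] >= mid))
        period = len(w2) * settings.dt / len(up) if len(up) > 1 else math.inf
        tail_x = xs[3 * n // 4 :]
        tail_y = ys[3 * n // 4 :]
        if saddles:
            dmin = min(
                float(np.min(np.hypot(tail_x - s.location.x, tail_y)))
                for s in saddles
            )
        else:
            dmin = math.inf
        lc = LimitCycleStats(
            amplitude=float(a2),
            period=float(period),
            x_min=float(w2.min()),
            x_max=float(w2.max()),
            min_saddle_distance=dmin,
        )
        break
    return AttractorProbe(rest_possible=len(stable) > 0, limit_cycle=lc)


def classify_region(
    point: SpherePoint | PlanarParams, settings: ProbeSettings = DEFAULT_PROBE
) -> RegionLabel:
    """Classify a sphere point as rest / bursting / bistable.

    Raises :class:`UnclassifiedRegionError` when neither a stable equilibrium
    nor a sustained limit cycle is found within the probe horizon.
    """
    params = point.params() if isinstance(point, SpherePoint) else point
    probe = probe_attractors(params, settings)
    if probe.rest_possible and probe.lc_possible:
        return RegionLabel.BISTABLE
    if probe.rest_possible:
        return RegionLabel.REST
    if probe.lc_possible:
        return RegionLabel.BURSTING
    raise UnclassifiedRegionError(
        f"no attractor found at {params} within probe horizon"
    )


# --------------------------------------------------------------------------
# bifurcation curves


@dataclass
class BifurcationCurve:
    """An ordered polyline of sphere points sampling one bifurcation curve.

    ``label`` is one of SN, SNIC, SupH, SubH, SH, FLC; ``role`` records
    whether crossings of this curve serve as seizure onset, offset or both.
    ``metadata`` carries the region labels found on either side of the curve
    and the construction settings.
    """

    label: str
    samples: list[SpherePoint]
    role: str = "both"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def R(self) -> float:
        return self.samples[0].R

    def arc_lengths(self) -> np.ndarray:
        """Cumulative central angle (radians) along the polyline, from 0."""
        out = np.zeros(len(self.samples))
        for i in range(1, len(self.samples)):
            out[i] = out[i - 1] + self.samples[i - 1].angle_to(self.samples[i])
        return out

    def sample_at(self, fraction: float) -> SpherePoint:
        return sample_anchor(self, fraction)

    def distance_to(self, point: SpherePoint) -> float:
        """Central angle from ``point`` to the nearest curve sample."""
        vecs = np.array([s.vector() / s.R for s in self.samples])
        u = point.vector() / point.R
        return float(np.arccos(np.clip(np.max(vecs @ u), -1.0, 1.0)))


def sample_anchor(curve: BifurcationCurve, fraction: float) -> SpherePoint:
    """Arc-length-proportional interpolation along a curve polyline."""
    if not curve.samples:
        raise ValueError("cannot sample an empty curve")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    arcs = curve.arc_lengths()
    target = fraction * arcs[-1]
    i = int(np.searchsorted(arcs, target, side="right") - 1)
    i = min(max(i, 0), len(arcs) - 2)
    seg = arcs[i + 1] - arcs[i]
    t = 0.0 if seg <= 0 else (target - arcs[i]) / seg
    vec = _slerp(curve.samples[i].vector(), curve.samples[i + 1].vector(), t)
    return SpherePoint.from_vector(vec, R=curve.R)


# --------------------------------------------------------------------------
# local curves (semi-analytic)


def _sn_locus_points(R: float, resolution: float) -> list[dict]:
    """Sample the saddle-node locus on the sphere.

    The locus is parameterized by the double root ``xd``: ``mu1 = -2*xd^3``,
    ``mu2 = 3*xd^2`` with ``nu = +/-sqrt(R^2 - mu1^2 - mu2^2)``.  Returns raw
    samples with branch ids: (sign of xd, sign of nu).
    """
    # max |xd|: 4 xd^6 + 9 xd^4 = R^2
    f = lambda u: 4 * u**6 + 9 * u**4 - R * R  # noqa: E731
    lo, hi = 0.0, max(1.0, R)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    xmax = 0.5 * (lo + hi)
    out = []
    for s_xd in (+1, -1):
        for s_nu in (+1, -1):
            pts = []
            n = 4000
            for u in np.linspace(0.0, xmax, n):
                xd = s_xd * u
                mu1, mu2 = -2 * xd**3, 3 * xd**2
                rad = R * R - mu1 * mu1 - mu2 * mu2
                if rad < 0:
                    continue
                nu = s_nu * math.sqrt(rad)
                pts.append(
                    {
                        "point": SpherePoint.from_vector(
                            np.array([mu2, -mu1, nu]), R=R
                        ),
                        "xd": xd,
                        "branch": (s_xd, s_nu),
                    }
                )
            # decimate to the requested arc resolution
            kept = []
            last = None
            for rec in pts:
                if last is None or last["point"].angle_to(rec["point"]) >= resolution:
                    kept.append(rec)
                    last = rec
            if pts and (not kept or kept[-1] is not pts[-1]):
                kept.append(pts[-1])
            out.append({"branch": (s_xd, s_nu), "samples": kept})
    return out


def _hopf_locus_points(R: float, resolution: float) -> list[dict]:
    """Sample the Hopf locus: equilibria with zero trace and positive
    determinant, on the sphere.  Parameterized by the equilibrium ``x``:
    ``nu = -x - x^2`` and ``mu2`` solves a quadratic from the sphere
    constraint, with ``mu1 = x^3 - mu2*x``."""
    recs = []
    for x in np.linspace(-1.8, 0.9, 36_000):
        nu = -x - x * x
        if abs(nu) > R:
            continue
        a = 1 + x * x
        b = -2 * x**4
        c = x**6 + nu * nu - R * R
        disc = b * b - 4 * a * c
        if disc < 0:
            continue
        for mu2 in ((-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)):
            det = 3 * x * x - mu2
            if det <= 1e-12:
                continue  # neutral saddle, not a Hopf
            mu1 = x**3 - mu2 * x
            recs.append(
                {
                    "point": SpherePoint.from_vector(np.array([mu2, -mu1, nu]), R=R),
                    "x": x,
                    "branch": 0 if mu2 == (-b + math.sqrt(disc)) / (2 * a) else 1,
                }
            )
    # chain into polylines by proximity (the locus may have several arcs)
    return _chain_records(recs, resolution)


def _chain_records(recs: list[dict], resolution: float) -> list[dict]:
    """Greedy nearest-neighbour chaining of point records into polylines with
    spacing ~resolution; splits chains at gaps larger than 4x resolution."""
    if not recs:
        return []
    vecs = np.array([r["point"].vector() / r["point"].R for r in recs])
    unused = set(range(len(recs)))
    chains = []
    while unused:
        seed = unused.pop()
        chain = [seed]
        # grow both ends
        for direction in (1, 0):
            while True:
                tip = chain[-1] if direction else chain[0]
                cand = list(unused)
                if not cand:
                    break
                d = np.arccos(np.clip(vecs[cand] @ vecs[tip], -1, 1))
                k = int(np.argmin(d))
                if d[k] > 4 * resolution:
                    break
                idx = cand[k]
                unused.discard(idx)
                if d[k] < 0.25 * resolution and len(chain) > 1:
                    continue  # decimate near-duplicates
                if direction:
                    chain.append(idx)
                else:
                    chain.insert(0, idx)
        chains.append([recs[i] for i in chain])
    return [{"samples": ch} for ch in chains if len(ch) >= 3]


def _side_labels(
    point: SpherePoint,
    tangent: np.ndarray,
    offset: float,
    settings: ProbeSettings,
) -> tuple[RegionLabel | None, RegionLabel | None]:
    """Region labels at +/- offset along the in-sphere normal of a curve."""
    u = point.vector() / point.R
    t = tangent / np.linalg.norm(tangent)
    nrm = np.cross(u, t)
    nrm /= np.linalg.norm(nrm)
    out = []
    for s in (+1, -1):
        v = point.R * (math.cos(offset) * u + math.sin(offset) * s * nrm)
        try:
            out.append(classify_region(SpherePoint.from_vector(v, R=point.R), settings))
        except UnclassifiedRegionError:
            out.append(None)
    return out[0], out[1]


def _curve_tangents(points: list[SpherePoint]) -> list[np.ndarray]:
    vecs = [p.vector() for p in points]
    tans = []
    for i in range(len(vecs)):
        a = vecs[max(i - 1, 0)]
        b = vecs[min(i + 1, len(vecs) - 1)]
        tans.append(b - a)
    return tans


def _segment_by_signature(
    points: list[SpherePoint],
    signatures: list,
    min_len: int = 3,
) -> list[tuple[list[SpherePoint], object]]:
    """Split a polyline into maximal runs of constant signature."""
    runs = []
    start = 0
    for i in range(1, len(points) + 1):
        if i == len(points) or signatures[i] != signatures[start]:
            if i - start >= min_len:
                runs.append((points[start:i], signatures[start]))
            start = i
    return runs


def locate_local_curves(
    R: float = DEFAULT_RADIUS,
    resolution: float = DEFAULT_RESOLUTION,
    settings: ProbeSettings = DEFAULT_PROBE,
    classify_sides: bool = True,
) -> list[BifurcationCurve]:
    """Locate the SN and Hopf curves on the sphere.

    The SN locus is sampled from its exact parameterization by the double
    root; the Hopf locus from the trace/determinant conditions.  Hopf arcs
    are split into supercritical (SupH) and subcritical (SubH) segments using
    the numerical criticality probe.  When ``classify_sides`` is set, region
    labels on both sides of each curve are stored per segment (needed by the
    global-curve search and by path construction); SN segments whose crossing
    creates/destroys the limit cycle together with the equilibrium pair are
    relabelled SNIC by :func:`locate_global_curves`.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    curves: list[BifurcationCurve] = []

    for branch in _sn_locus_points(R, resolution):
        pts = [rec["point"] for rec in branch["samples"]]
        if len(pts) < 3:
            continue
        meta = {"branch": branch["branch"], "family": "SN"}
        curve = BifurcationCurve("SN", pts, role="onset", metadata=meta)
        curves.append(curve)

    for arc in _hopf_locus_points(R, resolution):
        pts = [rec["point"] for rec in arc["samples"]]
        xs = [rec["x"] for rec in arc["samples"]]
        if len(pts) < 3:
            continue
        # split by criticality sign, probed at a subset and refined
        signs = _hopf_criticality_signs(pts, xs)
        for seg_pts, sign in _segment_by_signature(pts, signs):
            label = "SupH" if sign < 0 else "SubH"
            role = "both" if label == "SupH" else "onset"
            curves.append(
                BifurcationCurve(label, seg_pts, role=role, metadata={"family": "Hopf"})
            )

    if classify_sides:
        for curve in curves:
            _attach_side_labels(curve, resolution, settings)
    return curves


def _hopf_criticality_signs(pts: list[SpherePoint], xs: list[float]) -> list[int]:
    """Criticality sign per Hopf sample, probed on a subset then filled by
    nearest probed neighbour (the sign changes only at isolated Bautin
    points, so sparse probing suffices)."""
    idx = list(range(0, len(pts), max(1, len(pts) // 12)))
    if (len(pts) - 1) not in idx:
        idx.append(len(pts) - 1)
    probed: dict[int, int] = {}
    tans = _curve_tangents(pts)
    for i in idx:
        p = pts[i]
        u = p.vector() / p.R
        t = tans[i] / np.linalg.norm(tans[i])
        nrm = np.cross(u, t)
        params = p.params()
        sign = 0
        for s in (+1, -1):
            d3 = s * nrm
            # direction in (mu1, mu2, nu) axes from the (mu2,-mu1,nu) frame
            d = np.array([-d3[1], d3[0], d3[2]])
            try:
                sign = hopf_criticality(params, xs[i], d)
                break
            except ValueError:
                continue
        probed[i] = sign
    signs = []
    for i in range(len(pts)):
        j = min(probed.keys(), key=lambda k: abs(k - i))
        signs.append(probed[j])
    return signs


def _attach_side_labels(
    curve: BifurcationCurve, resolution: float, settings: ProbeSettings
) -> None:
    """Probe region labels on both sides of a curve at a few stations and
    store the dominant signature in the metadata."""
    tans = _curve_tangents(curve.samples)
    idx = list(range(0, len(curve.samples), max(1, len(curve.samples) // 6)))
    sigs = []
    for i in idx:
        a, b = _side_labels(
            curve.samples[i], tans[i], 2.5 * resolution, settings
        )
        sigs.append((None if a is None else a.value, None if b is None else b.value))
    curve.metadata["side_labels"] = sigs


# --------------------------------------------------------------------------
# global curves (simulation-located)


def _bisect_boundary(
    va: np.ndarray,
    vb: np.ndarray,
    R: float,
    predicate,
    tol: float,
    max_iter: int = 40,
) -> np.ndarray | None:
    """Bisection along the great-circle segment between two Cartesian points
    across a boolean predicate change.  Returns the midpoint vector or None
    when the bisection fails to converge."""
    pa = predicate(SpherePoint.from_vector(va, R=R))
    pb = predicate(SpherePoint.from_vector(vb, R=R))
    if pa == pb:
        return None
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        omega = math.acos(
            float(np.clip((va / R) @ (vb / R), -1, 1))
        )
        if omega * (hi - lo) < tol:
            break
        mid = 0.5 * (lo + hi)
        pm = predicate(SpherePoint.from_vector(_slerp(va, vb, mid), R=R))
        if pm == pa:
            lo = mid
        else:
            hi = mid
    return _slerp(va, vb, 0.5 * (lo + hi))


def _lc_exists(point: SpherePoint, settings: ProbeSettings) -> bool:
    return probe_attractors(point.params(), settings).lc_possible


def _rest_exists(point: SpherePoint, settings: ProbeSettings) -> bool:
    return probe_attractors(point.params(), settings).rest_possible


def _label_lc_boundary(
    vec: np.ndarray,
    inward: np.ndarray,
    R: float,
    resolution: float,
    settings: ProbeSettings,
) -> str:
    """Classify a limit-cycle-existence boundary point as SupH, SH or FLC.

    Probes the cycle just inside the bursting side at two distances.  At a
    supercritical Hopf boundary the amplitude vanishes as sqrt(distance)
    (amplitude ratio ~ 2 between the two stations); at a saddle-homoclinic
    boundary the orbit hugs a saddle and the period grows as the boundary is
    approached (logarithmic divergence); at a fold of limit cycles both the
    amplitude and the period stay finite, away from any saddle.
    """
    long_probe = replace(settings, n_steps=4 * settings.n_steps)
    stats = []
    for d in (0.5 * resolution, 0.125 * resolution):
        u = vec / R
        w = inward / np.linalg.norm(inward)
        v = R * (math.cos(d) * u + math.sin(d) * w)
        probe = probe_attractors(SpherePoint.from_vector(v, R=R).params(), long_probe)
        if probe.limit_cycle is None:
            return "FLC"  # no slow saddle-mediated cycle observable close in
        stats.append(probe.limit_cycle)
    far, near = stats
    if near.amplitude > 0 and far.amplitude / near.amplitude > 1.6:
        return "SupH"
    hugs_saddle = near.min_saddle_distance < 0.1
    period_grows = not math.isfinite(near.period) or (
        math.isfinite(far.period) and near.period > 1.1 * far.period
    )
    return "SH" if (hugs_saddle and period_grows) else "FLC"


def locate_global_curves(
    R: float = DEFAULT_RADIUS,
    resolution: float = DEFAULT_RESOLUTION,
    local_curves: list[BifurcationCurve] | None = None,
    settings: ProbeSettings = DEFAULT_PROBE,
    grid: tuple[int, int] | None = None,
) -> list[BifurcationCurve]:
    """Locate the SNIC, SH and FLC curves by simulation.

    Strategy: classify a latitude/longitude grid by the attractor probe,
    bisect every grid edge across which limit-cycle existence changes, and
    label each refined boundary point:

    * on the SN locus (discriminant ~ 0): the saddle-node sits on the
      invariant circle, i.e. the point belongs to the SNIC curve;
    * on the Hopf locus: the boundary is the SupH curve (already covered by
      the local search) and is skipped here;
    * elsewhere: SH vs FLC decided by the saddle-proximity/period-growth
      diagnostic of the cycle just inside the bursting side.

    Returns SNIC, SH and FLC curves; SNIC samples satisfy the SN defining
    equation to tolerance by construction.
    """
    if local_curves is None:
        local_curves = locate_local_curves(R, resolution, settings, classify_sides=False)

    if grid is None:
        nth = max(24, int(np.pi / (1.6 * resolution)))
        nph = 2 * nth
    else:
        nth, nph = grid
    thetas = np.linspace(0.02, np.pi - 0.02, nth)
    phis = np.linspace(0, 2 * np.pi, nph, endpoint=False)
    lc = np.zeros((nth, nph), dtype=bool)
    for i, th in enumerate(thetas):
        for j, ph in enumerate(phis):
            lc[i, j] = _lc_exists(SpherePoint(th, ph, R), settings)

    pred = lambda p: _lc_exists(p, settings)  # noqa: E731
    recs: list[dict] = []
    dropped = 0
    for i in range(nth):
        for j in range(nph):
            neighbours = [(i + 1, j), (i, (j + 1) % nph)]
            for i2, j2 in neighbours:
                if i2 >= nth:
                    continue
                if lc[i, j] == lc[i2, j2]:
                    continue
                va = SpherePoint(thetas[i], phis[j], R).vector()
                vb = SpherePoint(thetas[i2], phis[j2], R).vector()
                v = _bisect_boundary(va, vb, R, pred, tol=0.005 * resolution)
                if v is None:
                    dropped += 1
                    continue
                pt = SpherePoint.from_vector(v, R=R)
                # inward = toward the bursting side
                inward = (va if lc[i, j] else vb) - v
                inward -= (inward @ (v / R)) * (v / R)
                recs.append({"point": pt, "inward": inward})

    # partition refined points by locus membership.  A boundary point counts
    # as SNIC only if it sits on the SN locus (small discriminant) AND the
    # equilibrium pair and the cycle appear/disappear together across it
    # (rest on one side, bursting on the other) -- that is the defining
    # saddle-node-on-invariant-circle geometry and excludes a narrow
    # SN + SH sliver whose SH edge also hugs the locus.
    sn_tol = 1.5e-3 * (R / 0.4) ** 3
    snic, free = [], []
    for rec in recs:
        p = rec["point"].params()
        on_sn = abs(sn_residual(p)) < sn_tol and p.mu2 > 0
        if on_sn:
            u = rec["point"].vector() / R
            w = rec["inward"] / np.linalg.norm(rec["inward"])
            d = 0.25 * resolution
            side_in = SpherePoint.from_vector(
                R * (math.cos(d) * u + math.sin(d) * w), R=R
            )
            side_out = SpherePoint.from_vector(
                R * (math.cos(d) * u - math.sin(d) * w), R=R
            )
            pin = probe_attractors(side_in.params(), settings)
            pout = probe_attractors(side_out.params(), settings)
            if (
                pin.lc_possible
                and not pin.rest_possible
                and pout.rest_possible
                and not pout.lc_possible
            ):
                snic.append(rec)
            # else: the SN curve itself (already in the local set); skip
            continue
        free.append(rec)

    curves: list[BifurcationCurve] = []
    for chain in _chain_records(snic, resolution):
        pts = [r["point"] for r in chain["samples"]]
        if len(pts) >= 3:
            curves.append(
                BifurcationCurve("SNIC", pts, role="both", metadata={"family": "SN"})
            )

    labelled = []
    for rec in free:
        lab = _label_lc_boundary(
            rec["point"].vector(), rec["inward"], R, resolution, settings
        )
        if lab == "SupH":
            continue  # Hopf boundary: already covered by the local curves
        labelled.append({**rec, "label": lab})
    for lab in ("SH", "FLC"):
        subset = [r for r in labelled if r["label"] == lab]
        for chain in _chain_records(subset, resolution):
            pts = [r["point"] for r in chain["samples"]]
            if len(pts) >= 3:
                curves.append(
                    BifurcationCurve(
                        lab, pts, role="offset", metadata={"family": "global"}
                    )
                )
    if dropped:
        logging.getLogger(__name__).warning(
            "%d boundary bisections did not converge and were dropped", dropped
        )
    return curves


# --------------------------------------------------------------------------
# curve sets and caching


@dataclass
class CurveSet:
    """All located bifurcation curves on one sphere, with cache round-trip."""

    R: float
    resolution: float
    curves: list[BifurcationCurve]
    probe: ProbeSettings = DEFAULT_PROBE
    metadata: dict = field(default_factory=dict)

    def by_label(self, label: str) -> list[BifurcationCurve]:
        return [c for c in self.curves if c.label == label]

    def curve(self, label: str, index: int = 0) -> BifurcationCurve:
        matches = self.by_label(label)
        if not matches:
            raise KeyError(f"no curve labelled {label!r} in this curve set")
        return matches[index]

    def save(self, stem: str | Path) -> None:
        """Write the curve table as CSV plus a JSON sidecar of settings."""
        stem = Path(stem)
        rows = ["curve_id,label,role,theta,phi,R"]
        for ci, c in enumerate(self.curves):
            for s in c.samples:
                rows.append(
                    f"{ci},{c.label},{c.role},{s.theta!r},{s.phi!r},{s.R!r}"
                )
        stem.with_suffix(".csv").write_text("\n".join(rows) + "\n")
        side = {
            "R": self.R,
            "resolution": self.resolution,
            "probe": self.probe.to_dict(),
            "curve_metadata": [
                {k: v for k, v in c.metadata.items() if _json_safe(v)}
                for c in self.curves
            ],
            **self.metadata,
        }
        stem.with_suffix(".json").write_text(json.dumps(side, indent=1))

    @staticmethod
    def load(stem: str | Path) -> "CurveSet":
        stem = Path(stem)
        side = json.loads(stem.with_suffix(".json").read_text())
        lines = stem.with_suffix(".csv").read_text().strip().splitlines()[1:]
        curves: dict[int, BifurcationCurve] = {}
        for line in lines:
            ci_s, label, role, th, ph, r = line.split(",")
            ci = int(ci_s)
            if ci not in curves:
                curves[ci] = BifurcationCurve(label, [], role=role)
            curves[ci].samples.append(
                SpherePoint(float(th), float(ph), float(r))
            )
        ordered = [curves[k] for k in sorted(curves)]
        meta = side.pop("curve_metadata", None)
        if meta:
            for c, m in zip(ordered, meta):
                c.metadata.update(m)
        probe = ProbeSettings(
            dt=side["probe"]["dt"],
            n_steps=side["probe"]["n_steps"],
            outer_ics=tuple(tuple(ic) for ic in side["probe"]["outer_ics"]),
            fp_perturbation=side["probe"]["fp_perturbation"],
            amp_tol=side["probe"]["amp_tol"],
        )
        return CurveSet(
            R=side["R"],
            resolution=side["resolution"],
            curves=ordered,
            probe=probe,
            metadata={
                k: v
                for k, v in side.items()
                if k not in ("R", "resolution", "probe")
            },
        )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def build_curve_set(
    R: float = DEFAULT_RADIUS,
    resolution: float = DEFAULT_RESOLUTION,
    settings: ProbeSettings = DEFAULT_PROBE,
) -> CurveSet:
    """Locate all six bifurcation curve families on the sphere.

    The default radius is the smallest round value at which the probe detects
    all six curve types; it is recorded in the cache metadata.
    """
    local = locate_local_curves(R, resolution, settings)
    global_ = locate_global_curves(R, resolution, local, settings)
    return CurveSet(
        R=R,
        resolution=resolution,
        curves=local + global_,
        probe=settings,
        metadata={"note": "smallest round radius with all six curve types"},
    )


def refine_to_locus(point: SpherePoint, family: str) -> SpherePoint:
    """Project a near-curve point exactly onto an analytic locus.

    ``family`` is ``"SN"`` (saddle-node discriminant zero set; also the
    SNIC curve, which is a subset of the same locus) or ``"Hopf"`` (zero
    trace at a determinant-positive equilibrium; the SupH/SubH curves).
    Interpolated curve samples sit on chords between cached samples and can
    be off the true locus by a fraction of the cache resolution, which
    matters for paths that must cross a curve exactly at the anchor.
    """
    R = point.R
    p = point.vector()
    if family == "SN":
        s_nu = 1.0 if p[2] >= 0 else -1.0
        mu1 = -p[1]
        xd0 = float(np.cbrt(-mu1 / 2.0)) if mu1 != 0 else 0.0

        def locus(xd: float) -> np.ndarray | None:
            m1, m2 = -2 * xd**3, 3 * xd**2
            rad = R * R - m1 * m1 - m2 * m2
            if rad < 0:
                return None
            return np.array([m2, -m1, s_nu * math.sqrt(rad)])

        best, bd = None, np.inf
        for xd in np.linspace(xd0 - 0.05, xd0 + 0.05, 2001):
            v = locus(xd)
            if v is None:
                continue
            d = np.linalg.norm(v - p)
            if d < bd:
                bd, best = d, v
        if best is None:
            raise ValueError("no SN locus point near the given point")
        return SpherePoint.from_vector(best, R=R)
    if family == "Hopf":
        best, bd = None, np.inf
        for x in np.linspace(-1.8, 0.9, 40_000):
            nu = -x - x * x
            if abs(nu) > R:
                continue
            a = 1 + x * x
            b = -2 * x**4
            c = x**6 + nu * nu - R * R
            disc = b * b - 4 * a * c
            if disc < 0:
                continue
            for mu2 in ((-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)):
                if 3 * x * x - mu2 <= 1e-12:
                    continue
                v = np.array([mu2, -(x**3 - mu2 * x), nu])
                d = np.linalg.norm(v - p)
                if d < bd:
                    bd, best = d, v
        if best is None:
            raise ValueError("no Hopf locus point near the given point")
        return SpherePoint.from_vector(best, R=R)
    raise ValueError(f"unknown analytic locus family {family!r}")


_LOCUS_FAMILY = {"SN": "SN", "SNIC": "SN", "SupH": "Hopf", "SubH": "Hopf"}


def load_packaged_curves() -> CurveSet:
    """Load the curve cache shipped with the package (default sphere)."""
    return CurveSet.load(_DATA_DIR / "curves_R04")
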