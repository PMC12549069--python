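"""Bursting paths on the parameter sphere and the slow-variable dynamics.

A bursting path is a one-parameter family of sphere points indexed by the
slow variable ``z`` (radians of arc along the path) that connects an onset
bifurcation curve to an offset curve.  Three slow dynamics move the system
along its path:

* hysteresis feedback -- ``dz/dt = -c * (dist((x, y), (x_s, y_s)) - d*)``
  where ``(x_s, y_s)`` is the resting equilibrium at the current path
  position: the slow variable is pushed toward the onset curve while the
  system rests close to its equilibrium and pulled back while it bursts far
  from it, producing a hysteresis loop through a bistable region;
* slow wave -- ``dz/dt = k``, a constant autonomous drift around a closed
  circular path, with no feedback from the fast subsystem;
* piecewise -- ``dz/dt = k(t)``, piecewise-constant speeds along four
  great-circle arcs joining a rest point, an onset-curve point, a
  bursting-region point and an offset-curve point, with optional dwell
  intervals of zero speed at turning points.

All paths are composed of circular arcs on the sphere (great circles for
arcs between two points, small circles through three points), so each path
compiles to the arc-sequence arrays consumed by the integrator kernel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .sphere import (
    CurveSet,
    ProbeSettings,
    RegionLabel,
    SpherePoint,
    classify_region,
)

__all__ = [
    "ArcGeometry",
    "BurstingPath",
    "HysteresisConfig",
    "SlowWaveConfig",
    "PiecewiseConfig",
    "PathConstructionError",
    "great_circle_arc",
    "circle_through",
    "hysteresis_drift",
    "slow_wave_drift",
    "piecewise_drift",
    "build_path",
]


class PathConstructionError(ValueError):
    """Raised when anchors are inconsistent with the requested path kind."""


# --------------------------------------------------------------------------
# arc geometry


@dataclass(frozen=True)
class ArcGeometry:
    """One circular arc on the sphere: ``P(z) = C + r*(cos(a)*U + sin(a)*V)``
    with local angle ``a = z - z0``, for ``z`` in ``[z0, z1]``."""

    C: np.ndarray
    U: np.ndarray
    V: np.ndarray
    r: float
    z0: float
    z1: float

    def __call__(self, z: float | np.ndarray) -> np.ndarray:
        a = np.asarray(z, dtype=float) - self.z0
        out = (
            self.C
            + self.r * np.multiply.outer(np.cos(a), self.U)
            + self.r * np.multiply.outer(np.sin(a), self.V)
        )
        return out if np.ndim(z) else out[()]

    @property
    def span(self) -> float:
        return self.z1 - self.z0


def great_circle_arc(A: SpherePoint, B: SpherePoint, z0: float = 0.0) -> ArcGeometry:
    """Constant-speed minor great-circle arc from ``A`` to ``B``.

    The parameterization is by central angle so endpoints are reproduced
    exactly: ``geometry(z0) = A`` and ``geometry(z0 + angle(A, B)) = B``.
    Antipodal inputs are rejected (the connecting arc is not unique).
    """
    if not math.isclose(A.R, B.R, rel_tol=1e-9):
        raise ValueError("arc endpoints must lie on the same sphere")
    R = A.R
    a = A.vector() / R
    b = B.vector() / R
    omega = float(np.arccos(np.clip(a @ b, -1.0, 1.0)))
    if omega > np.pi - 1e-6:
        raise PathConstructionError("antipodal endpoints: great-circle arc not unique")
    if omega < 1e-12:
        raise PathConstructionError("coincident endpoints")
    v = b - (a @ b) * a
    v /= np.linalg.norm(v)
    return ArcGeometry(C=np.zeros(3), U=a, V=v, r=R, z0=z0, z1=z0 + omega)


def circle_through(
    A: SpherePoint, B: SpherePoint, C: SpherePoint, z0: float = 0.0
) -> ArcGeometry:
    """The unique circle on the sphere through three distinct points,
    parameterized periodically by its own central angle starting at ``A``."""
    R = A.R
    pa, pb, pc = A.vector(), B.vector(), C.vector()
    n = np.cross(pb - pa, pc - pa)
    norm = np.linalg.norm(n)
    if norm < 1e-10 * R * R:
        raise PathConstructionError("degenerate triple: points (nearly) collinear")
    n /= norm
    h = float(n @ pa)  # plane offset; circle = sphere ∩ plane
    center = h * n
    r = math.sqrt(max(R * R - h * h, 0.0))
    if r < 1e-9 * R:
        raise PathConstructionError("degenerate circle of vanishing radius")
    U = (pa - center) / r
    V = np.cross(n, U)
    return ArcGeometry(C=center, U=U, V=V, r=r, z0=z0, z1=z0 + 2 * np.pi)


def _angle_on_circle(arc: ArcGeometry, point: SpherePoint) -> float:
    """Angle of a point (assumed on the circle of ``arc``) in [0, 2*pi)."""
    p = point.vector() - arc.C
    return float(np.arctan2(p @ arc.V, p @ arc.U) % (2 * np.pi))


# --------------------------------------------------------------------------
# slow-dynamics configuration


@dataclass
class HysteresisConfig:
    """Slow feedback drift ``dz/dt = -c*(dist - d_star)``.

    ``c`` is the slow speed; ``d_star`` the excitability threshold distance:
    the drift is positive while the fast state is within ``d_star`` of its
    resting equilibrium and negative during large-amplitude bursting.  The
    resting equilibrium ``(x_s, y_s)`` tracks the stable root of the cubic
    as the path position moves and retains its last (ghost) value while the
    rest state is annihilated -- see the integrator kernel.
    """

    c: float = 2e-4
    d_star: float = 0.3

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("hysteresis speed c must be positive")
        if self.d_star < 0:
            raise ValueError("d_star must be nonnegative")


@dataclass
class SlowWaveConfig:
    """Constant autonomous slow drift ``dz/dt = k`` (sign sets direction)."""

    k: float = 2e-4

    def __post_init__(self) -> None:
        if self.k == 0:
            raise ValueError("slow-wave speed k must be nonzero")


@dataclass
class PiecewiseConfig:
    """Piecewise-constant slow speeds over the four arcs of a piecewise path,
    with optional dwell (zero-speed) intervals at the turning points.

    ``speeds`` has one entry per arc; ``dwells`` one entry per interior
    anchor (after arcs 1..3); ``end_point`` optionally replaces the final
    anchor with a distinct terminal point.
    """

    speeds: tuple[float, ...] = (2e-4, 2e-4, 2e-4, 2e-4)
    dwells: tuple[float, ...] = (0.0, 0.0, 0.0)
    end_point: SpherePoint | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.speeds):
            raise ValueError("piecewise arc speeds must be positive")
        if any(d < 0 for d in self.dwells):
            raise ValueError("dwell times must be nonnegative")


def hysteresis_drift(
    x: float, y: float, x_s: float, y_s: float, config: HysteresisConfig
) -> float:
    """Euclidean-distance hysteresis drift (see module docstring)."""
    dist = math.hypot(x - x_s, y - y_s)
    return -config.c * (dist - config.d_star)


def slow_wave_drift(config: SlowWaveConfig) -> float:
    """Constant drift ``k``; no feedback from the fast subsystem."""
    return config.k


def piecewise_drift(t: float, config: "PiecewiseConfig", path: "BurstingPath") -> float:
    """Speed profile of a piecewise path at time ``t`` (zero during dwells
    and after the terminal point is reached)."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    breaks, speeds = path.time_profile()
    for tb, sp in zip(breaks, speeds):
        if t < tb:
            return sp
    return 0.0


# --------------------------------------------------------------------------
# bursting paths


@dataclass
class BurstingPath:
    """A one-parameter family of sphere points indexed by the slow variable.

    ``z_onset``/``z_offset`` are the path parameters at which the path
    crosses its onset/offset bifurcation curves (``z_onset = 0`` for
    hysteresis paths by convention).  ``closed`` paths are periodic in ``z``
    with period ``2*pi`` (slow wave) and evaluate anywhere; open paths clamp
    outside their arc span.
    """

    kind: str  # hysteresis | slow_wave | piecewise
    arcs: list[ArcGeometry]
    z_onset: float
    z_offset: float
    closed: bool
    R: float
    config: HysteresisConfig | SlowWaveConfig | PiecewiseConfig | None = None
    z_start: float = 0.0  # recommended initial z for simulations
    metadata: dict = field(default_factory=dict)

    @property
    def period(self) -> float:
        return self.arcs[-1].z1 - self.arcs[0].z0

    def geometry(self, z: float) -> SpherePoint:
        v = self.geometry_vector(z)
        return SpherePoint.from_vector(v, R=self.R)

    def geometry_vector(self, z: float) -> np.ndarray:
        z0 = self.arcs[0].z0
        if self.closed:
            z = z0 + (z - z0) % self.period
        else:
            z = min(max(z, z0), self.arcs[-1].z1)
        for arc in self.arcs:
            if z <= arc.z1 or arc is self.arcs[-1]:
                return arc(z)
        raise AssertionError("unreachable")

    def params_at(self, z: float):
        return self.geometry(z).params()

    # ---- kernel compilation -------------------------------------------

    def kernel_arrays(self) -> dict:
        """Arrays consumed by the integrator kernel."""
        return {
            "arc_z0": np.array([a.z0 for a in self.arcs]),
            "arc_z1": np.array([a.z1 for a in self.arcs]),
            "C": np.array([a.C for a in self.arcs]),
            "U": np.array([a.U for a in self.arcs]),
            "V": np.array([a.V for a in self.arcs]),
            "r": np.array([a.r for a in self.arcs]),
            "closed": self.closed,
            "period": self.period,
        }

    def time_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant speed profile (segment end times, speeds) for
        piecewise paths: arcs traversed at their configured speeds separated
        by zero-speed dwells."""
        if self.kind != "piecewise":
            raise ValueError("time_profile is defined for piecewise paths only")
        cfg: PiecewiseConfig = self.config
        breaks: list[float] = []
        speeds: list[float] = []
        t = 0.0
        for i, arc in enumerate(self.arcs):
            t += arc.span / cfg.speeds[i]
            breaks.append(t)
            speeds.append(cfg.speeds[i])
            if i < len(cfg.dwells) and cfg.dwells[i] > 0:
                t += cfg.dwells[i]
                breaks.append(t)
                speeds.append(0.0)
        return np.array(breaks), np.array(speeds)

    @property
    def total_traversal_time(self) -> float:
        return float(self.time_profile()[0][-1])

    # ---- serialization ------------------------------------------------

    def spec_dict(self) -> dict:
        """JSON-serializable description (method, anchors, settings)."""
        meta = dict(self.metadata)
        out = {
            "kind": self.kind,
            "R": self.R,
            "z_onset": self.z_onset,
            "z_offset": self.z_offset,
            "z_start": self.z_start,
            "closed": self.closed,
            **{
                k: v
                for k, v in meta.items()
                if isinstance(v, (str, int, float, bool, list, tuple, type(None)))
            },
        }
        if isinstance(self.config, HysteresisConfig):
            out["config"] = {"c": self.config.c, "d_star": self.config.d_star}
        elif isinstance(self.config, SlowWaveConfig):
            out["config"] = {"k": self.config.k}
        elif isinstance(self.config, PiecewiseConfig):
            out["config"] = {
                "speeds": list(self.config.speeds),
                "dwells": list(self.config.dwells),
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.spec_dict(), indent=1)


# --------------------------------------------------------------------------
# construction


def _region_transect(
    path: BurstingPath,
    z_lo: float,
    z_hi: float,
    n: int,
    probe: ProbeSettings | None,
) -> list[RegionLabel]:
    settings = probe or ProbeSettings()
    return [
        classify_region(path.geometry(z), settings)
        for z in np.linspace(z_lo, z_hi, n)
    ]


def build_hysteresis_path(
    onset_anchor: SpherePoint,
    offset_anchor: SpherePoint,
    config: HysteresisConfig | None = None,
    validate: bool = False,
    probe: ProbeSettings | None = None,
    z_start: float | None = None,
    z_offset: float | None = None,
) -> BurstingPath:
    """Great-circle hysteresis path: ``z = 0`` at the onset anchor,
    increasing ``z`` leads from rest through the bistable strip into the
    bursting region; the offset anchor sits at negative ``z``.

    ``z_offset`` overrides the offset-crossing parameter; with
    ``z_offset = 0`` the offset is the return crossing of the onset curve
    itself, which is how a single-curve (e.g. SNIC/SNIC parabolic) burster
    is encoded -- the second point then only orients the great circle, with
    the rest-side of the curve at negative ``z``."""
    omega = onset_anchor.angle_to(offset_anchor)
    # orient the circle so that z increases from offset anchor to onset anchor
    arc = great_circle_arc(offset_anchor, onset_anchor)
    # reparameterize: z = 0 at onset anchor -> shift by omega
    full = ArcGeometry(
        C=arc.C, U=arc.U, V=arc.V, r=arc.r, z0=-omega, z1=-omega + 2 * np.pi
    )
    z_off = -omega if z_offset is None else z_offset
    path = BurstingPath(
        kind="hysteresis",
        arcs=[full],
        z_onset=0.0,
        z_offset=z_off,
        closed=True,
        R=onset_anchor.R,
        config=config or HysteresisConfig(),
        z_start=z_start if z_start is not None else -0.3 * omega,
    )
    if validate:
        labels = _region_transect(path, -omega, 0.0, 5, probe)
        if RegionLabel.BISTABLE not in labels:
            raise PathConstructionError(
                "no bistable region between hysteresis anchors; "
                f"transect labels: {[l.value for l in labels]}"
            )
    return path


def build_slow_wave_path(
    onset_anchor: SpherePoint,
    offset_anchor: SpherePoint,
    third_point: SpherePoint,
    config: SlowWaveConfig | None = None,
    z_start: float | None = None,
) -> BurstingPath:
    """Closed circular slow-wave path through the two anchors and a third
    point; ``z = 0`` at the onset anchor, traversal direction chosen so the
    third (bursting-region) point is visited after onset and before offset."""
    arc = circle_through(onset_anchor, offset_anchor, third_point)
    a_off = _angle_on_circle(arc, offset_anchor)
    a_third = _angle_on_circle(arc, third_point)
    if not (a_third < a_off):
        # flip orientation so onset (0) -> third -> offset in increasing z
        arc = ArcGeometry(C=arc.C, U=arc.U, V=-arc.V, r=arc.r, z0=0.0, z1=2 * np.pi)
        a_off = _angle_on_circle(arc, offset_anchor)
        a_third = _angle_on_circle(arc, third_point)
    if not (1e-9 < a_third < a_off):
        raise PathConstructionError(
            "cannot orient slow-wave circle with onset -> bursting -> offset"
        )
    return BurstingPath(
        kind="slow_wave",
        arcs=[arc],
        z_onset=0.0,
        z_offset=a_off,
        closed=True,
        R=onset_anchor.R,
        config=config or SlowWaveConfig(),
        z_start=z_start if z_start is not None else -0.3 * (2 * np.pi - a_off),
    )


def build_piecewise_path(
    rest_point: SpherePoint,
    onset_anchor: SpherePoint,
    bursting_point: SpherePoint,
    offset_anchor: SpherePoint,
    config: PiecewiseConfig | None = None,
) -> BurstingPath:
    """Four joined great-circle arcs rest -> onset -> bursting -> offset
    (-> optional distinct end point), traversed at per-arc speeds."""
    cfg = config or PiecewiseConfig()
    end = cfg.end_point if cfg.end_point is not None else rest_point
    anchors = [rest_point, onset_anchor, bursting_point, offset_anchor, end]
    arcs: list[ArcGeometry] = []
    z = 0.0
    z_marks = []
    for A, B in zip(anchors[:-1], anchors[1:]):
        arc = great_circle_arc(A, B, z0=z)
        arcs.append(arc)
        z = arc.z1
        z_marks.append(z)
    return BurstingPath(
        kind="piecewise",
        arcs=arcs,
        z_onset=z_marks[0],  # end of arc 1 = onset anchor
        z_offset=z_marks[2],  # end of arc 3 = offset anchor
        closed=False,
        R=rest_point.R,
        config=cfg,
        z_start=0.0,
    )


def build_path(
    onset_anchor: SpherePoint,
    offset_anchor: SpherePoint,
    method: str,
    config=None,
    third_point: SpherePoint | None = None,
    rest_point: SpherePoint | None = None,
    bursting_point: SpherePoint | None = None,
    curves: CurveSet | None = None,
    onset_label: str | None = None,
    offset_label: str | None = None,
    validate: bool = False,
) -> BurstingPath:
    """Construct a bursting path of the requested method between two anchor
    points sampled on bifurcation curves.

    When ``curves`` plus curve labels are given, the anchors are checked to
    lie on curves of the stated labels (within the curve resolution); method-
    specific auxiliary points (slow-wave third point, piecewise rest/bursting
    points) default to geometric constructions but can be supplied.
    """
    if curves is not None:
        for anchor, label, which in (
            (onset_anchor, onset_label, "onset"),
            (offset_anchor, offset_label, "offset"),
        ):
            if label is None:
                continue
            dmin = min(c.distance_to(anchor) for c in curves.by_label(label))
            if dmin > 2 * curves.resolution:
                raise PathConstructionError(
                    f"{which} anchor is {dmin:.3f} rad from the nearest "
                    f"{label} curve (resolution {curves.resolution})"
                )
    if method == "hysteresis":
        return build_hysteresis_path(
            onset_anchor, offset_anchor, config, validate=validate
        )
    if method == "slow_wave":
        if third_point is None:
            third_point = _default_third_point(onset_anchor, offset_anchor)
        return build_slow_wave_path(onset_anchor, offset_anchor, third_point, config)
    if method == "piecewise":
        if rest_point is None or bursting_point is None:
            raise PathConstructionError(
                "piecewise paths need explicit rest and bursting points"
            )
        cfg = config or PiecewiseConfig()
        return build_piecewise_path(
            rest_point, onset_anchor, bursting_point, offset_anchor, cfg
        )
    raise ValueError(f"unknown path method {method!r}")


def _default_third_point(
    onset_anchor: SpherePoint, offset_anchor: SpherePoint, tilt: float = 0.35
) -> SpherePoint:
    """Default slow-wave third point: the anchor midpoint rotated about the
    anchor axis by ``tilt`` radians toward the bursting side; the caller is
    expected to validate the side (both signs are tried by ``classify``-based
    construction in the registry)."""
    R = onset_anchor.R
    a = onset_anchor.vector() / R
    b = offset_anchor.vector() / R
    mid = a + b
    mid /= np.linalg.norm(mid)
    axis = b - a
    axis /= np.linalg.norm(axis)
    # rotate mid about axis by tilt (Rodrigues)
    m = (
        mid * math.cos(tilt)
        + np.cross(axis, mid) * math.sin(tilt)
        + axis * (axis @ mid) * (1 - math.cos(tilt))
    )
    return SpherePoint.from_vector(R * m / np.linalg.norm(m), R=R)
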