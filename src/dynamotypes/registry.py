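"""The dynamotype registry: the 16 onset/offset bifurcation classes, their
generation-method assignments, and concrete validated path recipes on the
default parameter sphere.

A dynamotype is a seizure class labelled by its onset bifurcation
(SN, SNIC, SupH, SubH) and offset bifurcation (SH, SNIC, SupH, FLC).  All
sixteen combinations are represented.  Method assignments follow the
dynamics each method can realize on the sphere map:

* hysteresis-loop bursting requires slow feedback through a region where
  the resting state and the cycle trade off; the five hysteresis classes
  are exactly the classic point-cycle bursters (fold/homoclinic SN/SH,
  fold/fold-cycle SN/FLC, subHopf/homoclinic SubH/SH, subHopf/fold-cycle
  SubH/FLC, and fold/circle SN/SNIC);
* slow-wave bursting traverses a closed circle autonomously and covers
  seven classes, all involving a SNIC or a Hopf-family crossing with no
  bistability required;
* piecewise bursting covers the five remaining combinations with
  customizable four-point paths (SNIC/SH is generated by both the
  slow-wave and the piecewise method, giving 17 class-method pairs for the
  16 classes).

Every recipe below was validated by noise-free simulation: it produces a
labelled seizure whose onset/offset signatures match the class (DC shift
for SN onsets, square-root frequency scaling at SNIC borders, growing
amplitude for SupH onsets, interspike-interval growth toward SH offsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .paths import (
    BurstingPath,
    HysteresisConfig,
    PiecewiseConfig,
    SlowWaveConfig,
    build_hysteresis_path,
    build_piecewise_path,
    build_slow_wave_path,
)
from .sphere import (
    _LOCUS_FAMILY,
    BifurcationCurve,
    CurveSet,
    SpherePoint,
    load_packaged_curves,
    refine_to_locus,
    sample_anchor,
)

__all__ = [
    "ONSETS",
    "OFFSETS",
    "DynamotypeSpec",
    "PathRecipe",
    "registry",
    "recipes",
    "get_spec",
    "get_recipe",
]

ONSETS = ("SN", "SNIC", "SupH", "SubH")
OFFSETS = ("SH", "SNIC", "SupH", "FLC")

_METHOD_ASSIGNMENT: dict[tuple[str, str], tuple[str, ...]] = {
    ("SN", "SH"): ("hysteresis",),
    ("SN", "SNIC"): ("hysteresis",),
    ("SN", "SupH"): ("piecewise",),
    ("SN", "FLC"): ("hysteresis",),
    ("SNIC", "SH"): ("slow_wave", "piecewise"),
    ("SNIC", "SNIC"): ("slow_wave",),
    ("SNIC", "SupH"): ("slow_wave",),
    ("SNIC", "FLC"): ("slow_wave",),
    ("SupH", "SH"): ("piecewise",),
    ("SupH", "SNIC"): ("slow_wave",),
    ("SupH", "SupH"): ("piecewise",),
    ("SupH", "FLC"): ("slow_wave",),
    ("SubH", "SH"): ("hysteresis",),
    ("SubH", "SNIC"): ("slow_wave",),
    ("SubH", "SupH"): ("piecewise",),
    ("SubH", "FLC"): ("hysteresis",),
}


@dataclass(frozen=True)
class DynamotypeSpec:
    """One seizure class: onset/offset bifurcation pair, the generation
    methods assigned to it, and the expected DC-shift flags (an SN onset
    displaces the baseline; an SH offset typically steps back)."""

    onset: str
    offset: str
    methods: tuple[str, ...]
    dc_onset: bool
    dc_offset: bool

    @property
    def name(self) -> str:
        return f"{self.onset}/{self.offset}"

    @property
    def key(self) -> tuple[str, str]:
        return (self.onset, self.offset)


def registry() -> list[DynamotypeSpec]:
    """The 16 dynamotypes (full onset x offset product) with their method
    assignments: 5 hysteresis, 7 slow-wave, 5 piecewise class-method pairs."""
    out = []
    for onset in ONSETS:
        for offset in OFFSETS:
            methods = _METHOD_ASSIGNMENT[(onset, offset)]
            out.append(
                DynamotypeSpec(
                    onset=onset,
                    offset=offset,
                    methods=methods,
                    dc_onset=onset == "SN",
                    dc_offset=offset == "SH",
                )
            )
    return out


def get_spec(onset: str, offset: str) -> DynamotypeSpec:
    for spec in registry():
        if spec.key == (onset, offset):
            return spec
    raise KeyError(f"unknown dynamotype {onset}/{offset}")


# --------------------------------------------------------------------------
# path recipes


def _nearest_curve(curves: CurveSet, label: str, target: SpherePoint) -> BifurcationCurve:
    cands = curves.by_label(label)
    if not cands:
        raise KeyError(f"curve cache has no {label} curve")
    return min(cands, key=lambda c: c.distance_to(target))


def _fraction_near(curve: BifurcationCurve, target: SpherePoint) -> float:
    arcs = curve.arc_lengths()
    dists = [target.angle_to(s) for s in curve.samples]
    k = int(np.argmin(dists))
    return float(arcs[k] / arcs[-1]) if arcs[-1] > 0 else 0.0


@dataclass(frozen=True)
class AnchorSpec:
    """An anchor on a named bifurcation curve, swept between two target
    points: sweep coordinate ``u`` in [0, 1] interpolates the arc-length
    fraction between the fractions nearest ``lo`` and ``hi``."""

    label: str
    lo: tuple[float, float]  # (theta, phi)
    hi: tuple[float, float]

    def resolve(self, curves: CurveSet, u: float) -> tuple[SpherePoint, float]:
        R = curves.R
        mid = SpherePoint(
            0.5 * (self.lo[0] + self.hi[0]), 0.5 * (self.lo[1] + self.hi[1]), R
        )
        curve = _nearest_curve(curves, self.label, mid)
        f_lo = _fraction_near(curve, SpherePoint(self.lo[0], self.lo[1] % (2 * np.pi), R))
        f_hi = _fraction_near(curve, SpherePoint(self.hi[0], self.hi[1] % (2 * np.pi), R))
        f = f_lo + u * (f_hi - f_lo)
        anchor = sample_anchor(curve, f)
        family = _LOCUS_FAMILY.get(self.label)
        if family is not None:
            anchor = refine_to_locus(anchor, family)
        return anchor, f


@dataclass(frozen=True)
class PathRecipe:
    """A validated construction plan for one class-method pair.

    ``sweep(u)`` moves both anchors along their legal spans; ``u = 0.5`` is
    the canonical path.  Auxiliary points (slow-wave third point, piecewise
    rest/bursting/end points) are fixed sphere points chosen inside the
    appropriate regions.
    """

    onset: str
    offset: str
    method: str
    onset_anchor: AnchorSpec
    offset_anchor: AnchorSpec | None  # None -> loop-back (z_offset = 0)
    waypoint: tuple[float, float] | None = None  # orients loop-back circles
    third: tuple[float, float] | None = None
    rest: tuple[float, float] | None = None
    burst: tuple[float, float] | None = None
    end: tuple[float, float] | None = None
    c: float = 3e-4
    d_star: float = 0.3
    k: float = 2e-3
    duration: float = 8000.0
    default_sigma: float = 0.0  # calibrated; populated from packaged surfaces

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.onset, self.offset, self.method)

    def build(
        self,
        curves: CurveSet | None = None,
        u: float = 0.5,
        u_onset: float | None = None,
        u_offset: float | None = None,
        c: float | None = None,
        d_star: float | None = None,
        k: float | None = None,
    ) -> BurstingPath:
        """Build the path; ``u`` sweeps both anchors together while
        ``u_onset``/``u_offset`` move them independently (the 2-D sweep used
        by noise-surface calibration and database generation)."""
        curves = curves or load_packaged_curves()
        R = curves.R
        pt = lambda th_ph: SpherePoint(th_ph[0], th_ph[1] % (2 * np.pi), R)  # noqa: E731
        u_on = u if u_onset is None else u_onset
        u_off = u if u_offset is None else u_offset
        on, f_on = self.onset_anchor.resolve(curves, u_on)
        if self.method == "hysteresis":
            cfg = HysteresisConfig(
                c=c if c is not None else self.c,
                d_star=d_star if d_star is not None else self.d_star,
            )
            if self.offset_anchor is None:
                path = build_hysteresis_path(
                    on, pt(self.waypoint), cfg, z_offset=0.0
                )
                f_off = f_on
            else:
                off, f_off = self.offset_anchor.resolve(curves, u_off)
                path = build_hysteresis_path(on, off, cfg)
        elif self.method == "slow_wave":
            off, f_off = self.offset_anchor.resolve(curves, u_off)
            cfg = SlowWaveConfig(k=k if k is not None else self.k)
            path = build_slow_wave_path(on, off, pt(self.third), cfg)
        else:
            off, f_off = self.offset_anchor.resolve(curves, u_off)
            speed = k if k is not None else self.k
            cfg = PiecewiseConfig(speeds=(speed,) * 4, end_point=pt(self.end))
            path = build_piecewise_path(pt(self.rest), on, pt(self.burst), off, cfg)
        path.metadata.update(
            {
                "dynamotype": f"{self.onset}/{self.offset}",
                "method": self.method,
                "sweep_u": u, "sweep_u_onset": u_on, "sweep_u_offset": u_off,
                "onset_fraction": f_on,
                "offset_fraction": f_off,
                "onset_curve": self.onset_anchor.label,
                "offset_curve": self.offset_anchor.label if self.offset_anchor else self.onset_anchor.label,
            }
        )
        return path


_RECIPES: list[PathRecipe] = [
    # ---- hysteresis: the five point-cycle bursters --------------------
    PathRecipe(
        "SN", "SH", "hysteresis",
        AnchorSpec("SN", (2.02, 0.22), (2.18, 0.22)),
        AnchorSpec("SH", (2.08, 0.18), (2.20, 0.13)),
    ),
    PathRecipe(
        "SN", "SNIC", "hysteresis",
        AnchorSpec("SN", (0.99, 0.22), (1.04, 0.22)),
        None, waypoint=(1.02, 0.10), c=2e-4, duration=14000.0,
    ),
    PathRecipe(
        "SN", "FLC", "hysteresis",
        AnchorSpec("SN", (2.50, 0.18), (2.56, 0.18)),
        AnchorSpec("FLC", (2.57, 6.21), (2.63, 6.17)),
    ),
    PathRecipe(
        "SubH", "SH", "hysteresis",
        AnchorSpec("SubH", (2.66, 0.16), (2.78, 0.12)),
        AnchorSpec("SH", (2.28, 0.11), (2.36, 0.08)),
        duration=16000.0,
    ),
    PathRecipe(
        "SubH", "FLC", "hysteresis",
        AnchorSpec("SubH", (2.62, 0.16), (2.68, 0.15)),
        AnchorSpec("FLC", (2.71, 6.07), (2.76, 5.99)),
    ),
    # ---- slow wave ----------------------------------------------------
    PathRecipe(
        "SNIC", "SH", "slow_wave",
        AnchorSpec("SNIC", (1.40, 0.23), (1.52, 0.24)),
        AnchorSpec("SH", (2.08, 0.18), (2.18, 0.14)),
        third=(1.85, 0.7),
    ),
    PathRecipe(
        "SNIC", "SNIC", "slow_wave",
        AnchorSpec("SNIC", (1.26, 0.23), (1.32, 0.23)),
        AnchorSpec("SNIC", (1.50, 0.24), (1.56, 0.24)),
        third=(1.40, 0.6),
    ),
    PathRecipe(
        "SNIC", "SupH", "slow_wave",
        AnchorSpec("SNIC", (1.28, 0.23), (1.40, 0.23)),
        AnchorSpec("SupH", (1.20, 2.97), (1.35, 3.05)),
        third=(1.5, 1.5),
    ),
    PathRecipe(
        "SNIC", "FLC", "slow_wave",
        AnchorSpec("SNIC", (1.44, 0.23), (1.54, 0.24)),
        AnchorSpec("FLC", (2.68, 6.10), (2.78, 5.96)),
        third=(2.2, 0.6),
    ),
    PathRecipe(
        "SupH", "SNIC", "slow_wave",
        AnchorSpec("SupH", (1.40, 3.07), (1.50, 3.12)),
        AnchorSpec("SNIC", (1.36, 0.23), (1.46, 0.23)),
        third=(1.6, 1.6),
    ),
    PathRecipe(
        "SubH", "SNIC", "slow_wave",
        AnchorSpec("SubH", (2.30, 3.39), (2.44, 3.43)),
        AnchorSpec("SNIC", (1.44, 0.23), (1.52, 0.24)),
        third=(2.0, 1.7),
    ),
    PathRecipe(
        "SupH", "FLC", "slow_wave",
        AnchorSpec("SupH", (1.22, 2.97), (1.32, 3.03)),
        AnchorSpec("FLC", (2.90, 5.30), (2.90, 5.65)),
        third=(2.3, 0.8),
    ),
    # ---- piecewise ----------------------------------------------------
    PathRecipe(
        "SupH", "SH", "piecewise",
        AnchorSpec("SupH", (1.40, 3.07), (1.50, 3.12)),
        AnchorSpec("SH", (2.08, 0.18), (2.18, 0.14)),
        rest=(1.3, 3.4), burst=(1.9, 1.2), end=(2.2, 6.2),
    ),
    PathRecipe(
        "SN", "SupH", "piecewise",
        AnchorSpec("SN", (2.10, 0.22), (2.18, 0.21)),
        AnchorSpec("SupH", (1.08, 0.90), (1.13, 1.08)),
        rest=(2.24, 0.03), burst=(1.75, 1.0), end=(0.95, 1.1),
    ),
    PathRecipe(
        "SubH", "SupH", "piecewise",
        AnchorSpec("SubH", (2.45, 3.43), (2.56, 3.47)),
        AnchorSpec("SupH", (1.40, 3.07), (1.50, 3.12)),
        rest=(2.6, 3.6), burst=(2.0, 2.2), end=(1.3, 3.3),
    ),
    PathRecipe(
        "SupH", "SupH", "piecewise",
        AnchorSpec("SupH", (1.22, 2.97), (1.30, 3.01)),
        AnchorSpec("SupH", (1.04, 2.81), (1.10, 2.87)),
        rest=(1.2, 3.3), burst=(1.4, 1.8), end=(1.0, 3.1),
    ),
    PathRecipe(
        "SNIC", "SH", "piecewise",
        AnchorSpec("SNIC", (1.42, 0.23), (1.50, 0.24)),
        AnchorSpec("SH", (2.02, 0.19), (2.10, 0.17)),
        rest=(1.45, 0.05), burst=(1.8, 0.9), end=(2.1, 0.02),
    ),
]


def recipes() -> dict[tuple[str, str, str], PathRecipe]:
    """All 17 validated class-method path recipes, keyed by
    ``(onset, offset, method)``."""
    return {r.key: r for r in _RECIPES}


def get_recipe(onset: str, offset: str, method: str | None = None) -> PathRecipe:
    """Recipe for a class; ``method`` defaults to the class's first assigned
    method."""
    spec = get_spec(onset, offset)
    method = method or spec.methods[0]
    if method not in spec.methods:
        raise KeyError(
            f"{spec.name} is not assigned the {method} method "
            f"(assigned: {', '.join(spec.methods)})"
        )
    return recipes()[(onset, offset, method)]


def _check_registry() -> None:
    specs = registry()
    assert len(specs) == 16
    assert len({s.key for s in specs}) == 16
    counts = {"hysteresis": 0, "slow_wave": 0, "piecewise": 0}
    for s in specs:
        for m in s.methods:
            counts[m] += 1
    assert counts == {"hysteresis": 5, "slow_wave": 7, "piecewise": 5}, counts
    assert sum(counts.values()) == 17
    assert {r.key for r in _RECIPES} == {
        (s.onset, s.offset, m) for s in specs for m in s.methods
    }


_check_registry()
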