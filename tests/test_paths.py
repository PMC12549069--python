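"""Path geometry on the sphere and the three slow-variable dynamics."""

import numpy as np
import pytest

from dynamotypes.integrate import IntegratorConfig, integrate
from dynamotypes.paths import (
    HysteresisConfig,
    PathConstructionError,
    PiecewiseConfig,
    SlowWaveConfig,
    build_hysteresis_path,
    build_piecewise_path,
    build_slow_wave_path,
    circle_through,
    great_circle_arc,
    hysteresis_drift,
    piecewise_drift,
    slow_wave_drift,
)
from dynamotypes.registry import get_recipe
from dynamotypes.sphere import RegionLabel, SpherePoint, classify_region

R = 0.4


def P(theta, phi):
    return SpherePoint(theta, phi % (2 * np.pi), R)


class TestGreatCircleArc:
    def test_quarter_circle_midpoint(self):
        A = SpherePoint.from_vector(np.array([R, 0, 0]))
        B = SpherePoint.from_vector(np.array([0, R, 0]))
        arc = great_circle_arc(A, B)
        assert arc.span == pytest.approx(np.pi / 2)
        mid = arc(arc.z0 + arc.span / 2)
        assert np.allclose(mid, [R / np.sqrt(2), R / np.sqrt(2), 0])

    def test_endpoints_reproduced_exactly(self):
        A, B = P(1.0, 0.3), P(1.8, 1.2)
        arc = great_circle_arc(A, B)
        assert np.allclose(arc(arc.z0), A.vector(), atol=1e-14)
        assert np.allclose(arc(arc.z1), B.vector(), atol=1e-12)

    def test_all_points_on_sphere(self):
        arc = great_circle_arc(P(0.7, 5.0), P(2.2, 2.0))
        for z in np.linspace(arc.z0, arc.z1, 17):
            assert np.linalg.norm(arc(z)) == pytest.approx(R, abs=1e-12)

    def test_antipodal_rejected(self):
        A = P(1.0, 1.0)
        B = SpherePoint.from_vector(-A.vector())
        with pytest.raises(PathConstructionError):
            great_circle_arc(A, B)


class TestCircleThrough:
    def test_equatorial_points_give_equator(self):
        pts = [P(np.pi / 2, phi) for phi in (0.0, 1.0, 2.5)]
        arc = circle_through(*pts)
        assert arc.r == pytest.approx(R, abs=1e-12)
        assert np.allclose(arc.C, 0, atol=1e-12)

    def test_passes_through_all_three_points(self):
        pts = [P(1.2, 0.5), P(1.9, 1.8), P(0.9, 3.5)]
        arc = circle_through(*pts)
        for pt in pts:
            dists = [
                np.linalg.norm(arc(z) - pt.vector())
                for z in np.linspace(0, 2 * np.pi, 3000)
            ]
            assert min(dists) < 1e-2  # on the circle (dense sampling bound)

    def test_center_matches_plane_fit_oracle(self):
        pts = [P(1.2, 0.5), P(1.9, 1.8), P(0.9, 3.5)]
        arc = circle_through(*pts)
        # least-squares plane through the three points: n . p = h
        M = np.array([p.vector() for p in pts])
        # solve for unit normal via SVD of centered points
        centroid = M.mean(axis=0)
        _, _, vt = np.linalg.svd(M - centroid)
        n = vt[-1]
        h = float(n @ centroid)
        center = h * n
        radius = np.sqrt(R * R - h * h)
        assert np.allclose(np.abs(arc.C), np.abs(center), atol=1e-10)
        assert arc.r == pytest.approx(radius, abs=1e-10)

    def test_degenerate_triple_rejected(self):
        A = P(1.0, 1.0)
        with pytest.raises(PathConstructionError):
            circle_through(A, A, P(1.5, 2.0))


class TestDrifts:
    def test_hysteresis_drift_at_rest_point(self):
        cfg = HysteresisConfig(c=1.0, d_star=0.3)
        assert hysteresis_drift(0.5, 0.0, 0.5, 0.0, cfg) == pytest.approx(0.3)

    def test_hysteresis_drift_zero_at_threshold_distance(self):
        cfg = HysteresisConfig(c=1.0, d_star=0.3)
        assert hysteresis_drift(0.8, 0.0, 0.5, 0.0, cfg) == pytest.approx(0.0)

    def test_hysteresis_drift_linear_in_c(self):
        c1 = HysteresisConfig(c=1.0, d_star=0.2)
        c2 = HysteresisConfig(c=2.0, d_star=0.2)
        d1 = hysteresis_drift(1.0, 0.5, 0.2, 0.0, c1)
        d2 = hysteresis_drift(1.0, 0.5, 0.2, 0.0, c2)
        assert d2 == pytest.approx(2 * d1)

    def test_slow_wave_drift_constant_and_signed(self):
        assert slow_wave_drift(SlowWaveConfig(k=0.002)) == 0.002
        assert slow_wave_drift(SlowWaveConfig(k=-0.002)) == -0.002
        with pytest.raises(ValueError):
            SlowWaveConfig(k=0.0)

    def test_piecewise_drift_zero_during_dwell_and_total_time(self):
        rest, on, burst, off = P(1.45, 0.05), P(1.45, 0.235), P(1.8, 0.9), P(2.06, 0.18)
        cfg = PiecewiseConfig(speeds=(1e-3,) * 4, dwells=(0.0, 50.0, 0.0))
        path = build_piecewise_path(rest, on, burst, off, cfg)
        # quadrature oracle: total = sum(arc span / speed) + dwells
        expected = sum(a.span for a in path.arcs) / 1e-3 + 50.0
        assert path.total_traversal_time == pytest.approx(expected, rel=1e-12)
        # mid-dwell time: after arcs 1+2
        t_dwell = path.arcs[0].span / 1e-3 + path.arcs[1].span / 1e-3 + 1.0
        assert piecewise_drift(t_dwell, cfg, path) == 0.0
        assert piecewise_drift(1.0, cfg, path) == 1e-3
        with pytest.raises(ValueError):
            piecewise_drift(-1.0, cfg, path)


class TestBuildPath:
    def test_hysteresis_region_sequence(self, curves):
        """The fold/homoclinic path orders regions rest -> bistable ->
        bursting along increasing z."""
        path = get_recipe("SN", "SH", "hysteresis").build(curves)
        omega = -path.z_offset
        seq = [
            classify_region(path.geometry(z))
            for z in (-2.0 * omega, -0.5 * omega, 0.5 * omega)
        ]
        assert seq == [
            RegionLabel.REST,
            RegionLabel.BISTABLE,
            RegionLabel.BURSTING,
        ]

    def test_hysteresis_validation_error_without_bistable_region(self):
        # two points deep inside the rest region: no bistable strip between
        with pytest.raises(PathConstructionError):
            build_hysteresis_path(P(0.5, 3.0), P(0.6, 3.5), validate=True)

    def test_slow_wave_path_is_closed_and_periodic(self, curves):
        path = get_recipe("SNIC", "SH", "slow_wave").build(curves)
        for z in (0.0, 1.0, 2.5):
            a = path.geometry_vector(z)
            b = path.geometry_vector(z + 2 * np.pi)
            assert np.allclose(a, b, atol=1e-12)

    def test_slow_wave_orientation_onset_then_third_then_offset(self, curves):
        path = get_recipe("SNIC", "SH", "slow_wave").build(curves)
        assert 0 < path.z_offset < 2 * np.pi

    def test_piecewise_path_passes_anchors_in_order(self, curves):
        rec = get_recipe("SNIC", "SH", "piecewise")
        path = rec.build(curves)
        assert path.z_onset == pytest.approx(path.arcs[0].z1)
        assert path.z_offset == pytest.approx(path.arcs[2].z1)
        assert not path.closed
        # terminal point is the configured end point
        end = path.geometry_vector(path.arcs[-1].z1)
        assert np.linalg.norm(end) == pytest.approx(R, abs=1e-12)

    def test_geometry_always_on_sphere(self, curves):
        for key in [("SN", "SH", "hysteresis"), ("SNIC", "SH", "slow_wave"),
                    ("SupH", "SH", "piecewise")]:
            path = get_recipe(*key).build(curves)
            for z in np.linspace(path.z_start, path.z_offset + 0.3, 50):
                assert np.linalg.norm(path.geometry_vector(z)) == pytest.approx(
                    R, abs=1e-10
                )

    def test_hysteresis_loop_alternates_rest_and_bursting(self, curves):
        """Noise-free hysteresis run revisits the seizure state repeatedly:
        at least two complete onset crossings in a long run."""
        path = get_recipe("SN", "SH", "hysteresis").build(curves)
        res = integrate(path, config=IntegratorConfig(tstep=0.05, duration=16000))
        z = res.z
        onsets = np.sum((z[1:] > 0) & (z[:-1] <= 0))
        assert onsets >= 2

    def test_path_spec_serializes_to_json(self, curves):
        path = get_recipe("SNIC", "SH", "slow_wave").build(curves)
        import json

        spec = json.loads(path.to_json())
        assert spec["kind"] == "slow_wave"
        assert spec["config"]["k"] == pytest.approx(2e-3)
        assert "onset_fraction" in spec
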