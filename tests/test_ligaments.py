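"""Ligament force law, wrapping geodesics, calibration and force application."""

from __future__ import annotations

import heapq

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import elbowsim as es
from elbowsim.errors import (
    CalibrationError,
    DegenerateGeometryError,
    ParameterError,
    StateError,
)
from elbowsim.kinematics import Pose, PoseSeries, quat_from_axis_angle


class TestForceLaw:
    def test_strain_definition(self):
        assert es.bundle_strain(50.0, 50.0) == 0.0
        assert es.bundle_strain(52.5, 50.0) == pytest.approx(0.05)
        assert es.bundle_strain(40.0, 50.0) == pytest.approx(-0.2)

    def test_strain_requires_positive_l0(self):
        with pytest.raises(ParameterError):
            es.bundle_strain(50.0, 0.0)

    def test_slack_bundle_carries_no_force(self):
        assert es.bundle_force(-0.01, k=100.0, eps_l=0.03) == 0.0

    def test_toe_region_value(self):
        # 0.25 * k * eps^2 / eps_l at eps = eps_l
        assert es.bundle_force(0.03, k=100.0, eps_l=0.03) == pytest.approx(0.75)

    def test_branches_agree_at_the_knot(self):
        k, eps_l = 100.0, 0.03
        eps = 2.0 * eps_l
        toe = 0.25 * k * eps ** 2 / eps_l
        linear = k * (eps - eps_l)
        assert toe == pytest.approx(linear, rel=1e-15)
        assert es.bundle_force(eps, k, eps_l) == pytest.approx(3.0, rel=1e-12)

    def test_c1_continuity_at_the_knot(self):
        k, eps_l = 137.0, 0.03
        knot = 2.0 * eps_l
        for h in (1e-4, 1e-6, 1e-8):
            left = (es.bundle_force(knot, k, eps_l)
                    - es.bundle_force(knot - h, k, eps_l)) / h
            right = (es.bundle_force(knot + h, k, eps_l)
                     - es.bundle_force(knot, k, eps_l)) / h
            assert left == pytest.approx(k, rel=10 * h)
            assert right == pytest.approx(k, rel=10 * h)

    @settings(deadline=None, max_examples=50)
    @given(eps=st.floats(-0.5, 0.5), k=st.floats(1.0, 5000.0),
           eps_l=st.floats(0.001, 0.2))
    def test_force_nonnegative_and_monotone(self, eps, k, eps_l):
        f = es.bundle_force(eps, k, eps_l)
        assert f >= 0.0
        assert es.bundle_force(eps + 1e-3, k, eps_l) >= f


# ---------------------------------------------------------------------------
# Wrapping
# ---------------------------------------------------------------------------

def _circle_dijkstra(p1, p2, radius, n=3000):
    """Brute-force shortest path in 2D around a circular obstacle at the
    origin: graph over circle samples plus the two endpoints."""
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    circle = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    pts = [np.asarray(p1, float), np.asarray(p2, float)] + list(circle)

    def blocked(a, b):
        d = b - a
        t = np.clip(-(a @ d) / (d @ d), 0.0, 1.0)
        return np.linalg.norm(a + t * d) < radius - 1e-9

    # edges: endpoint-to-endpoint / endpoint-to-circle when unblocked,
    # neighbouring circle samples along the arc
    dist = {0: 0.0}
    heap = [(0.0, 0)]
    adj = {}

    def neighbours(i):
        if i in adj:
            return adj[i]
        out = []
        a = pts[i]
        if i in (0, 1):
            j_other = 1 - i
            if not blocked(a, pts[j_other]):
                out.append((j_other, np.linalg.norm(a - pts[j_other])))
            for j in range(2, len(pts)):
                if not blocked(a, pts[j]):
                    out.append((j, np.linalg.norm(a - pts[j])))
        else:
            arc = 2 * np.pi * radius / n
            prev = 2 + (i - 2 - 1) % n
            nxt = 2 + (i - 2 + 1) % n
            out = [(prev, arc), (nxt, arc)]
            for j in (0, 1):
                if not blocked(a, pts[j]):
                    out.append((j, np.linalg.norm(a - pts[j])))
        adj[i] = out
        return out

    while heap:
        d, i = heapq.heappop(heap)
        if i == 1:
            return d
        if d > dist.get(i, np.inf):
            continue
        for j, w in neighbours(i):
            nd = d + w
            if nd < dist.get(j, np.inf):
                dist[j] = nd
                heapq.heappush(heap, (nd, j))
    raise RuntimeError("no path")


def _bundle(origin, insertion, via=(), wrap=(), k=100.0):
    return es.LigamentBundle(
        name="b", ligament="MCL-anterior",
        origin_body="humerus", origin_point=origin,
        insertion_body="ulna", insertion_point=insertion,
        via=via, wrap=wrap, k=k)


IDENTITY_POSES = {"humerus": Pose.identity(), "ulna": Pose.identity(),
                  "radius": Pose.identity()}


class TestWrappedLength:
    def test_straight_path_is_euclidean(self):
        b = _bundle([0, 0, 0], [30, 40, 0])
        assert es.wrapped_length(b, IDENTITY_POSES) == pytest.approx(50.0)

    def test_via_point_sums_segments(self):
        b = _bundle([0, 0, 0], [20, 0, 0], via=(("ulna", [10.0, 10.0, 0.0]),))
        assert es.wrapped_length(b, IDENTITY_POSES) == pytest.approx(
            2 * np.sqrt(200.0))

    @pytest.mark.parametrize("p1,p2,r", [
        ([-20.0, -3.0], [25.0, 4.0], 8.0),
        ([-15.0, 0.0], [15.0, 0.0], 6.0),
        ([-12.0, 7.0], [18.0, -6.5], 9.0),
    ])
    def test_sphere_wrap_matches_shortest_path_oracle(self, p1, p2, r):
        sphere = es.WrapSphere(body="humerus", center_local=[0, 0, 0], radius=r)
        b = _bundle([p1[0], p1[1], 0.0], [p2[0], p2[1], 0.0], wrap=(sphere,))
        expected = _circle_dijkstra(p1, p2, r)
        assert es.wrapped_length(b, IDENTITY_POSES) == pytest.approx(
            expected, rel=1e-5)

    def test_cylinder_wrap_unrolls_the_planar_geodesic(self):
        r = 6.0
        cyl = es.WrapCylinder(body="humerus", point_local=[0, 0, 0],
                              axis_local=[0, 0, 1], radius=r)
        planar = _circle_dijkstra([-15.0, 0.0], [15.0, 0.0], r)
        dz = 11.0
        b = _bundle([-15, 0, 0], [15, 0, dz], wrap=(cyl,))
        assert es.wrapped_length(b, IDENTITY_POSES) == pytest.approx(
            np.hypot(planar, dz), rel=1e-5)

    def test_clearing_segment_stays_straight(self):
        sphere = es.WrapSphere(body="humerus", center_local=[0, 20, 0], radius=5)
        b = _bundle([-10, 0, 0], [10, 0, 0], wrap=(sphere,))
        assert es.wrapped_length(b, IDENTITY_POSES) == pytest.approx(20.0)

    def test_attachment_inside_obstacle_raises(self):
        sphere = es.WrapSphere(body="humerus", center_local=[0, 0, 0], radius=5)
        b = _bundle([1, 0, 0], [20, 0, 0], wrap=(sphere,))
        with pytest.raises(DegenerateGeometryError):
            es.wrapped_length(b, IDENTITY_POSES)

    def test_wrapped_never_shorter_than_straight(self, rng):
        sphere = es.WrapSphere(body="humerus", center_local=[0, 0, 0], radius=7)
        for _ in range(25):
            p1 = rng.normal(size=3) * 20
            p2 = rng.normal(size=3) * 20
            if min(np.linalg.norm(p1), np.linalg.norm(p2)) <= 7.5:
                continue
            b = _bundle(p1, p2, wrap=(sphere,))
            assert (es.wrapped_length(b, IDENTITY_POSES)
                    >= np.linalg.norm(p2 - p1) - 1e-9)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _sweep_trial(angles_deg):
    """Ulna rotating about the world x axis; humerus fixed."""
    n = len(angles_deg)
    quats = np.array([quat_from_axis_angle([1, 0, 0], np.deg2rad(a))
                      for a in angles_deg])
    return es.MotionTrial(label="laxity", time=np.arange(n) * 0.01, bodies={
        "humerus": PoseSeries(np.zeros((n, 3)),
                              np.tile([1.0, 0, 0, 0], (n, 1))),
        "ulna": PoseSeries(np.zeros((n, 3)), quats),
        "radius": PoseSeries(np.zeros((n, 3)),
                             np.tile([1.0, 0, 0, 0], (n, 1))),
    })


class TestCalibration:
    def test_l0_is_factor_times_known_maximum(self):
        # origin on the rotation axis offset in x, insertion on a circle:
        # max distance over the sweep has a closed form
        origin = np.array([10.0, 0.0, 0.0])
        insertion = np.array([0.0, 0.0, -20.0])
        b = _bundle(origin, insertion)
        angles = np.linspace(0, 90, 91)
        trial = _sweep_trial(angles)
        expected_max = max(
            np.linalg.norm(Pose(np.zeros(3), quat_from_axis_angle(
                [1, 0, 0], np.deg2rad(a))).transform_points(insertion) - origin)
            for a in angles)
        cal, report = es.estimate_zero_load_lengths(
            es.LigamentComplex([b]), trial)
        assert cal.bundles[0].l0 == 0.8 * expected_max
        assert report.loc[0, "max_length_mm"] == expected_max

    def test_constant_length_bundle(self):
        b = _bundle([0, 0, 0], [0, 0, -25.0])  # on-axis: length invariant
        cal, _ = es.estimate_zero_load_lengths(
            es.LigamentComplex([b]), _sweep_trial(np.linspace(0, 60, 10)))
        assert cal.bundles[0].l0 == pytest.approx(0.8 * 25.0)

    def test_identity_factor_returns_the_maximum(self):
        b = _bundle([10, 0, 0], [0, 5, -20])
        trial = _sweep_trial(np.linspace(0, 90, 30))
        cal, report = es.estimate_zero_load_lengths(
            es.LigamentComplex([b]), trial, factor=1.0)
        assert cal.bundles[0].l0 == report.loc[0, "max_length_mm"]

    def test_empty_trial_raises(self):
        b = _bundle([0, 0, 0], [10, 0, 0])
        empty = es.MotionTrial(label="laxity", time=np.array([]), bodies={})
        with pytest.raises(CalibrationError):
            es.estimate_zero_load_lengths(es.LigamentComplex([b]), empty)


# ---------------------------------------------------------------------------
# Force application
# ---------------------------------------------------------------------------

class TestApplyForces:
    def test_uncalibrated_bundle_raises(self):
        b = _bundle([0, 0, 0], [10, 0, 0])
        with pytest.raises(StateError):
            es.apply_ligament_forces(es.LigamentComplex([b]), IDENTITY_POSES)

    def test_slack_bundles_produce_zero(self):
        b = _bundle([0, 0, 0], [10, 0, 0])
        b.l0 = 20.0  # longer than the path: slack
        wr, tensions = es.apply_ligament_forces(
            es.LigamentComplex([b]), IDENTITY_POSES)
        assert tensions["b"] == 0.0
        assert np.allclose(wr.force("humerus"), 0.0)
        assert np.allclose(wr.force("ulna"), 0.0)

    def test_taut_straight_bundle_obeys_newtons_third_law(self):
        b = _bundle([0, 0, 0], [30, 0, 0])
        b.l0 = 20.0
        wr, tensions = es.apply_ligament_forces(
            es.LigamentComplex([b]), IDENTITY_POSES)
        f_h, f_u = wr.force("humerus"), wr.force("ulna")
        assert np.allclose(f_h, -f_u)
        # collinear with the path (x axis), pulling the bodies together
        assert f_h[0] > 0 and abs(f_h[1]) < 1e-12 and abs(f_h[2]) < 1e-12
        assert tensions["b"] == pytest.approx(
            es.bundle_force(es.bundle_strain(30.0, 20.0), 100.0))

    def test_system_net_wrench_vanishes_for_random_poses(self, rng,
                                                         calibrated_subject):
        model = calibrated_subject.model
        for _ in range(5):
            poses = {}
            for name, base in calibrated_subject.neutral_poses().items():
                dq = quat_from_axis_angle(rng.normal(size=3), rng.normal() * 0.1)
                poses[name] = Pose(base.p + rng.normal(size=3),
                                   es.kinematics.quat_multiply(dq, base.q))
            wr, _ = es.apply_ligament_forces(model.ligaments, poses)
            net_f, net_tau = wr.net()
            assert np.allclose(net_f, 0.0, atol=1e-9)
            assert np.allclose(net_tau, 0.0, atol=1e-6)
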