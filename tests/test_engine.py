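"""Rigid-body integration, the two-phase protocol, and conservation checks."""

from __future__ import annotations

import numpy as np
import pytest

import elbowsim as es
from elbowsim.engine import Simulator
from elbowsim.errors import ShapeError, SolverError
from elbowsim.kinematics import (
    MotionTrial,
    Pose,
    PoseSeries,
    WrenchMap,
    quat_from_axis_angle,
)


def _free_body_model(mass=0.5, inertia=None, gravity=(0, 0, -9810.0),
                     drag=False):
    """A driven anchor plus one free body, no force elements."""
    bodies = {
        "humerus": es.RigidBody("humerus", 1.0, np.eye(3) * 100.0),
        "ball": es.RigidBody("ball", mass,
                             np.eye(3) * 50.0 if inertia is None else inertia),
    }
    return es.ElbowModel(bodies=bodies, ligaments=es.LigamentComplex([]),
                         contacts=[], muscles=[],
                         gravity=np.asarray(gravity, dtype=float),
                         body_drag_linear=0.02 if drag else 0.0,
                         body_drag_angular=2.0 if drag else 0.0)


def _static_poses():
    return {"humerus": Pose.identity(),
            "ball": Pose([0, 0, 100.0], [1, 0, 0, 0])}


class TestModelStructure:
    def test_default_model_has_18_degrees_of_freedom(self, subject):
        audit = subject.model.dof_audit()
        assert audit["generalized_coordinates"] == 18
        assert audit["kinematic_constraint_equations"] == 0
        assert audit["bodies"] == 3

    def test_inertia_validation(self):
        with pytest.raises(es.errors.ParameterError):
            es.RigidBody("x", 1.0, -np.eye(3))
        with pytest.raises(es.errors.ParameterError):
            es.RigidBody("x", -1.0, np.eye(3))


class TestStepDynamics:
    def test_zero_wrench_leaves_twist_unchanged(self):
        model = _free_body_model(gravity=(0, 0, 0))
        sim = Simulator(model, _static_poses())
        sim.set_twist("ball", es.Twist([1.0, 2.0, 3.0], [0.1, 0.0, 0.0]))
        before_v = sim.twist("ball").v.copy()
        sim.step(1e-3, WrenchMap())
        assert np.allclose(sim.twist("ball").v, before_v, atol=1e-12)

    def test_constant_force_gives_exact_velocity_increment(self):
        model = _free_body_model(mass=0.5, gravity=(0, 0, 0))
        sim = Simulator(model, _static_poses())
        w = WrenchMap()
        w.add("ball", sim.com_world("ball"), np.array([2.0, 0.0, 0.0]))
        dt = 1e-3
        sim.step(dt, w)
        # dv = F/m * dt, with N -> kg*mm/s^2 conversion
        assert sim.twist("ball").v[0] == pytest.approx(
            2.0 * 1000.0 / 0.5 * dt, rel=1e-15)

    def test_ballistic_drop_matches_closed_form(self):
        model = _free_body_model(mass=0.3)
        sim = Simulator(model, _static_poses())
        dt, t_end = 1e-4, 1.0
        z0 = sim.com_world("ball")[2]
        for _ in range(int(t_end / dt)):
            sim.step(dt, sim.accumulate_forces(dt=dt))
        drop = z0 - sim.com_world("ball")[2]
        assert drop == pytest.approx(0.5 * 9810.0 * t_end ** 2, rel=1e-3)

    def test_torque_free_rotation_conserves_angular_momentum(self):
        # symmetric top spinning off-axis; momentum-form integration keeps
        # the world angular momentum vector exact, orientation evolves
        inertia = np.diag([40.0, 40.0, 10.0])
        model = _free_body_model(mass=0.2, inertia=inertia, gravity=(0, 0, 0))
        sim = Simulator(model, _static_poses())
        sim.set_twist("ball", es.Twist([0, 0, 0], [1.0, 0.0, 2.0]))
        l0 = sim.ang_momentum["ball"].copy()
        e0 = sim.total_energy()
        for _ in range(100000):  # 10 s at 1e-4 s
            sim.step(1e-4, WrenchMap())
        l1 = sim.ang_momentum["ball"]
        assert np.linalg.norm(l1 - l0) <= 1e-12 * np.linalg.norm(l0)
        assert sim.total_energy() == pytest.approx(e0, rel=5e-3)

    def test_quaternion_stays_normalized(self):
        model = _free_body_model(gravity=(0, 0, 0))
        sim = Simulator(model, _static_poses())
        sim.set_twist("ball", es.Twist([0, 0, 0], [3.0, 2.0, 1.0]))
        for _ in range(1000):
            sim.step(1e-3, WrenchMap())
        assert np.linalg.norm(sim.poses["ball"].q) == pytest.approx(
            1.0, abs=1e-9)

    def test_divergence_raises_solver_error(self):
        model = _free_body_model(gravity=(0, 0, 0))
        sim = Simulator(model, _static_poses())
        w = WrenchMap()
        w.add("ball", np.zeros(3), np.array([1e9, 0.0, 0.0]))
        with pytest.raises(SolverError):
            for _ in range(10):
                sim.step(1e-3, w)

    def test_step_dynamics_entry_point(self):
        model = _free_body_model()
        sim = Simulator(model, _static_poses())
        es.step_dynamics(sim, 1e-4)
        assert sim.t == pytest.approx(1e-4)


class TestEnergyBehaviour:
    def test_conservative_suspension_energy_drift_below_one_percent(self):
        """Ulna-like body suspended by elastic bundles, no gravity, no drag,
        no contact: total energy over 10 s at dt = 1e-4 s."""
        bodies = {
            "humerus": es.RigidBody("humerus", 1.0, np.eye(3) * 100.0),
            "ulna": es.RigidBody("ulna", 0.08, np.diag([400.0, 400.0, 3.0]),
                                 com_local=[0, 0, -120.0]),
        }
        bundles = []
        for i, (ox, iy) in enumerate([(10.0, 8.0), (-10.0, -8.0), (0.0, 0.0)]):
            bundles.append(es.LigamentBundle(
                name=f"s{i}", ligament="MCL-anterior",
                origin_body="humerus", origin_point=[ox, 0.0, 0.0],
                insertion_body="ulna", insertion_point=[iy, 0.0, -25.0],
                k=10.0, l0=0.8 * 25.0))
        model = es.ElbowModel(
            bodies=bodies, ligaments=es.LigamentComplex(bundles), contacts=[],
            muscles=[], gravity=np.zeros(3),
            body_drag_linear=0.0, body_drag_angular=0.0)
        sim = Simulator(model, {"humerus": Pose.identity(),
                                "ulna": Pose([0, 0, 2.0], [1, 0, 0, 0])})
        e0 = sim.total_energy()
        assert e0 > 0.0  # taut bundles store elastic energy
        energies = []
        for step in range(100000):  # 10 s at 1e-4 s
            sim.step(1e-4, sim.accumulate_forces(dt=1e-4))
            if step % 100 == 0:
                energies.append(sim.total_energy())
        energies = np.asarray(energies)
        final_mean = energies[-100:].mean()
        assert abs(final_mean - e0) / e0 < 0.01
        assert np.abs(energies - e0).max() / e0 < 0.02  # bounded oscillation


class TestTwoPhaseProtocol:
    def test_ik_replays_poses_and_records_lengths(self, calibrated_subject,
                                                  trial_60, ik_60):
        assert ik_60.trial is trial_60  # kinematic replay: poses untouched
        assert list(ik_60.muscle_lengths.columns) == [
            m.name for m in calibrated_subject.model.muscles]
        assert len(ik_60.muscle_lengths) == trial_60.n_frames
        assert np.all(np.isfinite(ik_60.muscle_lengths.to_numpy()))

    def test_static_trial_gives_constant_targets(self, calibrated_subject):
        subj = calibrated_subject
        poses = subj.neutral_poses()
        n = 5
        trial = MotionTrial(label="static", time=np.arange(n) * 0.01, bodies={
            name: PoseSeries(np.tile(p.p, (n, 1)), np.tile(p.q, (n, 1)))
            for name, p in poses.items()})
        ik = es.run_inverse_kinematics(subj.model, trial)
        assert np.allclose(ik.muscle_lengths.std(), 0.0, atol=1e-12)

    def test_nonuniform_time_grid_rejected(self, calibrated_subject):
        poses = calibrated_subject.neutral_poses()
        t = np.array([0.0, 0.01, 0.05, 0.06])
        trial = MotionTrial(label="bad", time=t, bodies={
            name: PoseSeries(np.tile(p.p, (4, 1)), np.tile(p.q, (4, 1)))
            for name, p in poses.items()})
        with pytest.raises(ShapeError):
            es.run_inverse_kinematics(calibrated_subject.model, trial)

    def test_flexors_shorten_monotonically_during_flexion(self,
                                                          calibrated_subject):
        subj = calibrated_subject
        trial = es.generate_trial(subj, es.TrialSpec(
            label="60deg_s", seed=0, noise_pos_mm=0.0, noise_rot_deg=0.0))
        ik = es.run_inverse_kinematics(subj.model, trial)
        half = trial.n_frames // 2
        for muscle in ("biceps-long", "biceps-short", "brachialis"):
            up = ik.muscle_lengths[muscle].to_numpy()[:half]
            assert np.all(np.diff(up) <= 1e-9), f"{muscle} not shortening"
        # and the triceps heads lengthen
        for muscle in ("triceps-long", "triceps-lateral", "triceps-medial"):
            up = ik.muscle_lengths[muscle].to_numpy()[:half]
            assert np.all(np.diff(up) >= -1e-9), f"{muscle} not lengthening"

    def test_forward_dynamics_is_deterministic(self, calibrated_subject,
                                               ik_60):
        r1 = es.run_forward_dynamics(calibrated_subject.model, ik_60,
                                     duration=0.05)
        r2 = es.run_forward_dynamics(calibrated_subject.model, ik_60,
                                     duration=0.05)
        for body in ("ulna", "radius"):
            assert np.array_equal(r1.poses[body].positions,
                                  r2.poses[body].positions)
            assert np.array_equal(r1.poses[body].quaternions,
                                  r2.poses[body].quaternions)
        assert r1.muscle_forces.equals(r2.muscle_forces)

    def test_result_series_share_the_output_grid(self, fd_60):
        n = len(fd_60.time)
        assert all(len(fd_60.poses[b].positions) == n for b in fd_60.poses)
        assert len(fd_60.muscle_forces) == n
        assert len(fd_60.bundle_tensions) == n
        assert np.allclose(np.diff(fd_60.time), 0.01, atol=1e-9)

    def test_equilibrium_without_forcing(self):
        """No muscles, no gravity, slack ligaments, separated contact:
        bodies stay exactly at rest."""
        model = _free_body_model(gravity=(0, 0, 0))
        sim = Simulator(model, _static_poses())
        p0 = sim.poses["ball"].p.copy()
        for _ in range(100):
            sim.step(1e-3, sim.accumulate_forces(dt=1e-3))
        assert np.array_equal(sim.poses["ball"].p, p0)
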