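"""Rigid-body dynamics of the three elbow bones and the two-phase protocol.

The model has no kinematic joints: humerus, ulna and radius are free rigid
bodies (18 degrees of freedom) constrained only by ligament bundles and
compliant cartilage contact.  Simulation runs in two phases:

1. **Inverse kinematics** — the bones replay the recorded motion exactly and
   the shortening/lengthening pattern of every muscle path is recorded.
2. **Forward dynamics** — the kinematic constraints are dropped; the humerus
   is prescribed from the trial (motion driver) while ulna and radius evolve
   under gravity, ligament, contact and muscle forces, the muscles being PID
   actuators tracking the recorded length targets.

Integration is fixed-step semi-implicit (symplectic) Euler in momentum form:
linear and angular momentum are updated from the accumulated wrenches, then
poses from the new velocities.  Torque-free angular momentum is therefore
conserved exactly.  Units: mm, kg, N, N*mm; energies are reported in N*mm
(mJ).  The internal step defaults to 1e-4 s with outputs resampled to the
0.01 s reporting step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contact import (
    AnalyticSocket,
    ContactParameters,
    aggregate_contact,
    detect_penetrations,
    element_contact_force,
    smooth_step,
)
from .errors import ParameterError, ShapeError, SolverError, StateError
from .geometry import CartilageElementGrid, SurfaceMesh
from .kinematics import (
    MotionTrial,
    Pose,
    PoseSeries,
    Twist,
    WrenchMap,
    quat_from_rotvec,
    quat_multiply,
    quat_normalize,
    quat_slerp,
    quat_to_matrix,
)
from .ligaments import LigamentComplex, apply_ligament_forces, bundle_strain
from .muscles import MuscleActuator, apply_muscle_forces, muscle_length, pid_update

log = logging.getLogger(__name__)

GRAVITY_MM_S2 = np.array([0.0, 0.0, -9810.0])

# conversion: 1 N = 1000 kg*mm/s^2 and 1 N*mm = 1000 kg*mm^2/s^2
_N_TO_KG_MM = 1000.0


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class RigidBody:
    """A bone segment: mass properties plus the body-frame location of its
    centre of mass.  Inertia is about the COM, in the body frame (kg*mm^2)."""

    name: str
    mass: float
    inertia: np.ndarray
    com_local: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        self.com_local = np.asarray(self.com_local, dtype=float).reshape(3)
        if self.mass <= 0:
            raise ParameterError(f"body {self.name}: mass must be positive")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-9):
            raise ParameterError(f"body {self.name}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ParameterError(f"body {self.name}: inertia must be positive-definite")


@dataclass
class ContactPair:
    """A cartilage element grid against an opposing bearing surface."""

    name: str
    grid: CartilageElementGrid
    opposing: SurfaceMesh | AnalyticSocket
    params: ContactParameters = field(default_factory=ContactParameters)

    @property
    def opposing_body(self) -> str:
        if isinstance(self.opposing, SurfaceMesh):
            return self.opposing.body_name
        return self.opposing.body


@dataclass
class ElbowModel:
    """The assembled musculoskeletal elbow: bodies, passive constraints and
    muscle actuators.  ``driven_body`` is prescribed from the trial during
    forward dynamics; all other bodies are free."""

    bodies: dict[str, RigidBody]
    ligaments: LigamentComplex
    contacts: list[ContactPair]
    muscles: list[MuscleActuator]
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY_MM_S2.copy())
    driven_body: str = "humerus"
    meshes: dict[str, SurfaceMesh] = field(default_factory=dict)
    #: peri-articular soft-tissue dissipation on free bodies (the bones-only
    #: model has elastic ligaments and frictionless contact, so without this
    #: term millimetre-scale joint rattle is undamped).  Set both to zero for
    #: conservative-energy studies.
    body_drag_linear: float = 0.02   # N*s/mm on the COM velocity
    body_drag_angular: float = 2.0   # N*mm*s/rad on the angular velocity

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float).reshape(3)

    def dof_audit(self) -> dict[str, int]:
        """Count generalized coordinates before any motion driver is applied:
        every body contributes 6 DOF and there are no kinematic joints."""
        return {
            "bodies": len(self.bodies),
            "generalized_coordinates": 6 * len(self.bodies),
            "kinematic_constraint_equations": 0,
        }

    def free_bodies(self) -> list[str]:
        return [name for name in self.bodies if name != self.driven_body]


# ---------------------------------------------------------------------------
# Phase 1: inverse kinematics
# ---------------------------------------------------------------------------

@dataclass
class IKResult:
    """Recorded muscle length targets plus the reference motion."""

    trial: MotionTrial
    time: np.ndarray
    muscle_lengths: pd.DataFrame          # one column per muscle, mm
    bundle_tensions: pd.DataFrame | None = None

    def target_matrix(self, times: np.ndarray) -> np.ndarray:
        """Length targets linearly interpolated onto arbitrary times."""
        out = np.empty((len(times), self.muscle_lengths.shape[1]))
        for j, col in enumerate(self.muscle_lengths.columns):
            out[:, j] = np.interp(times, self.time,
                                  self.muscle_lengths[col].to_numpy())
        return out


def run_inverse_kinematics(model: ElbowModel, trial: MotionTrial,
                           record_tensions: bool = False) -> IKResult:
    """Replay the trial poses exactly and record per-step muscle lengths.

    Passive forces may be evaluated for reporting but never alter the motion.
    """
    if trial.n_frames == 0:
        raise ShapeError("trial contains no frames")
    if not trial.is_uniform():
        raise ShapeError("trial time grid must be uniform")
    lengths = np.empty((trial.n_frames, len(model.muscles)))
    tensions = [] if record_tensions and model.ligaments.is_calibrated() else None
    for i in range(trial.n_frames):
        poses = trial.frame(i)
        for j, muscle in enumerate(model.muscles):
            lengths[i, j] = muscle_length(muscle, poses)
        if tensions is not None:
            _, tens = apply_ligament_forces(model.ligaments, poses)
            tensions.append(tens)
    muscle_df = pd.DataFrame(lengths, columns=[m.name for m in model.muscles])
    tension_df = pd.DataFrame(tensions) if tensions else None
    return IKResult(trial=trial, time=trial.time.copy(),
                    muscle_lengths=muscle_df, bundle_tensions=tension_df)


# ---------------------------------------------------------------------------
# Phase 2: forward dynamics
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Output series of a forward-dynamics run, on the reporting time grid."""

    label: str
    time: np.ndarray
    poses: dict[str, PoseSeries]
    bundle_tensions: pd.DataFrame
    muscle_forces: pd.DataFrame
    muscle_lengths: pd.DataFrame
    contact_summary: pd.DataFrame
    element_peak_force: dict[str, np.ndarray] = field(default_factory=dict)

    def trial(self) -> MotionTrial:
        """The simulated poses repackaged as a motion trial."""
        return MotionTrial(label=f"{self.label}-fd", time=self.time,
                           bodies=self.poses)

    def save_csv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.trial().to_csv(directory / "poses.csv")
        for name, df in [("bundle_tensions", self.bundle_tensions),
                         ("muscle_forces", self.muscle_forces),
                         ("muscle_lengths", self.muscle_lengths),
                         ("contact_summary", self.contact_summary)]:
            out = df.copy()
            if len(out) == len(self.time) and "time_s" not in out.columns:
                out.insert(0, "time_s", self.time)
            out.to_csv(directory / f"{name}.csv", index=False)
        for pair_name, peaks in self.element_peak_force.items():
            pd.DataFrame({"element_id": np.arange(len(peaks)),
                          "peak_force_N": peaks}).to_csv(
                directory / f"peak_element_force_{pair_name}.csv", index=False)


class Simulator:
    """Explicit state holder for stepping the model; used by
    :func:`run_forward_dynamics` and directly by low-level tests."""

    def __init__(self, model: ElbowModel,
                 initial_poses: Mapping[str, Pose],
                 driver: MotionTrial | None = None) -> None:
        self.model = model
        self.driver = driver
        self.t = 0.0
        self.poses: dict[str, Pose] = {n: initial_poses[n] for n in model.bodies}
        # momentum state for free bodies: linear (kg*mm/s) and angular about
        # the COM in world coordinates (kg*mm^2/s)
        self.lin_momentum = {n: np.zeros(3) for n in model.free_bodies()}
        self.ang_momentum = {n: np.zeros(3) for n in model.free_bodies()}
        self.driver_twist = Twist.zero()
        self.last_tensions: dict[str, float] = {}
        self.last_muscle_forces = np.zeros(len(model.muscles))
        self.last_muscle_lengths = np.zeros(len(model.muscles))
        self.last_contact: list[tuple[ContactPair, np.ndarray, np.ndarray, np.ndarray]] = []

    # -- state helpers ----------------------------------------------------

    def com_world(self, name: str) -> np.ndarray:
        pose = self.poses[name]
        return pose.transform_points(self.model.bodies[name].com_local)

    def twist(self, name: str) -> Twist:
        if name == self.model.driven_body:
            return self.driver_twist
        body = self.model.bodies[name]
        pose = self.poses[name]
        v_com = self.lin_momentum[name] / body.mass
        R = pose.R
        inertia_world_inv = R @ np.linalg.inv(body.inertia) @ R.T
        w = inertia_world_inv @ self.ang_momentum[name]
        com = pose.transform_points(body.com_local)
        v_origin = v_com + np.cross(w, pose.p - com)
        return Twist(v_origin, w)

    def set_twist(self, name: str, twist: Twist) -> None:
        body = self.model.bodies[name]
        pose = self.poses[name]
        com = pose.transform_points(body.com_local)
        v_com = twist.v + np.cross(twist.w, com - pose.p)
        self.lin_momentum[name] = body.mass * v_com
        R = pose.R
        self.ang_momentum[name] = (R @ body.inertia @ R.T) @ twist.w

    def velocities(self) -> dict[str, Twist]:
        return {n: self.twist(n) for n in self.model.bodies}

    # -- forces -----------------------------------------------------------

    def accumulate_forces(self, targets: np.ndarray | None = None,
                          dt: float = 1e-4) -> WrenchMap:
        """Evaluate gravity, ligament, contact and muscle forces at the
        current state.  ``targets`` are this step's muscle length targets;
        when None the muscles are inactive."""
        model = self.model
        poses = self.poses
        velocities = self.velocities()
        wrench = WrenchMap()

        for name, body in model.bodies.items():
            com = poses[name].transform_points(body.com_local)
            wrench.add(name, com, body.mass * model.gravity / _N_TO_KG_MM)
        if model.body_drag_linear > 0.0 or model.body_drag_angular > 0.0:
            for name in model.free_bodies():
                tw = velocities[name]
                body = model.bodies[name]
                com = poses[name].transform_points(body.com_local)
                v_com = tw.point_velocity(com, poses[name].p)
                wrench.add(name, com, -model.body_drag_linear * v_com)
                # a pure couple is origin-independent
                wrench.add_wrench(name, np.zeros(3),
                                  -model.body_drag_angular * tw.w)

        if model.ligaments.n_bundles:
            lig_wrench, tensions = apply_ligament_forces(model.ligaments, poses)
            wrench = wrench.merged(lig_wrench)
            self.last_tensions = tensions

        if model.muscles and targets is not None:
            lengths = np.array([muscle_length(m, poses) for m in model.muscles])
            forces = np.array([
                pid_update(m, targets[j], lengths[j], dt)
                for j, m in enumerate(model.muscles)])
            wrench = wrench.merged(apply_muscle_forces(model.muscles, poses, forces))
            self.last_muscle_forces = forces
            self.last_muscle_lengths = lengths

        self.last_contact = []
        for pair in model.contacts:
            depth, rate = detect_penetrations(pair.grid, pair.opposing,
                                              poses, velocities)
            forces = np.zeros_like(depth)
            loaded = depth > 0.0
            if np.any(loaded):
                gp = poses[pair.grid.parent_body]
                pts = gp.transform_points(pair.grid.centroids[loaded])
                nrm = gp.transform_vectors(pair.grid.normals[loaded])
                forces[loaded] = self._stable_contact_forces(
                    pair, depth[loaded], rate[loaded], pts, nrm, dt)
                f_vec = forces[loaded, None] * nrm
                wrench.add_points(pair.grid.parent_body, pts, -f_vec)
                wrench.add_points(pair.opposing_body, pts, f_vec)
            self.last_contact.append((pair, depth, rate, forces))
        return wrench

    def _stable_contact_forces(self, pair: ContactPair, depth: np.ndarray,
                               rate: np.ndarray, pts: np.ndarray,
                               nrm: np.ndarray, dt: float) -> np.ndarray:
        """Contact force on the loaded elements, with an explicit-integration
        damping limiter.

        The elastic term is the pure power law.  The damping coefficient of
        each element is capped so the viscous impulse over one step cannot
        exceed half of what would annihilate the pair's relative momentum in
        that element's normal direction — including the rotational part of
        the effective mass, since the damping torque about a slender bone's
        long axis is otherwise far stiffer than the explicit step can carry.
        The cap keeps the term strictly dissipative.
        """
        p = pair.params
        n_loaded = len(depth)
        elastic = p.kc * np.power(depth, p.n)
        c_model = smooth_step(depth / p.d_max) * p.c_max
        # per-element inverse effective mass along the contact normal
        inv_meff = np.zeros(n_loaded)
        free = set(self.model.free_bodies())
        for body in (pair.grid.parent_body, pair.opposing_body):
            if body not in free:
                continue
            b = self.model.bodies[body]
            pose = self.poses[body]
            com = pose.transform_points(b.com_local)
            lever = np.cross(pts - com, nrm)
            inertia_world_inv = pose.R @ np.linalg.inv(b.inertia) @ pose.R.T
            inv_meff += (1.0 / b.mass
                         + np.einsum("ij,jk,ik->i", lever, inertia_world_inv,
                                     lever))
        if np.any(inv_meff > 0.0):
            with np.errstate(divide="ignore"):
                m_eff = np.where(inv_meff > 0, 1.0 / inv_meff, np.inf)
            c_cap = 0.5 * m_eff / (dt * n_loaded * _N_TO_KG_MM)  # N*s/mm
            c_eff = np.minimum(c_model, c_cap)
        else:
            c_eff = c_model
        return np.maximum(elastic + c_eff * rate, 0.0)

    def suggest_substeps(self, dt: float, target_omega_dt: float = 0.3,
                         max_rate_step: float = 0.02,
                         max_substeps: int = 256) -> int:
        """Sub-steps needed to carry the engaged contact stably.

        Two triggers, both from the last evaluated contact state: (1) the
        linearized contact frequency — translational plus rotational, since
        the slender bones have small inertias about their long axes — must
        stay below ``target_omega_dt`` per sub-step; (2) the penetration
        change per sub-step must stay below ``max_rate_step`` mm so the
        hardening power law cannot deepen explosively within one step.
        """
        free = set(self.model.free_bodies())
        omega_sq = {name: 0.0 for name in free}
        max_rate = 0.0
        for pair, depth, rate, _ in self.last_contact:
            loaded = depth > 0.0
            if not np.any(loaded):
                continue
            max_rate = max(max_rate, float(np.abs(rate[loaded]).max()))
            p = pair.params
            k_el = p.n * p.kc * np.power(depth[loaded], p.n - 1.0)
            gp = self.poses[pair.grid.parent_body]
            pts = gp.transform_points(pair.grid.centroids[loaded])
            nrm = gp.transform_vectors(pair.grid.normals[loaded])
            k_lin = float(k_el.sum())
            for body in (pair.grid.parent_body, pair.opposing_body):
                if body not in free:
                    continue
                b = self.model.bodies[body]
                pose = self.poses[body]
                com = pose.transform_points(b.com_local)
                lever = np.cross(pts - com, nrm)
                inertia_world = np.diag(pose.R @ b.inertia @ pose.R.T)
                k_rot = (k_el[:, None] * lever ** 2).sum(axis=0)
                omega_sq[body] += _N_TO_KG_MM * (
                    k_lin / b.mass + float((k_rot / inertia_world).max()))
        n_sub = 1
        if omega_sq:
            w_max = np.sqrt(max(omega_sq.values()))
            n_sub = max(n_sub, int(np.ceil(w_max * dt / target_omega_dt)))
        n_sub = max(n_sub, int(np.ceil(max_rate * dt / max_rate_step)))
        return min(n_sub, max_substeps)

    # -- integration ------------------------------------------------------

    def step(self, dt: float, wrench: WrenchMap,
             next_driven_pose: Pose | None = None) -> None:
        """One semi-implicit Euler step: momenta first, then poses."""
        model = self.model
        for name in model.free_bodies():
            body = model.bodies[name]
            pose = self.poses[name]
            com = pose.transform_points(body.com_local)
            force = wrench.force(name)
            torque = wrench.torque_about(name, com)
            if not (np.all(np.isfinite(force)) and np.all(np.isfinite(torque))):
                raise SolverError(f"non-finite wrench on body '{name}' at t={self.t:.6f}")
            self.lin_momentum[name] = self.lin_momentum[name] + force * _N_TO_KG_MM * dt
            self.ang_momentum[name] = self.ang_momentum[name] + torque * _N_TO_KG_MM * dt

            v_com = self.lin_momentum[name] / body.mass
            R = pose.R
            w = R @ np.linalg.solve(body.inertia, R.T @ self.ang_momentum[name])
            if np.linalg.norm(v_com) > 1e6 or np.linalg.norm(w) > 1e4:
                raise SolverError(
                    f"divergence on body '{name}' at t={self.t:.6f}: "
                    f"|v|={np.linalg.norm(v_com):.3g} mm/s, "
                    f"|w|={np.linalg.norm(w):.3g} rad/s")
            com_new = com + v_com * dt
            q_new = quat_normalize(quat_multiply(quat_from_rotvec(w * dt), pose.q))
            R_new = quat_to_matrix(q_new)
            origin_new = com_new - R_new @ body.com_local
            self.poses[name] = Pose(origin_new, q_new)

        if next_driven_pose is not None:
            name = model.driven_body
            old = self.poses[name]
            self.poses[name] = next_driven_pose
            dq = quat_multiply(next_driven_pose.q,
                               old.q * np.array([1.0, -1.0, -1.0, -1.0]))
            dq = quat_normalize(dq)
            angle = 2.0 * np.arctan2(np.linalg.norm(dq[1:]), dq[0])
            axis = dq[1:] / np.linalg.norm(dq[1:]) if angle > 1e-12 else np.zeros(3)
            self.driver_twist = Twist((next_driven_pose.p - old.p) / dt,
                                      axis * angle / dt)
        self.t += dt

    # -- diagnostics ------------------------------------------------------

    def total_energy(self) -> float:
        """Kinetic + gravitational + ligament + contact elastic energy (N*mm).

        Meaningful for conservative configurations (no contact damping, no
        muscles); gravity potential is referenced to the world origin."""
        model = self.model
        total = 0.0
        for name in model.free_bodies():
            body = model.bodies[name]
            pose = self.poses[name]
            v_com = self.lin_momentum[name] / body.mass
            R = pose.R
            w = R @ np.linalg.solve(body.inertia, R.T @ self.ang_momentum[name])
            total += 0.5 * body.mass * float(v_com @ v_com) / _N_TO_KG_MM
            total += 0.5 * float(w @ (R @ body.inertia @ R.T @ w)) / _N_TO_KG_MM
        for name, body in model.bodies.items():
            com = self.poses[name].transform_points(body.com_local)
            total -= body.mass * float(model.gravity @ com) / _N_TO_KG_MM
        for bundle in model.ligaments.bundles:
            if bundle.l0 is None:
                continue
            from .ligaments import wrapped_length

            eps = bundle_strain(wrapped_length(bundle, self.poses), bundle.l0)
            total += _ligament_energy(eps, bundle.k, bundle.eps_l) * bundle.l0
        for pair in model.contacts:
            depth, _ = detect_penetrations(pair.grid, pair.opposing, self.poses)
            p = pair.params
            total += float(np.sum(p.kc * np.power(np.maximum(depth, 0.0), p.n + 1.0)
                                  / (p.n + 1.0)))
        return total


def _ligament_energy(eps: float, k: float, eps_l: float) -> float:
    """Elastic energy per unit zero-load length (N) stored at strain eps."""
    if eps <= 0.0:
        return 0.0
    if eps <= 2.0 * eps_l:
        return 0.25 * k * eps ** 3 / (3.0 * eps_l)
    toe = 0.25 * k * (2.0 * eps_l) ** 3 / (3.0 * eps_l)
    return toe + 0.5 * k * ((eps - eps_l) ** 2 - eps_l ** 2)


def step_dynamics(sim: Simulator, dt: float,
                  targets: np.ndarray | None = None) -> Simulator:
    """Accumulate all force elements at the current state and advance one
    fixed step (semi-implicit Euler; quaternions renormalized)."""
    wrench = sim.accumulate_forces(targets=targets, dt=dt)
    sim.step(dt, wrench)
    return sim


def run_forward_dynamics(model: ElbowModel, ik: IKResult,
                         dt: float = 1e-4, dt_output: float = 0.01,
                         duration: float | None = None,
                         store_tension_history: bool = True,
                         ) -> SimulationResult:
    """Muscle-driven forward dynamics tracking the IK length targets.

    The driven body follows the trial; the remaining bodies start at the
    first trial frame with zero twist and evolve freely.  Outputs are
    recorded every ``dt_output`` (default 0.01 s).
    """
    if dt <= 0 or dt_output < dt:
        raise ParameterError("need dt > 0 and dt_output >= dt")
    if not model.ligaments.is_calibrated() and model.ligaments.n_bundles:
        raise StateError("ligaments are not calibrated; run the laxity "
                         "calibration first")
    trial = ik.trial
    span = float(trial.time[-1] - trial.time[0]) if trial.n_frames > 1 else 0.0
    duration = span if duration is None else min(duration, span)
    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(dt_output / dt)))

    for m in model.muscles:
        m.reset()

    t0 = float(trial.time[0]) if trial.n_frames else 0.0
    times = t0 + dt * np.arange(n_steps + 1)
    targets = ik.target_matrix(times) if model.muscles else None

    # precompute the driven body's pose at every substep
    driven = model.driven_body
    drv_p = np.empty((n_steps + 1, 3))
    drv_q = np.empty((n_steps + 1, 4))
    if driven in trial.bodies:
        series = trial.bodies[driven]
        for k, t in enumerate(times):
            i = int(np.clip(np.searchsorted(trial.time, t, side="right") - 1,
                            0, trial.n_frames - 2)) if trial.n_frames > 1 else 0
            if trial.n_frames == 1:
                drv_p[k], drv_q[k] = series.positions[0], series.quaternions[0]
            else:
                frac = (t - trial.time[i]) / (trial.time[i + 1] - trial.time[i])
                frac = float(np.clip(frac, 0.0, 1.0))
                drv_p[k] = (1 - frac) * series.positions[i] + frac * series.positions[i + 1]
                drv_q[k] = quat_slerp(series.quaternions[i], series.quaternions[i + 1], frac)
    else:
        raise StateError(f"trial lacks poses for driven body '{driven}'")

    sim = Simulator(model, trial.frame(0))
    sim.t = t0
    # prime the contact state so the first step is already sub-stepped if the
    # (possibly noisy) initial frame starts in contact
    for pair in model.contacts:
        depth0, rate0 = detect_penetrations(pair.grid, pair.opposing,
                                            sim.poses, sim.velocities())
        sim.last_contact.append((pair, depth0, rate0, np.zeros_like(depth0)))

    n_out = n_steps // rec_every + 1
    out_time = np.empty(n_out)
    out_pos = {n: np.empty((n_out, 3)) for n in model.bodies}
    out_quat = {n: np.empty((n_out, 4)) for n in model.bodies}
    bundle_names = [b.name for b in model.ligaments.bundles]
    out_tension = np.zeros((n_out, len(bundle_names)))
    muscle_names = [m.name for m in model.muscles]
    out_mforce = np.zeros((n_out, len(muscle_names)))
    out_mlength = np.zeros((n_out, len(muscle_names)))
    contact_rows: list[dict] = []
    peak_force = {p.name: np.zeros(p.grid.n_elements) for p in model.contacts}

    def record(slot: int) -> None:
        out_time[slot] = sim.t
        for n in model.bodies:
            out_pos[n][slot] = sim.poses[n].p
            out_quat[n][slot] = sim.poses[n].q
        if bundle_names:
            out_tension[slot] = [sim.last_tensions.get(b, 0.0) for b in bundle_names]
        if muscle_names:
            out_mforce[slot] = sim.last_muscle_forces
            out_mlength[slot] = sim.last_muscle_lengths
        if sim.last_contact:
            state = aggregate_contact(
                [p.grid for p, *_ in sim.last_contact],
                [f for *_, f in sim.last_contact],
                depths=[d for _, d, _, _ in sim.last_contact],
                rates=[r for _, _, r, _ in sim.last_contact],
                poses=sim.poses)
            for row in state.per_compartment().to_dict("records"):
                row["time_s"] = sim.t
                contact_rows.append(row)

    def check_and_track(step_index: int) -> None:
        for pair, depth, _, forces in sim.last_contact:
            np.maximum(peak_force[pair.name], forces, out=peak_force[pair.name])
            if depth.max(initial=0.0) > 5.0:
                raise SolverError(
                    f"contact pair '{pair.name}': penetration "
                    f"{depth.max():.2f} mm at t={sim.t:.4f} s (step {step_index})")

    slot = 0
    for k in range(n_steps + 1):
        # sub-step while the hardening contact is stiffer than the base step
        # can stably carry (decided from the contact state just evaluated)
        n_sub = sim.suggest_substeps(dt)
        dt_sub = dt / n_sub
        for j in range(n_sub):
            wrench = sim.accumulate_forces(
                targets=targets[k] if targets is not None else None, dt=dt_sub)
            check_and_track(k)
            if j == 0 and k % rec_every == 0:
                record(slot)
                slot += 1
            if k == n_steps:
                break
            frac = (j + 1) / n_sub
            drv_pose = Pose(
                (1 - frac) * drv_p[k] + frac * drv_p[k + 1],
                quat_slerp(drv_q[k], drv_q[k + 1], frac))
            sim.step(dt_sub, wrench, next_driven_pose=drv_pose)
        if k == n_steps:
            break

    poses_out = {n: PoseSeries(out_pos[n][:slot], out_quat[n][:slot])
                 for n in model.bodies}
    contact_df = pd.DataFrame(
        contact_rows, columns=["time_s", "compartment", "contact_area_mm2",
                               "peak_pressure_MPa", "total_force_N"])
    return SimulationResult(
        label=trial.label,
        time=out_time[:slot],
        poses=poses_out,
        bundle_tensions=pd.DataFrame(out_tension[:slot], columns=bundle_names),
        muscle_forces=pd.DataFrame(out_mforce[:slot], columns=muscle_names),
        muscle_lengths=pd.DataFrame(out_mlength[:slot], columns=muscle_names),
        contact_summary=contact_df,
        element_peak_force=peak_force,
    )
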