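"""Muscle path geometry and PID force control.

Muscles are origin -> via points -> insertion polylines.  During forward
dynamics each muscle's force comes from a discrete PID controller that drives
the current path length toward the length recorded during inverse kinematics:

    e = l_current - l_target           (a longer-than-target muscle pulls)
    u = P*e + I*sum(e*dt) + D*(e - e_prev)/dt
    force = clamp(u, 0, F_max)         (muscles pull, never push)

Per-muscle gains scale linearly with physiological cross-sectional area:
gain_i = (PCSA_i / reference PCSA) * global gain, with global (P, I, D) =
(50, 5, 0.0005) and reference PCSA 487 mm^2.  Integral accumulation freezes
while the output is clamped (anti-windup), which the clamp makes necessary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError, StateError
from .kinematics import Pose, WrenchMap

log = logging.getLogger(__name__)


@dataclass
class GainSchedule:
    """Global PID gains and the reference PCSA used for linear scaling."""

    global_p: float = 50.0
    global_i: float = 5.0
    global_d: float = 0.0005
    reference_pcsa: float = 487.0  # mm^2

    def __post_init__(self) -> None:
        if min(self.global_p, self.global_i, self.global_d) <= 0:
            raise ParameterError("global PID gains must all be positive")
        if self.reference_pcsa <= 0:
            raise ParameterError("reference PCSA must be positive")


def scale_gains(pcsa: float, schedule: GainSchedule | None = None,
                ) -> tuple[float, float, float]:
    """PID gains for a muscle of the given PCSA: (PCSA / reference) * global."""
    schedule = schedule or GainSchedule()
    if pcsa <= 0:
        raise ParameterError(f"PCSA must be positive, got {pcsa}")
    ratio = pcsa / schedule.reference_pcsa
    return (ratio * schedule.global_p, ratio * schedule.global_i,
            ratio * schedule.global_d)


@dataclass
class PIDState:
    """Discrete controller state, reset to zero at every trial start."""

    integral: float = 0.0
    prev_error: float = 0.0


@dataclass
class MuscleActuator:
    """A pull-only actuator along an origin/via/insertion polyline."""

    name: str
    path: Sequence[tuple[str, np.ndarray]]  # [(body, local point mm), ...]
    pcsa: float                             # mm^2
    f_max: float                            # N
    gains: tuple[float, float, float] | None = None  # (P, I, D); derived if None
    schedule: GainSchedule = field(default_factory=GainSchedule)
    state: PIDState = field(default_factory=PIDState)

    def __post_init__(self) -> None:
        self.path = tuple((b, np.asarray(p, dtype=float).reshape(3))
                          for b, p in self.path)
        if len(self.path) < 2:
            raise ParameterError(f"muscle {self.name}: path needs >= 2 points")
        if self.pcsa <= 0:
            raise ParameterError(f"muscle {self.name}: PCSA must be positive")
        if self.f_max <= 0:
            raise ParameterError(f"muscle {self.name}: F_max must be positive")
        if self.gains is None:
            self.gains = scale_gains(self.pcsa, self.schedule)

    def touched_bodies(self) -> set[str]:
        return {b for b, _ in self.path}

    def reset(self) -> None:
        self.state = PIDState()

    def world_path(self, poses: Mapping[str, Pose]) -> np.ndarray:
        missing = self.touched_bodies() - set(poses)
        if missing:
            raise StateError(
                f"muscle {self.name}: missing poses for {sorted(missing)}")
        return np.array([poses[b].transform_points(p) for b, p in self.path])


def muscle_length(muscle: MuscleActuator, poses: Mapping[str, Pose]) -> float:
    """Polyline length origin -> via points -> insertion in the world frame (mm)."""
    pts = muscle.world_path(poses)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def pid_update(muscle: MuscleActuator, l_target: float, l_current: float,
               dt: float) -> float:
    """One controller step; returns the clamped muscle force in N.

    Rectangular integration, backward-difference derivative; the integral
    freezes whenever the raw output is outside [0, F_max] and the error would
    push it further (anti-windup).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    p_gain, i_gain, d_gain = muscle.gains
    e = float(l_current - l_target)
    st = muscle.state
    integral = st.integral + e * dt
    derivative = (e - st.prev_error) / dt
    u = p_gain * e + i_gain * integral + d_gain * derivative
    if (u > muscle.f_max and e > 0.0) or (u < 0.0 and e < 0.0):
        integral = st.integral  # freeze accumulation while clamped
        u = p_gain * e + i_gain * integral + d_gain * derivative
    st.integral = integral
    st.prev_error = e
    return float(np.clip(u, 0.0, muscle.f_max))


def apply_muscle_forces(muscles: Sequence[MuscleActuator],
                        poses: Mapping[str, Pose],
                        forces: Sequence[float]) -> WrenchMap:
    """Apply each muscle's tension along its path.

    Terminal points are pulled along the adjacent segment; via points receive
    the redirection force (the vector sum of tensions toward both neighbours),
    so the whole muscle system exerts zero net force and torque on the model.
    """
    wrenches = WrenchMap()
    for muscle, f in zip(muscles, forces):
        f = float(f)
        if f < 0.0 or f > muscle.f_max + 1e-9:
            raise ParameterError(
                f"muscle {muscle.name}: force {f} outside [0, F_max]")
        if f == 0.0:
            continue
        pts = muscle.world_path(poses)
        segs = np.diff(pts, axis=0)
        lens = np.linalg.norm(segs, axis=1)
        units = segs / np.where(lens[:, None] > 1e-12, lens[:, None], 1.0)
        node_forces = np.zeros_like(pts)
        node_forces[:-1] += f * units
        node_forces[1:] -= f * units
        node_bodies = [b for b, _ in muscle.path]
        for body in set(node_bodies):
            mask = np.array([b == body for b in node_bodies])
            wrenches.add_points(body, pts[mask], node_forces[mask])
    return wrenches
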