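"""Rigid-body poses, quaternion utilities, motion trials and wrench maps.

Conventions: positions in mm, quaternions scalar-first (w, x, y, z) and unit
norm, angular velocities in rad/s, forces in N, torques in N*mm.  Torques in a
:class:`WrenchMap` are accumulated about the world origin; the dynamics engine
shifts them to each body's centre of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ShapeError, StateError


# ---------------------------------------------------------------------------
# Quaternions (scalar-first)
# ---------------------------------------------------------------------------

def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-15:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv)
    if angle < 1e-15:
        return np.array([1.0, 0.5 * rv[0], 0.5 * rv[1], 0.5 * rv[2]]) / np.sqrt(
            1.0 + 0.25 * (rv @ rv))
    return quat_from_axis_angle(rv, angle)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_slerp(q0: np.ndarray, q1: np.ndarray, t: float) -> np.ndarray:
    q0 = quat_normalize(q0)
    q1 = quat_normalize(q1)
    d = float(q0 @ q1)
    if d < 0.0:
        q1, d = -q1, -d
    if d > 1.0 - 1e-12:
        return quat_normalize(q0 + t * (q1 - q0))
    theta = np.arccos(np.clip(d, -1.0, 1.0))
    s = np.sin(theta)
    return (np.sin((1 - t) * theta) / s) * q0 + (np.sin(t * theta) / s) * q1


# ---------------------------------------------------------------------------
# Poses and twists
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    """Position of a body frame origin plus orientation quaternion."""

    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).reshape(3)
        self.q = quat_normalize(np.asarray(self.q, dtype=float).reshape(4))
        self._R = quat_to_matrix(self.q)

    @property
    def R(self) -> np.ndarray:
        return self._R

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.zeros(3), np.array([1.0, 0.0, 0.0, 0.0]))

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self._R.T + self.p

    def transform_vectors(self, vecs: np.ndarray) -> np.ndarray:
        return np.asarray(vecs, dtype=float) @ self._R.T


@dataclass
class Twist:
    """Spatial velocity: v is the velocity of the body frame origin (mm/s),
    w the angular velocity (rad/s), both in world coordinates."""

    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float).reshape(3)
        self.w = np.asarray(self.w, dtype=float).reshape(3)

    @classmethod
    def zero(cls) -> "Twist":
        return cls(np.zeros(3), np.zeros(3))

    def point_velocity(self, point_world: np.ndarray, origin_world: np.ndarray) -> np.ndarray:
        return self.v + np.cross(self.w, np.asarray(point_world) - np.asarray(origin_world))


# ---------------------------------------------------------------------------
# Wrench accumulation
# ---------------------------------------------------------------------------

def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product without numpy's axis-dispatch overhead; supports (3,)
    and (N, 3) inputs of matching shape."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.stack([
        a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
        a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
        a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0],
    ], axis=-1)


class WrenchMap:
    """Accumulates point forces per body as (net force, torque about world origin)."""

    def __init__(self) -> None:
        self._data: dict[str, list[np.ndarray]] = {}

    def add(self, body: str, point_world: np.ndarray, force: np.ndarray) -> None:
        entry = self._data.setdefault(body, [np.zeros(3), np.zeros(3)])
        force = np.asarray(force, dtype=float)
        entry[0] += force
        entry[1] += _cross3(np.asarray(point_world, dtype=float), force)

    def add_points(self, body: str, points_world: np.ndarray,
                   forces: np.ndarray) -> None:
        """Accumulate many point forces on one body at once."""
        entry = self._data.setdefault(body, [np.zeros(3), np.zeros(3)])
        entry[0] += forces.sum(axis=0)
        entry[1] += _cross3(points_world, forces).sum(axis=0)

    def add_wrench(self, body: str, force: np.ndarray, torque_origin: np.ndarray) -> None:
        entry = self._data.setdefault(body, [np.zeros(3), np.zeros(3)])
        entry[0] += np.asarray(force, dtype=float)
        entry[1] += np.asarray(torque_origin, dtype=float)

    def force(self, body: str) -> np.ndarray:
        return self._data.get(body, [np.zeros(3), np.zeros(3)])[0]

    def torque_about(self, body: str, point_world: np.ndarray) -> np.ndarray:
        f, tau0 = self._data.get(body, [np.zeros(3), np.zeros(3)])
        return tau0 - _cross3(np.asarray(point_world, dtype=float), f)

    def bodies(self) -> Iterator[str]:
        return iter(self._data)

    def net(self) -> tuple[np.ndarray, np.ndarray]:
        """System net force and torque about the world origin (should vanish
        for internal force systems such as ligaments and muscles)."""
        f = np.zeros(3)
        tau = np.zeros(3)
        for body_f, body_tau in self._data.values():
            f += body_f
            tau += body_tau
        return f, tau

    def merged(self, other: "WrenchMap") -> "WrenchMap":
        out = WrenchMap()
        for src in (self, other):
            for body, (f, tau) in src._data.items():
                out.add_wrench(body, f, tau)
        return out


# ---------------------------------------------------------------------------
# Motion trials
# ---------------------------------------------------------------------------

TRIAL_CSV_COLUMNS = ["time_s", "body", "x_mm", "y_mm", "z_mm", "qw", "qx", "qy", "qz"]


@dataclass
class PoseSeries:
    """Time series of poses for one body (positions (n,3), quats (n,4))."""

    positions: np.ndarray
    quaternions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        q = np.asarray(self.quaternions, dtype=float)
        # enforce sign continuity so interpolation never crosses the double cover
        q = q / np.linalg.norm(q, axis=1, keepdims=True)
        flips = np.cumsum(np.einsum("ij,ij->i", q[1:], q[:-1]) < 0.0)
        sign = np.ones(len(q))
        sign[1:] = np.where(flips % 2 == 1, -1.0, 1.0)
        self.quaternions = q * sign[:, None]
        if len(self.positions) != len(self.quaternions):
            raise ShapeError("position and quaternion series lengths differ")

    def pose(self, i: int) -> Pose:
        return Pose(self.positions[i], self.quaternions[i])


@dataclass
class MotionTrial:
    """Uniformly sampled rigid-body pose series for a motion recording."""

    label: str
    time: np.ndarray
    bodies: dict[str, PoseSeries]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ShapeError("trial time grid must be strictly increasing")
        for name, series in self.bodies.items():
            if len(series.positions) != len(self.time):
                raise ShapeError(f"pose series for '{name}' does not match time grid")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def rate(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return 1.0 / float(np.mean(np.diff(self.time)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if self.n_frames < 3:
            return True
        dt = np.diff(self.time)
        return bool(np.allclose(dt, dt[0], rtol=rtol))

    def frame(self, i: int) -> dict[str, Pose]:
        return {name: series.pose(i) for name, series in self.bodies.items()}

    def interpolate(self, t: float) -> dict[str, Pose]:
        """Linear position / slerp orientation interpolation at time t
        (clamped to the trial's span)."""
        if self.n_frames == 0:
            raise StateError("cannot interpolate an empty trial")
        t = float(np.clip(t, self.time[0], self.time[-1]))
        i = int(np.clip(np.searchsorted(self.time, t, side="right") - 1,
                        0, self.n_frames - 2)) if self.n_frames > 1 else 0
        if self.n_frames == 1:
            return self.frame(0)
        frac = (t - self.time[i]) / (self.time[i + 1] - self.time[i])
        out = {}
        for name, series in self.bodies.items():
            p = (1 - frac) * series.positions[i] + frac * series.positions[i + 1]
            q = quat_slerp(series.quaternions[i], series.quaternions[i + 1], frac)
            out[name] = Pose(p, q)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, series in self.bodies.items():
            df = pd.DataFrame(
                np.column_stack([self.time, series.positions, series.quaternions]),
                columns=["time_s", "x_mm", "y_mm", "z_mm", "qw", "qx", "qy", "qz"])
            df.insert(1, "body", name)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)[TRIAL_CSV_COLUMNS]

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "MotionTrial":
        df = pd.read_csv(path)
        missing = set(TRIAL_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ShapeError(f"trial CSV missing columns {sorted(missing)}")
        bodies = {}
        time = None
        for name, group in df.groupby("body", sort=False):
            group = group.sort_values("time_s")
            t = group["time_s"].to_numpy()
            if time is None:
                time = t
            elif len(t) != len(time) or not np.allclose(t, time):
                raise ShapeError("trial CSV bodies have inconsistent time grids")
            bodies[str(name)] = PoseSeries(
                group[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                group[["qw", "qx", "qy", "qz"]].to_numpy())
        return cls(label=label or Path(path).stem, time=time, bodies=bodies)
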