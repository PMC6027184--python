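"""Tension-only nonlinear ligament bundles with toe region and wrapping.

Each bundle is an elastic, tension-only spring.  Its force-strain law has a
parabolic toe region (modelling fibre crimp) that blends into a linear region
with stiffness ``k`` (N per unit strain):

    f(eps) = k * eps^2 / (4 * eps_l)   for 0 <= eps <= 2*eps_l
    f(eps) = k * (eps - eps_l)         for eps > 2*eps_l
    f(eps) = 0                         for eps < 0

with strain eps = (l - l0) / l0.  The two branches meet at eps = 2*eps_l with
equal value and equal slope k, so the law is C1.  The toe parameter eps_l
defaults to 0.03.

Zero-load lengths l0 are calibrated from a passive laxity sweep: l0 is a
fixed fraction (default 0.8) of the maximum origin-to-insertion path length
observed over the sweep.  Path lengths account for via points and analytic
sphere/cylinder wrap obstacles; the wrap geodesics are closed-form
(tangent - arc - tangent, unrolled for cylinders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    DegenerateGeometryError,
    ParameterError,
    StateError,
)
from .kinematics import MotionTrial, Pose, WrenchMap

log = logging.getLogger(__name__)

DEFAULT_TOE_STRAIN = 0.03
DEFAULT_LAXITY_FACTOR = 0.8

#: bundle counts per ligament group in the default model
DEFAULT_BUNDLE_COUNTS = {
    "MCL-anterior": 3,
    "MCL-posterior": 3,
    "LUCL": 3,
    "RCL": 3,
    "annular": 2,
}


# ---------------------------------------------------------------------------
# Force-strain law
# ---------------------------------------------------------------------------

def bundle_strain(l: float | np.ndarray, l0: float) -> float | np.ndarray:
    """Engineering strain (l - l0) / l0; may be negative for a slack bundle."""
    if l0 <= 0:
        raise ParameterError(f"zero-load length must be positive, got {l0}")
    return (np.asarray(l, dtype=float) - l0) / l0


def bundle_force(eps: float | np.ndarray, k: float,
                 eps_l: float = DEFAULT_TOE_STRAIN) -> float | np.ndarray:
    """Tension-only piecewise force: parabolic toe, then linear, zero if slack."""
    if eps_l <= 0:
        raise ParameterError(f"toe strain must be positive, got {eps_l}")
    if k <= 0:
        raise ParameterError(f"stiffness must be positive, got {k}")
    eps = np.asarray(eps, dtype=float)
    toe = 0.25 * k * eps ** 2 / eps_l
    linear = k * (eps - eps_l)
    out = np.where(eps < 0.0, 0.0, np.where(eps <= 2.0 * eps_l, toe, linear))
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Wrap obstacles
# ---------------------------------------------------------------------------

@dataclass
class WrapSphere:
    """Analytic wrapping sphere rigidly attached to a body."""

    body: str
    center_local: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center_local = np.asarray(self.center_local, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ParameterError("wrap sphere radius must be positive")


@dataclass
class WrapCylinder:
    """Analytic wrapping cylinder (infinite axis) attached to a body."""

    body: str
    point_local: np.ndarray
    axis_local: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.point_local = np.asarray(self.point_local, dtype=float).reshape(3)
        axis = np.asarray(self.axis_local, dtype=float).reshape(3)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            raise ParameterError("wrap cylinder axis must be nonzero")
        self.axis_local = axis / n
        if self.radius <= 0:
            raise ParameterError("wrap cylinder radius must be positive")


def _wrap_segment_sphere(p1: np.ndarray, p2: np.ndarray, center: np.ndarray,
                         radius: float, arc_step: float = np.deg2rad(15.0),
                         ) -> tuple[float, list[np.ndarray]] | None:
    """Shortest path from p1 to p2 around a sphere, if the chord penetrates it.

    Returns (length, arc points excluding endpoints) or None when the straight
    segment clears the sphere.  The geodesic lies in the plane spanned by the
    two points and the sphere centre: two tangents plus a great-circle arc.
    """
    d1 = p1 - center
    d2 = p2 - center
    r1, r2 = np.linalg.norm(d1), np.linalg.norm(d2)
    if r1 <= radius or r2 <= radius:
        raise DegenerateGeometryError("ligament attachment inside wrap obstacle")
    # closest approach of the chord to the centre
    seg = p2 - p1
    seg_len2 = float(seg @ seg)
    t = np.clip(-(d1 @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    closest = d1 + t * seg
    if np.linalg.norm(closest) >= radius or t in (0.0, 1.0):
        return None
    e1 = d1 / r1
    w = d2 - (d2 @ e1) * e1
    wn = np.linalg.norm(w)
    if wn < 1e-12:  # chord passes through the centre: direction degenerate
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        w = helper - (helper @ e1) * e1
        wn = np.linalg.norm(w)
    e2 = w / wn
    phi2 = float(np.arctan2(d2 @ e2, d2 @ e1))
    phi2 = abs(phi2)
    a1 = float(np.arccos(np.clip(radius / r1, -1.0, 1.0)))
    a2 = float(np.arccos(np.clip(radius / r2, -1.0, 1.0)))
    theta_arc = phi2 - a1 - a2
    if theta_arc <= 0.0:
        return None
    length = float(np.sqrt(r1 ** 2 - radius ** 2) + np.sqrt(r2 ** 2 - radius ** 2)
                   + radius * theta_arc)
    n_arc = max(2, int(np.ceil(theta_arc / arc_step)) + 1)
    angles = np.linspace(a1, phi2 - a2, n_arc)
    pts = [center + radius * (np.cos(a) * e1 + np.sin(a) * e2) for a in angles]
    return length, pts


def _wrap_segment_cylinder(p1: np.ndarray, p2: np.ndarray, point: np.ndarray,
                           axis: np.ndarray, radius: float,
                           arc_step: float = np.deg2rad(15.0),
                           ) -> tuple[float, list[np.ndarray]] | None:
    """Geodesic around a cylinder: solve the 2D circle problem in the
    cross-section plane, then unroll (total = hypot(planar length, axial))."""
    d1 = p1 - point
    d2 = p2 - point
    z1, z2 = float(d1 @ axis), float(d2 @ axis)
    q1 = d1 - z1 * axis
    q2 = d2 - z2 * axis
    r1, r2 = np.linalg.norm(q1), np.linalg.norm(q2)
    if r1 <= radius or r2 <= radius:
        raise DegenerateGeometryError("ligament attachment inside wrap obstacle")
    e1 = q1 / r1
    e2 = np.cross(axis, e1)
    x2, y2 = float(q2 @ e1), float(q2 @ e2)
    phi2 = float(np.arctan2(y2, x2))
    sign = 1.0 if phi2 >= 0 else -1.0
    phi2 = abs(phi2)
    a1 = float(np.arccos(np.clip(radius / r1, -1.0, 1.0)))
    a2 = float(np.arccos(np.clip(radius / r2, -1.0, 1.0)))
    theta_arc = phi2 - a1 - a2
    if theta_arc <= 0.0:
        return None
    t1 = float(np.sqrt(r1 ** 2 - radius ** 2))
    t2 = float(np.sqrt(r2 ** 2 - radius ** 2))
    planar = t1 + t2 + radius * theta_arc
    dz = z2 - z1
    length = float(np.hypot(planar, dz))
    # axial coordinate varies linearly with unrolled arc length
    n_arc = max(2, int(np.ceil(theta_arc / arc_step)) + 1)
    angles = np.linspace(a1, phi2 - a2, n_arc)
    pts = []
    for a in angles:
        s = t1 + radius * (a - a1)  # unrolled distance from p1's tangent point
        z = z1 + dz * s / planar if planar > 0 else z1
        pts.append(point + radius * (np.cos(a) * e1 + sign * np.sin(a) * e2) + z * axis)
    return length, pts


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class LigamentBundle:
    """A single tension-only bundle between two bodies."""

    name: str
    ligament: str
    origin_body: str
    origin_point: np.ndarray          # local mm
    insertion_body: str
    insertion_point: np.ndarray       # local mm
    k: float                          # N per unit strain
    eps_l: float = DEFAULT_TOE_STRAIN
    l0: float | None = None           # mm, set by calibration
    via: Sequence[tuple[str, np.ndarray]] = field(default_factory=tuple)
    wrap: Sequence[WrapSphere | WrapCylinder] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.origin_point = np.asarray(self.origin_point, dtype=float).reshape(3)
        self.insertion_point = np.asarray(self.insertion_point, dtype=float).reshape(3)
        self.via = tuple((b, np.asarray(p, dtype=float).reshape(3)) for b, p in self.via)
        self.wrap = tuple(self.wrap)
        if self.k <= 0:
            raise ParameterError(f"bundle {self.name}: k must be positive")
        if self.eps_l <= 0:
            raise ParameterError(f"bundle {self.name}: eps_l must be positive")
        if self.l0 is not None and self.l0 <= 0:
            raise ParameterError(f"bundle {self.name}: l0 must be positive")

    def touched_bodies(self) -> set[str]:
        bodies = {self.origin_body, self.insertion_body}
        bodies.update(b for b, _ in self.via)
        bodies.update(o.body for o in self.wrap)
        return bodies


def _require_poses(bundle: LigamentBundle, poses: Mapping[str, Pose]) -> None:
    missing = bundle.touched_bodies() - set(poses)
    if missing:
        raise StateError(f"bundle {bundle.name}: missing poses for {sorted(missing)}")


def wrap_path(bundle: LigamentBundle,
              poses: Mapping[str, Pose]) -> tuple[float, list[tuple[str, np.ndarray]]]:
    """World-space path of a bundle: (total length, [(body, point), ...]).

    The path runs origin -> via points -> insertion; each straight segment is
    replaced by the tangent-arc-tangent geodesic whenever it penetrates a wrap
    obstacle.  Arc points are attributed to the obstacle's body so redirection
    forces land on the wrapped bone.
    """
    _require_poses(bundle, poses)
    nodes: list[tuple[str, np.ndarray]] = [
        (bundle.origin_body,
         poses[bundle.origin_body].transform_points(bundle.origin_point))]
    for body, pt in bundle.via:
        nodes.append((body, poses[body].transform_points(pt)))
    nodes.append((bundle.insertion_body,
                  poses[bundle.insertion_body].transform_points(bundle.insertion_point)))

    obstacles = []
    for obs in bundle.wrap:
        pose = poses[obs.body]
        if isinstance(obs, WrapSphere):
            obstacles.append(("sphere", obs.body,
                              pose.transform_points(obs.center_local), None, obs.radius))
        else:
            obstacles.append(("cylinder", obs.body,
                              pose.transform_points(obs.point_local),
                              pose.transform_vectors(obs.axis_local), obs.radius))

    total = 0.0
    path: list[tuple[str, np.ndarray]] = [nodes[0]]
    for (body_a, pa), (body_b, pb) in zip(nodes[:-1], nodes[1:]):
        seg_len = float(np.linalg.norm(pb - pa))
        inserted: list[tuple[str, np.ndarray]] = []
        for kind, obody, center, axis, radius in obstacles:
            if kind == "sphere":
                res = _wrap_segment_sphere(pa, pb, center, radius)
            else:
                res = _wrap_segment_cylinder(pa, pb, center, axis, radius)
            if res is not None:
                seg_len, arc_pts = res
                inserted = [(obody, p) for p in arc_pts]
                break  # at most one obstacle engages per segment
        total += seg_len
        path.extend(inserted)
        path.append((body_b, pb))
    return total, path


def wrapped_length(bundle: LigamentBundle, poses: Mapping[str, Pose]) -> float:
    """Length of the (possibly wrapped) origin-to-insertion path, in mm."""
    length, _ = wrap_path(bundle, poses)
    return length


def straight_length(bundle: LigamentBundle, poses: Mapping[str, Pose]) -> float:
    """Euclidean origin-insertion distance, ignoring via points and wrapping."""
    _require_poses(bundle, poses)
    a = poses[bundle.origin_body].transform_points(bundle.origin_point)
    b = poses[bundle.insertion_body].transform_points(bundle.insertion_point)
    return float(np.linalg.norm(b - a))


# ---------------------------------------------------------------------------
# Ligament complex
# ---------------------------------------------------------------------------

@dataclass
class LigamentComplex:
    """All bundles of the model, grouped by ligament name."""

    bundles: list[LigamentBundle]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.bundles:
            out[b.ligament] = out.get(b.ligament, 0) + 1
        return out

    @property
    def n_bundles(self) -> int:
        return len(self.bundles)

    def is_calibrated(self) -> bool:
        return all(b.l0 is not None for b in self.bundles)

    def by_name(self, name: str) -> LigamentBundle:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)


def estimate_zero_load_lengths(complex_: LigamentComplex, laxity: MotionTrial,
                               factor: float = DEFAULT_LAXITY_FACTOR,
                               use_wrapped: bool = True,
                               per_bundle_factor: Mapping[str, float] | None = None,
                               ) -> tuple[LigamentComplex, pd.DataFrame]:
    """Calibrate l0 = factor * max path length over a passive laxity sweep.

    The default factor 0.8 compensates the small stretch imposed by the
    examiner during the passive sweep; it can be overridden per bundle.
    Returns the calibrated complex and a report table
    (bundle, ligament, max_length_mm, factor, l0_mm).
    """
    if laxity.n_frames == 0:
        raise CalibrationError("laxity trial contains no frames")
    if factor <= 0 or factor > 1.0:
        raise CalibrationError(f"correction factor must be in (0, 1], got {factor}")
    length_fn = wrapped_length if use_wrapped else straight_length
    max_len = np.zeros(complex_.n_bundles)
    for i in range(laxity.n_frames):
        poses = laxity.frame(i)
        for j, bundle in enumerate(complex_.bundles):
            max_len[j] = max(max_len[j], length_fn(bundle, poses))

    rows = []
    new_bundles = []
    for j, bundle in enumerate(complex_.bundles):
        fac = factor if per_bundle_factor is None else \
            per_bundle_factor.get(bundle.name, factor)
        l0 = fac * max_len[j]
        if l0 <= 0:
            raise CalibrationError(f"bundle {bundle.name}: non-positive max length")
        new_bundles.append(replace(bundle, l0=l0))
        rows.append({"bundle": bundle.name, "ligament": bundle.ligament,
                     "max_length_mm": max_len[j], "factor": fac, "l0_mm": l0})
    report = pd.DataFrame(rows)
    log.info("calibrated %d bundles from laxity trial '%s' (factor %.2f)",
             len(new_bundles), laxity.label, factor)
    return LigamentComplex(new_bundles), report


# ---------------------------------------------------------------------------
# Force application
# ---------------------------------------------------------------------------

def apply_ligament_forces(complex_: LigamentComplex, poses: Mapping[str, Pose],
                          ) -> tuple[WrenchMap, dict[str, float]]:
    """Evaluate all bundle tensions and accumulate them as body wrenches.

    Tension acts along the local path direction at every path node; equal and
    opposite pairs along each segment make the ligament system contribute zero
    net force and torque to the model.  Returns the wrench map and the
    per-bundle tension record (N).
    """
    wrenches = WrenchMap()
    tensions: dict[str, float] = {}
    per_body_pts: dict[str, list[np.ndarray]] = {}
    per_body_f: dict[str, list[np.ndarray]] = {}
    for bundle in complex_.bundles:
        if bundle.l0 is None:
            raise StateError(f"bundle {bundle.name} is not calibrated (l0 unset)")
        length, path = wrap_path(bundle, poses)
        eps = bundle_strain(length, bundle.l0)
        f = bundle_force(eps, bundle.k, bundle.eps_l)
        tensions[bundle.name] = float(f)
        if f <= 0.0:
            continue
        pts = np.array([p for _, p in path])
        segs = np.diff(pts, axis=0)
        seg_lens = np.sqrt(np.einsum("ij,ij->i", segs, segs))
        units = segs / np.where(seg_lens[:, None] > 1e-12, seg_lens[:, None], 1.0)
        # node force = tension toward next node minus tension toward previous
        node_forces = np.zeros_like(pts)
        node_forces[:-1] += f * units
        node_forces[1:] -= f * units
        for i, (body, _) in enumerate(path):
            per_body_pts.setdefault(body, []).append(pts[i])
            per_body_f.setdefault(body, []).append(node_forces[i])
    for body, pts_list in per_body_pts.items():
        wrenches.add_points(body, np.array(pts_list), np.array(per_body_f[body]))
    return wrenches, tensions
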