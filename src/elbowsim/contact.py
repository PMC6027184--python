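"""Element-wise compliant cartilage contact.

Each humeral cartilage element exerts a frictionless normal force on the
opposing surface when its reference point (the element centroid) penetrates
that surface by depth ``delta``:

    Fc = kc * delta^n + Bc(delta) * delta_dot,   clamped at >= 0

with contact stiffness ``kc`` (default 40 N/mm^n), exponent ``n`` (3.05) and
a depth-ramped damping coefficient ``Bc(delta) = c_max * s(delta / d_max)``,
where ``s`` is the cubic smooth-step ``3u^2 - 2u^3`` clamped to [0, 1] and
``d_max`` (0.1 mm) is the penetration at which damping is fully active.
Ramping the damping in from zero avoids a force discontinuity at first touch;
clamping the total at zero prevents damping from acting as adhesion during
separation.

Penetration depth is measured along the element's outward normal, either
against a closed triangle mesh (parity containment + ray casting; no external
spatial index required) or against the analytic concave sockets used for the
congruent articular surfaces of the synthetic subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeError, StateError
from .geometry import CartilageElementGrid, SurfaceMesh
from .kinematics import Pose, Twist

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameters and force law
# ---------------------------------------------------------------------------

@dataclass
class ContactParameters:
    """Compliant contact parameters (defaults: optimized cadaver values)."""

    kc: float = 40.0       # N/mm^n
    n: float = 3.05        # force exponent
    c_max: float = 5.0     # N*s/mm, fully-ramped damping coefficient
    d_max: float = 0.1     # mm, penetration at full damping

    def __post_init__(self) -> None:
        if self.kc <= 0:
            raise ParameterError("contact stiffness kc must be positive")
        if self.n < 1:
            raise ParameterError("contact exponent n must be >= 1")
        if self.c_max < 0:
            raise ParameterError("damping coefficient must be non-negative")
        if self.d_max <= 0:
            raise ParameterError("d_max must be positive")


def smooth_step(u: np.ndarray) -> np.ndarray:
    """Cubic smooth-step 3u^2 - 2u^3, clamped to [0, 1]."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def element_contact_force(depth: float | np.ndarray, depth_rate: float | np.ndarray,
                          params: ContactParameters) -> float | np.ndarray:
    """Per-element normal force: elastic power law plus ramped damping.

    Zero for non-penetrating elements; the total is clamped at >= 0 so the
    damping term can never pull the surfaces together.
    """
    depth = np.asarray(depth, dtype=float)
    depth_rate = np.asarray(depth_rate, dtype=float)
    loaded = depth > 0.0
    elastic = np.where(loaded, params.kc * np.power(np.where(loaded, depth, 0.0),
                                                    params.n), 0.0)
    damping = np.where(loaded,
                       smooth_step(depth / params.d_max) * params.c_max * depth_rate,
                       0.0)
    out = np.maximum(elastic + damping, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Ray casting against closed meshes (no external spatial index)
# ---------------------------------------------------------------------------

def _ray_triangle_hits(origins: np.ndarray, direction: np.ndarray,
                       v0: np.ndarray, e1: np.ndarray, e2: np.ndarray,
                       eps: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Moller-Trumbore for N rays with a shared direction against M triangles.

    Returns (hit mask (N, M), distances t (N, M), +inf where no hit)."""
    pvec = np.cross(direction, e2)                    # (M, 3)
    det = np.einsum("mj,mj->m", e1, pvec)             # (M,)
    valid = np.abs(det) > eps
    inv_det = np.where(valid, 1.0 / np.where(valid, det, 1.0), 0.0)
    tvec = origins[:, None, :] - v0[None, :, :]       # (N, M, 3)
    u = np.einsum("nmj,mj->nm", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1[None, :, :])             # (N, M, 3)
    v = np.einsum("nmj,j->nm", qvec, direction) * inv_det
    t = np.einsum("nmj,mj->nm", qvec, e2) * inv_det
    hit = (valid[None, :] & (u >= -1e-12) & (v >= -1e-12)
           & (u + v <= 1.0 + 1e-12) & (t > eps))
    return hit, np.where(hit, t, np.inf)


def mesh_penetration_depths(points: np.ndarray, normals: np.ndarray,
                            mesh_vertices: np.ndarray, mesh_faces: np.ndarray,
                            ) -> np.ndarray:
    """Penetration depth of each point into a closed mesh along its normal.

    A point is inside when a ray along -normal crosses the surface an odd
    number of times; its depth is the distance to the first crossing (the
    surface it came through).  Points outside get depth 0.
    """
    points = np.asarray(points, dtype=float)
    normals = np.asarray(normals, dtype=float)
    tri = mesh_vertices[mesh_faces]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    depths = np.zeros(len(points))
    # group points by identical normal? directions differ per point: loop in
    # chunks casting each point's own ray (meshes here are small)
    for i, (p, n) in enumerate(zip(points, normals)):
        hit, t = _ray_triangle_hits(p[None, :], -n, v0, e1, e2)
        ts = t[0][hit[0]]
        if len(ts) == 0:
            continue
        # de-duplicate edge-shared hits at identical distance
        ts = np.unique(np.round(np.sort(ts), 9))
        if len(ts) % 2 == 1:
            depths[i] = ts[0]
    return depths


# ---------------------------------------------------------------------------
# Analytic concave sockets (congruent articular counter-surfaces)
# ---------------------------------------------------------------------------

@dataclass
class CylindricalSocket:
    """Concave cylindrical bearing surface (e.g. the ulnar sigmoid notch).

    Material lies at radius > ``inner_radius`` from the axis, over an axial
    window of +-``half_length`` and an angular aperture of half-angle
    ``aperture_half_angle`` around ``aperture_center_local`` (a unit vector
    orthogonal to the axis pointing at the middle of the covered sector).
    """

    body: str
    center_local: np.ndarray
    axis_local: np.ndarray
    inner_radius: float
    half_length: float
    aperture_center_local: np.ndarray
    aperture_half_angle: float  # rad

    def __post_init__(self) -> None:
        self.center_local = np.asarray(self.center_local, dtype=float).reshape(3)
        self.axis_local = _unit(self.axis_local)
        self.aperture_center_local = _unit(self.aperture_center_local)
        if self.inner_radius <= 0 or self.half_length <= 0:
            raise ParameterError("socket dimensions must be positive")

    def depths(self, points: np.ndarray, pose: Pose) -> np.ndarray:
        c = pose.transform_points(self.center_local)
        a = pose.transform_vectors(self.axis_local)
        ap = pose.transform_vectors(self.aperture_center_local)
        d = np.asarray(points, dtype=float) - c
        t = d @ a
        q = d - np.outer(t, a)
        rho = np.linalg.norm(q, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = (q @ ap) / np.where(rho > 1e-12, rho, 1.0)
        inside = ((np.abs(t) <= self.half_length)
                  & (cosang >= np.cos(self.aperture_half_angle))
                  & (rho > self.inner_radius))
        return np.where(inside, rho - self.inner_radius, 0.0)


@dataclass
class SphericalSocket:
    """Concave spherical bearing surface (e.g. the radial head dish).

    Material lies outside ``inner_radius`` within a cone of half-angle
    ``aperture_half_angle`` about ``aperture_axis_local`` (pointing from the
    sphere centre toward the deepest point of the dish).
    """

    body: str
    center_local: np.ndarray
    inner_radius: float
    aperture_axis_local: np.ndarray
    aperture_half_angle: float  # rad

    def __post_init__(self) -> None:
        self.center_local = np.asarray(self.center_local, dtype=float).reshape(3)
        self.aperture_axis_local = _unit(self.aperture_axis_local)
        if self.inner_radius <= 0:
            raise ParameterError("socket radius must be positive")

    def depths(self, points: np.ndarray, pose: Pose) -> np.ndarray:
        c = pose.transform_points(self.center_local)
        axis = pose.transform_vectors(self.aperture_axis_local)
        d = np.asarray(points, dtype=float) - c
        r = np.linalg.norm(d, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = (d @ axis) / np.where(r > 1e-12, r, 1.0)
        inside = ((cosang >= np.cos(self.aperture_half_angle))
                  & (r > self.inner_radius))
        return np.where(inside, r - self.inner_radius, 0.0)


AnalyticSocket = CylindricalSocket | SphericalSocket


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ParameterError("direction vector must be nonzero")
    return v / n


# ---------------------------------------------------------------------------
# Penetration detection
# ---------------------------------------------------------------------------

def detect_penetrations(grid: CartilageElementGrid,
                        opposing: SurfaceMesh | AnalyticSocket,
                        poses: Mapping[str, Pose],
                        velocities: Mapping[str, Twist] | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-element penetration depth and depth rate against an opposing body.

    Depth is measured along each element's outward normal into the opposing
    closed surface (0 when outside); the rate is the normal component of the
    relative velocity of the coincident material points.
    """
    grid_body = grid.parent_body
    if grid_body not in poses:
        raise StateError(f"missing pose for grid body '{grid_body}'")
    gp = poses[grid_body]
    pts = gp.transform_points(grid.centroids)
    nrm = gp.transform_vectors(grid.normals)

    if isinstance(opposing, (CylindricalSocket, SphericalSocket)):
        opp_body = opposing.body
        if opp_body not in poses:
            raise StateError(f"missing pose for socket body '{opp_body}'")
        depth = opposing.depths(pts, poses[opp_body])
    else:
        opp_body = opposing.body_name
        if opp_body not in poses:
            raise StateError(f"missing pose for mesh body '{opp_body}'")
        if not opposing.mesh.is_watertight:
            raise StateError(
                f"opposing mesh '{opp_body}' is not watertight; "
                "containment test undefined")
        op = poses[opp_body]
        verts = op.transform_points(opposing.vertices)
        depth = mesh_penetration_depths(pts, nrm, verts, opposing.faces)

    rate = np.zeros_like(depth)
    if velocities is not None:
        tw_g = velocities.get(grid_body, Twist.zero())
        tw_o = velocities.get(opp_body, Twist.zero())
        og = poses[grid_body].p
        oo = poses[opp_body].p
        v_rel = (tw_g.v + np.cross(tw_g.w, pts - og)
                 - tw_o.v - np.cross(tw_o.w, pts - oo))
        rate = np.einsum("ij,ij->i", v_rel, nrm)
    return depth, rate


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class ContactState:
    """Per-element contact record plus whole-joint and per-compartment totals."""

    depth: np.ndarray          # mm
    rate: np.ndarray           # mm/s
    force: np.ndarray          # N
    pressure: np.ndarray       # MPa (N/mm^2)
    areas: np.ndarray          # mm^2 element areas
    centroids: np.ndarray      # world positions (N, 3)
    compartments: np.ndarray   # per-element labels

    @property
    def contact_area(self) -> float:
        return float(self.areas[self.force > 0].sum())

    @property
    def peak_pressure(self) -> float:
        return float(self.pressure.max(initial=0.0))

    @property
    def mean_pressure(self) -> float:
        loaded = self.force > 0
        if not loaded.any():
            return 0.0
        return float(self.pressure[loaded].mean())

    @property
    def total_force(self) -> float:
        return float(self.force.sum())

    @property
    def center_of_pressure(self) -> np.ndarray:
        total = self.force.sum()
        if total <= 0:
            return np.full(3, np.nan)
        return (self.force[:, None] * self.centroids).sum(axis=0) / total

    def per_compartment(self) -> pd.DataFrame:
        rows = []
        for name in dict.fromkeys(self.compartments.tolist()):
            m = self.compartments == name
            force = self.force[m]
            loaded = force > 0
            rows.append({
                "compartment": name,
                "contact_area_mm2": float(self.areas[m][loaded].sum()),
                "peak_pressure_MPa": float(self.pressure[m].max(initial=0.0)),
                "total_force_N": float(force.sum()),
            })
        return pd.DataFrame(rows)


def aggregate_contact(grids: CartilageElementGrid | Sequence[CartilageElementGrid],
                      forces: np.ndarray | Sequence[np.ndarray],
                      depths: np.ndarray | Sequence[np.ndarray] | None = None,
                      rates: np.ndarray | Sequence[np.ndarray] | None = None,
                      poses: Mapping[str, Pose] | None = None) -> ContactState:
    """Combine per-element forces into pressures, areas and compartment totals.

    Pressure is element force over element area.  Pass several grids (e.g.
    the trochlear and capitellar patches) to obtain medial/lateral
    sub-aggregates via their compartment labels.
    """
    if isinstance(grids, CartilageElementGrid):
        grids = [grids]
        forces = [np.asarray(forces, dtype=float)]
        depths = None if depths is None else [np.asarray(depths, dtype=float)]
        rates = None if rates is None else [np.asarray(rates, dtype=float)]
    else:
        grids = list(grids)
        forces = [np.asarray(f, dtype=float) for f in forces]
        depths = None if depths is None else [np.asarray(d, dtype=float) for d in depths]
        rates = None if rates is None else [np.asarray(r, dtype=float) for r in rates]
    for g, f in zip(grids, forces):
        if len(f) != g.n_elements:
            raise ShapeError(f"grid '{g.compartment}': {g.n_elements} elements "
                             f"but {len(f)} forces")

    all_force = np.concatenate(forces) if forces else np.zeros(0)
    all_area = np.concatenate([g.areas for g in grids]) if grids else np.zeros(0)
    all_depth = (np.concatenate(depths) if depths is not None
                 else np.zeros_like(all_force))
    all_rate = (np.concatenate(rates) if rates is not None
                else np.zeros_like(all_force))
    cents = []
    for g in grids:
        c = g.centroids
        if poses is not None and g.parent_body in poses:
            c = poses[g.parent_body].transform_points(c)
        cents.append(c)
    all_cent = np.concatenate(cents) if cents else np.zeros((0, 3))
    labels = np.concatenate([
        np.full(g.n_elements, g.compartment or g.parent_body, dtype=object)
        for g in grids]) if grids else np.zeros(0, dtype=object)
    pressure = np.where(all_area > 0, all_force / all_area, 0.0)
    return ContactState(depth=all_depth, rate=all_rate, force=all_force,
                        pressure=pressure, areas=all_area, centroids=all_cent,
                        compartments=labels)
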