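"""Mesh handling, anatomical frames, and cartilage discretization.

All geometry is expressed in millimetres.  Surface meshes are thin wrappers
around :class:`trimesh.Trimesh`; the humeral articular cartilage is tiled into
quadrilateral contact elements of approximately ``target_size``-square
cross-section along two surface parameter directions (planar, cylindrical or
spherical, auto-detected from the distribution of face normals).  Border
elements keep their true (smaller) area, and the sum of element areas equals
the mesh surface area by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import trimesh

from .errors import (
    DegenerateGeometryError,
    EmptyMeshError,
    MeshFormatError,
    ShapeError,
)

log = logging.getLogger(__name__)

_UNIT_SCALES = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "metres": 1000.0, "meters": 1000.0}


# ---------------------------------------------------------------------------
# Surface meshes
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A triangulated surface attached to a named body, in millimetres."""

    mesh: trimesh.Trimesh
    body_name: str = ""

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices, dtype=float)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces, dtype=int)

    @property
    def area(self) -> float:
        return float(self.mesh.area)

    @property
    def bounds(self) -> np.ndarray:
        return np.asarray(self.mesh.bounds, dtype=float)

    def validate(self) -> None:
        faces = self.faces
        if faces.size == 0:
            raise EmptyMeshError(f"mesh '{self.body_name}' has no faces")
        if faces.max(initial=-1) >= len(self.vertices) or faces.min(initial=0) < 0:
            raise MeshFormatError(f"mesh '{self.body_name}' has invalid face indices")
        if np.any(self.mesh.area_faces <= 0.0):
            raise DegenerateGeometryError(
                f"mesh '{self.body_name}' contains zero-area triangles"
            )


def load_mesh(path: str | Path, units: str | float = "mm",
              body_name: str | None = None) -> SurfaceMesh:
    """Load an STL or OBJ surface and scale it to millimetres.

    ``units`` is a hint for the file's length unit: one of ``mm``/``cm``/``m``
    or a numeric scale factor to millimetres.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise MeshFormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise EmptyMeshError(f"mesh file {path} contains no faces")
    scale = _UNIT_SCALES.get(units, None) if isinstance(units, str) else float(units)
    if scale is None:
        raise MeshFormatError(f"unknown unit hint {units!r}")
    if scale != 1.0:
        mesh = mesh.copy()
        mesh.apply_scale(scale)
    sm = SurfaceMesh(mesh=mesh, body_name=body_name or path.stem)
    sm.validate()
    log.info("loaded mesh %s: %d vertices, %d faces, bbox %s mm",
             sm.body_name, len(sm.vertices), len(sm.faces),
             np.round(sm.bounds, 2).tolist())
    return sm


# ---------------------------------------------------------------------------
# Anatomical frames
# ---------------------------------------------------------------------------

@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal triad with anatomical axis labels.

    ``axes`` columns are, in order, the medial–lateral (+ML points medially for
    a right arm), anterior–posterior (+AP anteriorly) and superior–inferior
    (+SI proximally) directions expressed in the parent coordinate system.
    """

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns = [ml, ap, si]

    AXIS_LABELS = ("ML", "AP", "SI")

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        gram = self.axes.T @ self.axes
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise DegenerateGeometryError("frame is left-handed")

    @property
    def ml(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def ap(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def si(self) -> np.ndarray:
        return self.axes[:, 2]


def build_anatomical_frame(landmarks: Mapping[str, np.ndarray]) -> AnatomicalFrame:
    """Construct a bone frame from named landmarks.

    Convention (documented, fixed): ``medial`` and ``lateral`` are the
    epicondyle-equivalent points spanning the joint axis, ``shaft`` is a point
    up the diaphysis on the proximal side.  ML runs lateral→medial, SI is the
    shaft direction orthogonalized against ML, AP completes the right-handed
    triad (AP = SI × ML).  Origin is the midpoint of the medial and lateral
    landmarks.
    """
    try:
        medial = np.asarray(landmarks["medial"], dtype=float).reshape(3)
        lateral = np.asarray(landmarks["lateral"], dtype=float).reshape(3)
        shaft = np.asarray(landmarks["shaft"], dtype=float).reshape(3)
    except KeyError as exc:
        raise DegenerateGeometryError(f"missing landmark {exc}") from exc
    ml = medial - lateral
    norm_ml = np.linalg.norm(ml)
    if norm_ml < 1e-9:
        raise DegenerateGeometryError("medial and lateral landmarks coincide")
    ml = ml / norm_ml
    origin = 0.5 * (medial + lateral)
    si = shaft - origin
    si = si - (si @ ml) * ml
    norm_si = np.linalg.norm(si)
    if norm_si < 1e-9:
        raise DegenerateGeometryError("landmarks are collinear")
    si = si / norm_si
    ap = np.cross(si, ml)
    return AnatomicalFrame(origin=origin, axes=np.column_stack([ml, ap, si]))


# ---------------------------------------------------------------------------
# Cartilage discretization
# ---------------------------------------------------------------------------

@dataclass
class CartilageElementGrid:
    """Discrete contact elements tiling an articular cartilage surface.

    Centroids and outward normals are stored in the parent body's local frame.
    ``cell_index`` keeps each element's (u, v) tile so scalar fields can be
    unfolded into a 2D map; ``u_edges``/``v_edges`` are the tile boundaries in
    the surface parameterization (mm).
    """

    parent_body: str
    centroids: np.ndarray       # (N, 3) mm
    normals: np.ndarray         # (N, 3) unit
    areas: np.ndarray           # (N,) mm^2
    thickness: np.ndarray       # (N,) mm, stored for visualization only
    cell_index: np.ndarray      # (N, 2) int
    u_edges: np.ndarray
    v_edges: np.ndarray
    surface_kind: str = "planar"
    compartment: str = ""
    target_size: float = 3.0

    @property
    def n_elements(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def validate(self) -> None:
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise DegenerateGeometryError("element normals are not unit length")
        if np.any(self.areas <= 0):
            raise DegenerateGeometryError("element with non-positive area")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "element_id": np.arange(self.n_elements),
            "cx": self.centroids[:, 0], "cy": self.centroids[:, 1],
            "cz": self.centroids[:, 2],
            "nx": self.normals[:, 0], "ny": self.normals[:, 1],
            "nz": self.normals[:, 2],
            "area_mm2": self.areas,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _subdivide(tri: np.ndarray, max_edge: float, max_rounds: int = 6) -> np.ndarray:
    """Split (M,3,3) triangles into 4 children until edges <= max_edge."""
    for _ in range(max_rounds):
        edges = np.linalg.norm(tri - np.roll(tri, -1, axis=1), axis=2)
        if edges.max() <= max_edge:
            break
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        ab, bc, ca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
        tri = np.concatenate([
            np.stack([a, ab, ca], axis=1),
            np.stack([ab, b, bc], axis=1),
            np.stack([ca, bc, c], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ])
    return tri


class _Parameterization:
    """Maps 3D surface points to a 2D (u, v) chart in mm."""

    kind = "planar"

    def uv(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class _PlanarParam(_Parameterization):
    kind = "planar"

    def __init__(self, center, e1, e2):
        self.center, self.e1, self.e2 = center, e1, e2

    def uv(self, points):
        d = points - self.center
        return np.column_stack([d @ self.e1, d @ self.e2])


class _CylinderParam(_Parameterization):
    """u = axial coordinate, v = unrolled arc length R*(angle - cut)."""

    kind = "cylindrical"

    def __init__(self, center, axis, e1, e2, radius, cut):
        self.center, self.axis = center, axis
        self.e1, self.e2, self.radius, self.cut = e1, e2, radius, cut

    def uv(self, points):
        d = points - self.center
        u = d @ self.axis
        ang = np.arctan2(d @ self.e2, d @ self.e1)
        ang = np.mod(ang - self.cut, 2.0 * np.pi)
        return np.column_stack([u, self.radius * ang])


class _SphereParam(_Parameterization):
    """Lambert azimuthal equal-area projection about the cap pole."""

    kind = "spherical"

    def __init__(self, center, pole, e1, e2, radius):
        self.center, self.pole = center, pole
        self.e1, self.e2, self.radius = e1, e2, radius

    def uv(self, points):
        d = points - self.center
        r = np.linalg.norm(d, axis=1)
        r = np.where(r < 1e-12, 1.0, r)
        dn = d / r[:, None]
        ct = np.clip(dn @ self.pole, -1.0, 1.0)
        rho = 2.0 * self.radius * np.sin(0.5 * np.arccos(ct))
        phi = np.arctan2(dn @ self.e2, dn @ self.e1)
        return np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])


def _orthonormal_complement(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _fit_parameterization(mesh: trimesh.Trimesh) -> _Parameterization:
    areas = np.asarray(mesh.area_faces)
    normals = np.asarray(mesh.face_normals)
    w = areas / areas.sum()
    nbar = (w[:, None] * normals).sum(axis=0)
    centered = normals - nbar
    spread = float((w[:, None] * centered ** 2).sum())
    verts = np.asarray(mesh.vertices)
    center = verts.mean(axis=0)

    if spread < 1e-8:  # all normals identical -> planar patch
        pole = nbar / np.linalg.norm(nbar)
        d = verts - center
        d_in = d - np.outer(d @ pole, pole)
        # align the grid with the dominant in-plane direction; when the patch
        # is nearly isotropic the principal direction is arbitrary, so fall
        # back to the first world axis with a usable in-plane projection
        _, s, vt = np.linalg.svd(d_in, full_matrices=False)
        if s[1] > 0.95 * s[0]:
            for cand in np.eye(3):
                e1 = cand - (cand @ pole) * pole
                if np.linalg.norm(e1) > 0.1:
                    break
        else:
            e1 = vt[0]
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(pole, e1)
        return _PlanarParam(center, e1, e2)

    # second moment of normals: a cylinder's normals are exactly orthogonal
    # to its axis, so the smallest eigenvalue is ~0 along the axis
    moment = (w[:, None, None] * normals[:, :, None] * normals[:, None, :]).sum(axis=0)
    evals, evecs = np.linalg.eigh(moment)
    if evals[0] < 0.02:
        axis = evecs[:, 0]
        e1, e2 = _orthonormal_complement(axis)
        d = verts - center
        proj = np.column_stack([d @ e1, d @ e2])
        # Kasa algebraic circle fit in the cross-section plane
        a_mat = np.column_stack([2 * proj, np.ones(len(proj))])
        b_vec = (proj ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
        c2d = sol[:2]
        radius = float(np.sqrt(sol[2] + c2d @ c2d))
        center3 = center + c2d[0] * e1 + c2d[1] * e2
        ang = np.arctan2((verts - center3) @ e2, (verts - center3) @ e1)
        cut = _angular_branch_cut(ang)
        return _CylinderParam(center3, axis, e1, e2, radius, cut)

    # spherical cap: algebraic sphere fit, pole = mean normal
    a_mat = np.column_stack([2 * verts, np.ones(len(verts))])
    b_vec = (verts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    c3 = sol[:3]
    radius = float(np.sqrt(sol[3] + c3 @ c3))
    pole = nbar / np.linalg.norm(nbar)
    e1, e2 = _orthonormal_complement(pole)
    return _SphereParam(c3, pole, e1, e2, radius)


def _angular_branch_cut(angles: np.ndarray) -> float:
    """Place the branch cut inside the largest angular gap so that a partial
    cylindrical patch gets a contiguous parameter range."""
    srt = np.sort(np.mod(angles, 2.0 * np.pi))
    gaps = np.diff(np.concatenate([srt, [srt[0] + 2.0 * np.pi]]))
    i = int(np.argmax(gaps))
    return float(np.mod(srt[i] + 0.5 * gaps[i], 2.0 * np.pi))


def discretize_cartilage(surface: SurfaceMesh, target_size: float = 3.0,
                         thickness: float = 2.0,
                         compartment: str = "") -> CartilageElementGrid:
    """Tile an open cartilage shell into ~``target_size``-square elements.

    The default 3 mm target reproduces 3 x 3 mm element cross-sections.  Each
    element stores its true patch area (border elements are smaller), an
    area-weighted centroid, and the area-weighted outward normal.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    surface.validate()
    mesh = surface.mesh
    param = _fit_parameterization(mesh)

    tri = np.asarray(mesh.triangles, dtype=float)
    tri = _subdivide(tri, max_edge=target_size / 4.0)
    sub_c = tri.mean(axis=1)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    sub_a = 0.5 * np.linalg.norm(cross, axis=1)
    sub_n = cross / (2.0 * sub_a[:, None])

    uv_verts = param.uv(np.asarray(mesh.vertices))
    uv_sub = param.uv(sub_c)
    lo, hi = uv_verts.min(axis=0), uv_verts.max(axis=0)
    extent = hi - lo
    n_u = max(1, int(round(extent[0] / target_size)))
    n_v = max(1, int(round(extent[1] / target_size)))
    if n_u == 1 and n_v == 1 and max(extent) < target_size:
        warnings.warn("cartilage surface smaller than one element; "
                      "returning a single-element grid", stacklevel=2)
    u_edges = np.linspace(lo[0], hi[0], n_u + 1)
    v_edges = np.linspace(lo[1], hi[1], n_v + 1)

    iu = np.clip(np.searchsorted(u_edges, uv_sub[:, 0], side="right") - 1, 0, n_u - 1)
    iv = np.clip(np.searchsorted(v_edges, uv_sub[:, 1], side="right") - 1, 0, n_v - 1)
    flat = iu * n_v + iv

    order = np.argsort(flat, kind="stable")
    flat_s, a_s, c_s, n_s = flat[order], sub_a[order], sub_c[order], sub_n[order]
    cells, starts = np.unique(flat_s, return_index=True)
    areas = np.add.reduceat(a_s, starts)
    wc = np.add.reduceat(a_s[:, None] * c_s, starts)
    wn = np.add.reduceat(a_s[:, None] * n_s, starts)
    centroids = wc / areas[:, None]
    normals = wn / np.linalg.norm(wn, axis=1, keepdims=True)

    grid = CartilageElementGrid(
        parent_body=surface.body_name,
        centroids=centroids,
        normals=normals,
        areas=areas,
        thickness=np.full(len(areas), float(thickness)),
        cell_index=np.column_stack([cells // n_v, cells % n_v]).astype(int),
        u_edges=u_edges,
        v_edges=v_edges,
        surface_kind=param.kind,
        compartment=compartment or surface.body_name,
        target_size=float(target_size),
    )
    grid.validate()
    log.info("discretized %s into %d elements (%s chart), total area %.1f mm^2",
             surface.body_name, grid.n_elements, param.kind, grid.total_area)
    return grid


# ---------------------------------------------------------------------------
# Unfolded pressure maps
# ---------------------------------------------------------------------------

@dataclass
class PressureMap:
    """Per-cell scalar field on the unfolded 2D cartilage chart (mm coords)."""

    values: np.ndarray  # (n_u, n_v), NaN where no element
    u_edges: np.ndarray
    v_edges: np.ndarray

    @property
    def extent_u(self) -> float:
        return float(self.u_edges[-1] - self.u_edges[0])

    @property
    def extent_v(self) -> float:
        return float(self.v_edges[-1] - self.v_edges[0])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        u_mid = 0.5 * (self.u_edges[:-1] + self.u_edges[1:])
        v_mid = 0.5 * (self.v_edges[:-1] + self.v_edges[1:])
        pd.DataFrame(self.values, index=np.round(u_mid, 4),
                     columns=np.round(v_mid, 4)).to_csv(path)

    def to_png(self, path: str | Path, label: str = "contact pressure (MPa)") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        pm = ax.pcolormesh(self.v_edges, self.u_edges, self.values, shading="flat")
        fig.colorbar(pm, ax=ax, label=label)
        ax.set_xlabel("unrolled arc (mm)")
        ax.set_ylabel("axial (mm)")
        ax.set_aspect("equal")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def unfold_pressure_map(grid: CartilageElementGrid,
                        values: np.ndarray) -> PressureMap:
    """Project per-element scalars onto the grid's 2D surface chart."""
    values = np.asarray(values, dtype=float).reshape(-1)
    if len(values) != grid.n_elements:
        raise ShapeError(
            f"expected {grid.n_elements} values, got {len(values)}")
    n_u, n_v = len(grid.u_edges) - 1, len(grid.v_edges) - 1
    img = np.full((n_u, n_v), np.nan)
    img[grid.cell_index[:, 0], grid.cell_index[:, 1]] = values
    return PressureMap(values=img, u_edges=grid.u_edges, v_edges=grid.v_edges)
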