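"""Deterministic synthetic elbow subject: geometry, motion trials, EMG.

No subject data ship with the package, so every pipeline stage is exercised
on a parametric right-arm elbow built from analytic primitives:

* the humeral trochlea is a cylindrical cartilage surface on the flexion
  axis (the world +x / medial-lateral axis), the capitellum a spherical cap
  lateral to it;
* the ulnar sigmoid notch and the radial head dish are congruent concave
  sockets, so at the neutral pose penetration is zero everywhere and pure
  flexion keeps the joint perfectly congruent;
* 14 ligament bundles (MCL anterior 3, MCL posterior 3, LUCL 3, RCL 3,
  annular 2) attach at anatomically inspired sites, the LUCL wrapping the
  radial head; 6 muscles (3 triceps heads, 2 biceps heads, brachialis) run
  over fixed via points with Holzbaur-type PCSA and peak forces;
* bone masses follow from shaft volumes at 1600 kg/m^3 (cartilage at
  1000 kg/m^3 contributes its shell mass to the humerus).

The world frame is the humeral anatomical frame: +x medial, +y anterior,
+z proximal; gravity acts along -z.  Flexion is a positive rotation about
+x, carrying the hanging forearm (-z) anteriorly.  Identical seeds yield
identical subjects, trials and EMG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .contact import ContactParameters, CylindricalSocket, SphericalSocket
from .engine import ContactPair, ElbowModel, RigidBody, SimulationResult
from .errors import ParameterError, TrajectoryError
from .geometry import AnatomicalFrame, SurfaceMesh, discretize_cartilage
from .kinematics import (
    MotionTrial,
    Pose,
    PoseSeries,
    quat_from_axis_angle,
    quat_multiply,
)
from .ligaments import LigamentBundle, LigamentComplex, WrapSphere
from .muscles import GainSchedule, MuscleActuator

log = logging.getLogger(__name__)

#: default bundle stiffness (N per unit strain) per ligament group
DEFAULT_LIGAMENT_STIFFNESS = {
    "MCL-anterior": 300.0,
    "MCL-posterior": 250.0,
    "LUCL": 250.0,
    "RCL": 200.0,
    "annular": 150.0,
}

#: name, PCSA (mm^2), peak isometric force (N) for the six modelled muscles
MUSCLE_TABLE = [
    ("triceps-long", 570.0, 798.5),
    ("triceps-lateral", 450.0, 624.3),
    ("triceps-medial", 450.0, 624.3),
    ("biceps-long", 450.0, 624.3),
    ("biceps-short", 310.0, 435.6),
    ("brachialis", 710.0, 987.3),
]

BONE_DENSITY = 1.6e-6       # kg/mm^3 (1600 kg/m^3)
CARTILAGE_DENSITY = 1.0e-6  # kg/mm^3 (1000 kg/m^3)


@dataclass
class SubjectParameters:
    """Geometric and inertial parameters of the synthetic subject (mm, kg)."""

    seed: int = 0
    trochlea_radius: float = 12.0        # cartilage outer radius
    trochlea_half_width: float = 10.0
    trochlea_center_x: float = 12.0
    capitellum_radius: float = 10.0
    capitellum_center_x: float = -12.0
    radial_rim_radius: float = 11.0
    cartilage_thickness: float = 2.0
    humerus_length: float = 280.0
    humerus_shaft_radius: float = 10.0
    ulna_length: float = 240.0
    ulna_shaft_radius: float = 8.0
    radius_length: float = 230.0
    radius_shaft_radius: float = 7.0
    laxity_amplitude_deg: float = 6.0
    element_size: float = 3.0
    ligament_stiffness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIGAMENT_STIFFNESS))

    def __post_init__(self) -> None:
        for name in ("trochlea_radius", "capitellum_radius", "cartilage_thickness",
                     "humerus_length", "ulna_length", "radius_length",
                     "element_size"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.cartilage_thickness >= min(self.trochlea_radius,
                                           self.capitellum_radius):
            raise ParameterError("cartilage thicker than the articular radius")


@dataclass
class SyntheticSubject:
    """A generated model plus the anatomical frames and source meshes."""

    params: SubjectParameters
    model: ElbowModel
    frames: dict[str, AnatomicalFrame]

    def neutral_poses(self) -> dict[str, Pose]:
        p = self.params
        return {
            "humerus": Pose.identity(),
            "ulna": Pose(np.array([p.trochlea_center_x, 0.0, 0.0]),
                         np.array([1.0, 0.0, 0.0, 0.0])),
            "radius": Pose(np.array([p.capitellum_center_x, 0.0, 0.0]),
                           np.array([1.0, 0.0, 0.0, 0.0])),
        }


# ---------------------------------------------------------------------------
# Parametric shell meshes
# ---------------------------------------------------------------------------

def _quad_grid_mesh(points: np.ndarray, outward: np.ndarray) -> trimesh.Trimesh:
    """Triangulate an (n, m, 3) structured point grid; winding chosen so face
    normals align with the given per-vertex outward directions."""
    n, m, _ = points.shape
    verts = points.reshape(-1, 3)
    idx = np.arange(n * m).reshape(n, m)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, c], axis=1),
                            np.stack([a, c, d], axis=1)])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    ref = outward.reshape(-1, 3)[mesh.faces].mean(axis=1)
    agree = np.einsum("ij,ij->", np.asarray(mesh.face_normals), ref)
    if agree < 0:
        mesh.invert()
    return mesh


def trochlea_shell(p: SubjectParameters, phi_range=(-30.0, 290.0),
                   d_phi: float = 2.5, d_x: float = 1.0) -> SurfaceMesh:
    """Cylindrical cartilage surface of the trochlea (humerus frame)."""
    x0 = p.trochlea_center_x - p.trochlea_half_width
    x1 = p.trochlea_center_x + p.trochlea_half_width
    xs = np.linspace(x0, x1, max(2, int(round((x1 - x0) / d_x)) + 1))
    phis = np.deg2rad(np.linspace(phi_range[0], phi_range[1],
                                  int(round((phi_range[1] - phi_range[0]) / d_phi)) + 1))
    r = p.trochlea_radius
    pts = np.empty((len(xs), len(phis), 3))
    nrm = np.empty_like(pts)
    pts[..., 0] = xs[:, None]
    pts[..., 1] = -r * np.sin(phis)[None, :]
    pts[..., 2] = r * np.cos(phis)[None, :]
    nrm[..., 0] = 0.0
    nrm[..., 1] = -np.sin(phis)[None, :]
    nrm[..., 2] = np.cos(phis)[None, :]
    return SurfaceMesh(_quad_grid_mesh(pts, nrm), body_name="humerus")


def capitellum_shell(p: SubjectParameters, cap_half_angle: float = 115.0,
                     d_ang: float = 3.0) -> SurfaceMesh:
    """Spherical cartilage cap of the capitellum, about a mid-flexion axis."""
    center = np.array([p.capitellum_center_x, 0.0, 0.0])
    axis = np.array([0.0, np.sin(np.deg2rad(50.0)), -np.cos(np.deg2rad(50.0))])
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(axis, e1)
    r = p.capitellum_radius
    alphas = np.deg2rad(np.linspace(d_ang, cap_half_angle,
                                    int(round(cap_half_angle / d_ang))))
    betas = np.linspace(0.0, 2.0 * np.pi, int(round(360.0 / d_ang)) + 1)
    dirs = (np.cos(alphas)[:, None, None] * axis
            + np.sin(alphas)[:, None, None]
            * (np.cos(betas)[None, :, None] * e1 + np.sin(betas)[None, :, None] * e2))
    pts = center + r * dirs
    mesh = _quad_grid_mesh(pts, dirs)
    # close the pole with a fan
    pole = center + r * axis
    verts = np.vstack([mesh.vertices, pole])
    pole_idx = len(verts) - 1
    ring = np.arange(len(betas))
    fan = np.stack([np.full(len(betas) - 1, pole_idx), ring[:-1], ring[1:]], axis=1)
    faces = np.vstack([mesh.faces, fan])
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    ref = (np.asarray(out.triangles).mean(axis=1) - center)
    if np.einsum("ij,ij->", np.asarray(out.face_normals), ref) < 0:
        out.invert()
    return SurfaceMesh(out, body_name="humerus")


def radial_rim_shell(p: SubjectParameters, z_range=(-11.0, -1.0),
                     d_phi: float = 5.0, d_z: float = 1.0) -> SurfaceMesh:
    """Cylindrical band around the radial head rim (radius body frame)."""
    zs = np.linspace(z_range[0], z_range[1],
                     max(2, int(round((z_range[1] - z_range[0]) / d_z)) + 1))
    phis = np.deg2rad(np.linspace(0.0, 360.0, int(round(360.0 / d_phi)) + 1))
    r = p.radial_rim_radius
    pts = np.empty((len(zs), len(phis), 3))
    nrm = np.zeros_like(pts)
    pts[..., 0] = r * np.cos(phis)[None, :]
    pts[..., 1] = r * np.sin(phis)[None, :]
    pts[..., 2] = zs[:, None]
    nrm[..., 0] = np.cos(phis)[None, :]
    nrm[..., 1] = np.sin(phis)[None, :]
    return SurfaceMesh(_quad_grid_mesh(pts, nrm), body_name="radius")


def distal_rim_shell(p: SubjectParameters, z_center: float = -200.0,
                     half_height: float = 3.0, d_phi: float = 10.0,
                     d_z: float = 1.5) -> SurfaceMesh:
    """Cylindrical band near the distal radius (radius body frame); bears
    against the ulnar shaft through the distal radioulnar joint."""
    r = p.radius_shaft_radius + 1.0
    zs = np.linspace(z_center - half_height, z_center + half_height,
                     max(2, int(round(2 * half_height / d_z)) + 1))
    phis = np.deg2rad(np.linspace(0.0, 360.0, int(round(360.0 / d_phi)) + 1))
    pts = np.empty((len(zs), len(phis), 3))
    nrm = np.zeros_like(pts)
    pts[..., 0] = r * np.cos(phis)[None, :]
    pts[..., 1] = r * np.sin(phis)[None, :]
    pts[..., 2] = zs[:, None]
    nrm[..., 0] = np.cos(phis)[None, :]
    nrm[..., 1] = np.sin(phis)[None, :]
    return SurfaceMesh(_quad_grid_mesh(pts, nrm), body_name="radius")


def bone_shaft_mesh(body: str, radius: float, z0: float, z1: float) -> SurfaceMesh:
    """Watertight cylindrical shaft stand-in for a bone (synthetic)."""
    mesh = trimesh.creation.cylinder(radius=radius, height=abs(z1 - z0),
                                     sections=48)
    mesh.apply_translation([0.0, 0.0, 0.5 * (z0 + z1)])
    return SurfaceMesh(mesh, body_name=body)


# ---------------------------------------------------------------------------
# Subject assembly
# ---------------------------------------------------------------------------

def _rod_body(name: str, density: float, radius: float, z0: float, z1: float,
              extra_mass: float = 0.0) -> RigidBody:
    length = abs(z1 - z0)
    mass = density * np.pi * radius ** 2 * length + extra_mass
    com = np.array([0.0, 0.0, 0.5 * (z0 + z1)])
    i_trans = mass * (length ** 2 / 12.0 + radius ** 2 / 4.0)
    i_axial = 0.5 * mass * radius ** 2
    return RigidBody(name=name, mass=mass,
                     inertia=np.diag([i_trans, i_trans, i_axial]),
                     com_local=com)


def _ligament_bundles(p: SubjectParameters) -> list[LigamentBundle]:
    k = p.ligament_stiffness
    med, lat = 29.0, -29.0  # humeral epicondyle x-offsets (on the flexion axis)
    bundles: list[LigamentBundle] = []

    def add(name, lig, ob, op, ib, ip, via=(), wrap=()):
        bundles.append(LigamentBundle(
            name=name, ligament=lig, origin_body=ob, origin_point=op,
            insertion_body=ib, insertion_point=ip, k=k[lig],
            via=via, wrap=wrap))

    # MCL anterior: medial epicondyle -> coronoid / sublime tubercle
    add("MCLa-anterior", "MCL-anterior", "humerus", (med, 3, 0),
        "ulna", (9, 8, -5))
    add("MCLa-central", "MCL-anterior", "humerus", (med, 1, 0),
        "ulna", (9, 7, -9))
    add("MCLa-posterior", "MCL-anterior", "humerus", (med, -1, 0),
        "ulna", (9, 5, -13))
    # MCL posterior: medial epicondyle -> medial olecranon
    add("MCLp-anterior", "MCL-posterior", "humerus", (med, -2, 1),
        "ulna", (9, -7, 3))
    add("MCLp-central", "MCL-posterior", "humerus", (med, -3, 0),
        "ulna", (9, -6, 7))
    add("MCLp-posterior", "MCL-posterior", "humerus", (med, -4, -1),
        "ulna", (9, -4, 10))
    # LUCL: lateral epicondyle around the radial head -> supinator crest
    lucl_wrap = (WrapSphere(body="radius", center_local=(0.0, 0.0, -4.0),
                            radius=p.radial_rim_radius - 0.5),)
    add("LUCL-anterior", "LUCL", "humerus", (lat, 1, 0),
        "ulna", (-9, -4, -16), wrap=lucl_wrap)
    add("LUCL-central", "LUCL", "humerus", (lat, 0, 0),
        "ulna", (-9, -3, -19), wrap=lucl_wrap)
    add("LUCL-posterior", "LUCL", "humerus", (lat, -1, 0),
        "ulna", (-9, -2, -22), wrap=lucl_wrap)
    # RCL: lateral epicondyle -> radial neck / annular region
    add("RCL-anterior", "RCL", "humerus", (lat, 2, -1), "radius", (-8, 5, -10))
    add("RCL-central", "RCL", "humerus", (lat, 0, -1), "radius", (-9, 0, -11))
    add("RCL-posterior", "RCL", "humerus", (lat, -2, -1), "radius", (-8, -5, -10))
    # annular: ulna -> around the radial neck -> ulna
    add("annular-proximal", "annular", "ulna", (-20, 7, -3),
        "ulna", (-20, -7, -3), via=(("radius", (-10.5, 0.0, -3.0)),))
    add("annular-distal", "annular", "ulna", (-20, 7, -9),
        "ulna", (-20, -7, -9), via=(("radius", (-10.5, 0.0, -9.0)),))
    return bundles


def _muscle_actuators() -> list[MuscleActuator]:
    schedule = GainSchedule()
    paths = {
        "triceps-long": [("humerus", (0, -14, 200)), ("humerus", (0, -16, 30)),
                         ("ulna", (0, -12, 8))],
        "triceps-lateral": [("humerus", (0, -16, 140)), ("humerus", (0, -16, 30)),
                            ("ulna", (0, -13, 9))],
        "triceps-medial": [("humerus", (0, -13, 100)), ("humerus", (0, -15, 28)),
                           ("ulna", (0, -11, 7))],
        "biceps-long": [("humerus", (0, 10, 280)), ("humerus", (0, 18, 25)),
                        ("radius", (0, 9, -35))],
        "biceps-short": [("humerus", (5, 12, 275)), ("humerus", (2, 17, 25)),
                         ("radius", (2, 8, -33))],
        "brachialis": [("humerus", (0, 16, 65)), ("ulna", (0, 9, -22))],
    }
    return [MuscleActuator(name=name, path=paths[name], pcsa=pcsa, f_max=fmax,
                           schedule=schedule)
            for name, pcsa, fmax in MUSCLE_TABLE]


def generate_subject(params: SubjectParameters | None = None) -> SyntheticSubject:
    """Build the full synthetic elbow model (geometry, ligaments, muscles)."""
    p = params or SubjectParameters()

    trochlea = trochlea_shell(p)
    capitellum = capitellum_shell(p)
    rim = radial_rim_shell(p)
    distal_rim = distal_rim_shell(p)
    troch_grid = discretize_cartilage(trochlea, p.element_size,
                                      thickness=p.cartilage_thickness,
                                      compartment="ulnohumeral")
    cap_grid = discretize_cartilage(capitellum, p.element_size,
                                    thickness=p.cartilage_thickness,
                                    compartment="radiohumeral")
    rim_grid = discretize_cartilage(rim, p.element_size,
                                    thickness=p.cartilage_thickness / 2.0,
                                    compartment="radioulnar")
    distal_grid = discretize_cartilage(distal_rim, p.element_size,
                                       thickness=p.cartilage_thickness / 2.0,
                                       compartment="radioulnar")

    cartilage_mass = CARTILAGE_DENSITY * p.cartilage_thickness * (
        trochlea.area + capitellum.area)
    bodies = {
        "humerus": _rod_body("humerus", BONE_DENSITY, p.humerus_shaft_radius,
                             10.0, p.humerus_length, extra_mass=cartilage_mass),
        "ulna": _rod_body("ulna", BONE_DENSITY, p.ulna_shaft_radius,
                          -10.0, -p.ulna_length),
        "radius": _rod_body("radius", BONE_DENSITY, p.radius_shaft_radius,
                            -10.0, -p.radius_length),
    }

    sockets = {
        "ulnohumeral": CylindricalSocket(
            body="ulna", center_local=(0, 0, 0), axis_local=(1, 0, 0),
            inner_radius=p.trochlea_radius,
            half_length=p.trochlea_half_width - 0.5,
            # notch floor faces the ulna shaft (local -z): the joint is loaded
            # in compression by the taut collaterals pulling the ulna proximally
            aperture_center_local=(0, 0, -1),
            aperture_half_angle=np.deg2rad(100.0)),
        "radiohumeral": SphericalSocket(
            body="radius", center_local=(0, 0, 0),
            inner_radius=p.capitellum_radius,
            aperture_axis_local=(0, 0, -1),
            # slightly past the equator: the dish plus the annular hood grip
            # the capitellum, giving the head lateral bearing support
            aperture_half_angle=np.deg2rad(105.0)),
        # a ring bearing: the lesser sigmoid notch plus the annular ligament
        # ring, which together encircle the radial head and keep the radial
        # shaft aligned with the ulna
        "radioulnar": CylindricalSocket(
            body="ulna",
            center_local=(p.capitellum_center_x - p.trochlea_center_x, 0, -6),
            axis_local=(0, 0, 1), inner_radius=p.radial_rim_radius,
            half_length=5.5, aperture_center_local=(1, 0, 0),
            aperture_half_angle=np.deg2rad(180.0)),
        # distal radioulnar joint: slaves the radial shaft to the ulna over a
        # long lever (the role of the interosseous membrane), leaving
        # pronation about the shaft axis free
        "radioulnar-distal": CylindricalSocket(
            body="ulna",
            center_local=(p.capitellum_center_x - p.trochlea_center_x, 0,
                          -200.0),
            axis_local=(0, 0, 1),
            inner_radius=p.radius_shaft_radius + 1.0,
            half_length=4.5, aperture_center_local=(1, 0, 0),
            aperture_half_angle=np.deg2rad(180.0)),
    }
    contacts = [
        ContactPair("ulnohumeral", troch_grid, sockets["ulnohumeral"],
                    ContactParameters()),
        ContactPair("radiohumeral", cap_grid, sockets["radiohumeral"],
                    ContactParameters()),
        ContactPair("radioulnar", rim_grid, sockets["radioulnar"],
                    ContactParameters()),
        ContactPair("radioulnar-distal", distal_grid,
                    sockets["radioulnar-distal"], ContactParameters()),
    ]

    frames = {
        "humerus": AnatomicalFrame(origin=np.zeros(3), axes=np.eye(3)),
        "ulna": AnatomicalFrame(origin=np.zeros(3), axes=np.eye(3)),
        "radius": AnatomicalFrame(origin=np.zeros(3), axes=np.eye(3)),
    }

    model = ElbowModel(
        bodies=bodies,
        ligaments=LigamentComplex(_ligament_bundles(p)),
        contacts=contacts,
        muscles=_muscle_actuators(),
        meshes={"trochlea_cartilage": trochlea,
                "capitellum_cartilage": capitellum,
                "radial_rim": rim,
                "distal_rim": distal_rim,
                "humerus_shaft": bone_shaft_mesh("humerus", p.humerus_shaft_radius,
                                                 10.0, p.humerus_length),
                "ulna_shaft": bone_shaft_mesh("ulna", p.ulna_shaft_radius,
                                              -10.0, -p.ulna_length),
                "radius_shaft": bone_shaft_mesh("radius", p.radius_shaft_radius,
                                                -10.0, -p.radius_length)},
    )
    return SyntheticSubject(params=p, model=model, frames=frames)


# ---------------------------------------------------------------------------
# Motion trials
# ---------------------------------------------------------------------------

TRIAL_LABELS = ("10deg_s", "60deg_s", "free", "laxity")


@dataclass
class TrialSpec:
    """Specification of a synthetic flexion/extension trial."""

    label: str = "60deg_s"
    flexion_start_deg: float = 10.0
    flexion_end_deg: float = 100.0
    omega_deg_s: float | None = None        # derived from the label if None
    peak_velocity_deg_s: float = 300.0      # "free" trial peak
    blend_s: float = 0.2                    # cosine velocity blend at ramps
    laxity_duration_s: float = 8.0
    sample_rate_hz: float = 100.0
    emg_rate_hz: float = 1400.0
    noise_pos_mm: float = 0.2               # marker-like pose jitter
    noise_rot_deg: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in TRIAL_LABELS:
            raise ParameterError(f"unknown trial label {self.label!r}; "
                                 f"expected one of {TRIAL_LABELS}")
        if self.omega_deg_s is None:
            self.omega_deg_s = {"10deg_s": 10.0, "60deg_s": 60.0}.get(self.label)
        if self.flexion_end_deg <= self.flexion_start_deg:
            raise TrajectoryError("flexion range must be increasing")


def _isokinetic_half(t: np.ndarray, rng_deg: float, omega: float,
                     tb: float) -> np.ndarray:
    """Flexion excursion (deg) of one constant-velocity half-cycle with
    raised-cosine velocity blends of duration tb at both ends."""
    t_half = rng_deg / omega + tb
    v = np.full_like(t, omega)
    m0 = t < tb
    v[m0] = omega * 0.5 * (1 - np.cos(np.pi * t[m0] / tb))
    m1 = t > t_half - tb
    v[m1] = omega * 0.5 * (1 - np.cos(np.pi * (t_half - t[m1]) / tb))
    v[t > t_half] = 0.0
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    x = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
    return x


def flexion_profile(spec: TrialSpec) -> tuple[np.ndarray, np.ndarray]:
    """Time grid and flexion angle series (deg) for a trial spec."""
    rng_deg = spec.flexion_end_deg - spec.flexion_start_deg
    fs = spec.sample_rate_hz
    if spec.label == "laxity":
        t = np.arange(0.0, spec.laxity_duration_s + 0.5 / fs, 1.0 / fs)
        theta = spec.flexion_start_deg + rng_deg * 0.5 * (
            1 - np.cos(2.0 * np.pi * t / spec.laxity_duration_s))
        return t, theta
    if spec.label == "free":
        t_half = 2.0 * rng_deg / spec.peak_velocity_deg_s
        t = np.arange(0.0, 2 * t_half + 0.5 / fs, 1.0 / fs)
        up = np.clip(t, 0, t_half)
        down = np.clip(t - t_half, 0, t_half)
        x = (rng_deg * (up / t_half - np.sin(2 * np.pi * up / t_half) / (2 * np.pi))
             - rng_deg * (down / t_half - np.sin(2 * np.pi * down / t_half) / (2 * np.pi)))
        return t, spec.flexion_start_deg + x
    omega = float(spec.omega_deg_s)
    t_half = rng_deg / omega + spec.blend_s
    t = np.arange(0.0, 2 * t_half + 0.5 / fs, 1.0 / fs)
    up = _isokinetic_half(np.clip(t, 0, t_half), rng_deg, omega, spec.blend_s)
    down = _isokinetic_half(np.clip(t - t_half, 0, t_half), rng_deg, omega,
                            spec.blend_s)
    return t, spec.flexion_start_deg + up - down


def generate_trial(subject: SyntheticSubject, spec: TrialSpec) -> MotionTrial:
    """Synthesize a motion trial for the subject.

    Flexion follows the spec's velocity profile; the laxity trial adds
    +-laxity-amplitude varus-valgus and internal-external excursions so the
    passive sweep spans the joint's play.  Seeded Gaussian jitter emulates
    marker noise on every pose channel.
    """
    p = subject.params
    t, theta_deg = flexion_profile(spec)
    n = len(t)
    if not (theta_deg.max() <= 175.0 and theta_deg.min() >= -15.0):
        raise TrajectoryError("flexion profile exceeds the model's range")
    vv_deg = np.zeros(n)
    ie_deg = np.zeros(n)
    if spec.label == "laxity":
        amp = p.laxity_amplitude_deg
        vv_deg = amp * np.sin(2.0 * np.pi * 0.8 * t)
        ie_deg = amp * np.sin(2.0 * np.pi * 0.6 * t + 1.0)

    rng = np.random.default_rng(spec.seed)
    x_axis = np.array([1.0, 0.0, 0.0])
    y_axis = np.array([0.0, 1.0, 0.0])
    z_axis = np.array([0.0, 0.0, 1.0])

    def jitter_quat() -> np.ndarray:
        if spec.noise_rot_deg == 0.0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        return quat_from_axis_angle(axis, np.deg2rad(spec.noise_rot_deg)
                                    * rng.standard_normal())

    def jitter_pos() -> np.ndarray:
        return spec.noise_pos_mm * rng.standard_normal(3)

    hum_p = np.zeros((n, 3))
    hum_q = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    ulna_p = np.tile([p.trochlea_center_x, 0.0, 0.0], (n, 1))
    ulna_q = np.empty((n, 4))
    rad_p = np.tile([p.capitellum_center_x, 0.0, 0.0], (n, 1))
    rad_q = np.empty((n, 4))
    for i in range(n):
        q_flex = quat_from_axis_angle(x_axis, np.deg2rad(theta_deg[i]))
        q_ulna = quat_multiply(q_flex, quat_multiply(
            quat_from_axis_angle(y_axis, np.deg2rad(vv_deg[i])),
            quat_from_axis_angle(z_axis, np.deg2rad(ie_deg[i]))))
        ulna_q[i] = quat_multiply(jitter_quat(), q_ulna)
        rad_q[i] = quat_multiply(jitter_quat(), q_flex)
        hum_q[i] = quat_multiply(jitter_quat(), hum_q[i])
        hum_p[i] += jitter_pos()
        ulna_p[i] += jitter_pos()
        rad_p[i] += jitter_pos()

    return MotionTrial(label=spec.label, time=t, bodies={
        "humerus": PoseSeries(hum_p, hum_q),
        "ulna": PoseSeries(ulna_p, ulna_q),
        "radius": PoseSeries(rad_p, rad_q),
    })


# ---------------------------------------------------------------------------
# Surrogate EMG
# ---------------------------------------------------------------------------

def modulation_envelopes(result: SimulationResult, rate_hz: float = 1400.0,
                         cutoff_hz: float = 2.0) -> pd.DataFrame:
    """The activation-like envelopes that modulate the surrogate EMG.

    Normalized muscle forces are band-limited with a zero-phase second-order
    Butterworth at ``cutoff_hz`` (activation dynamics smooth out the
    millisecond-scale force fluctuations a feedback controller produces),
    clipped at zero, re-normalized to a unit trial maximum, and resampled to
    the EMG rate.  Columns: ``time_s`` plus one column per muscle.
    """
    from scipy import signal as sps

    from .evaluation import normalize_muscle_forces

    env = normalize_muscle_forces(result.muscle_forces)
    t_src = result.time
    fs = 1.0 / float(np.mean(np.diff(t_src))) if len(t_src) > 1 else rate_hz
    t = np.arange(t_src[0], t_src[-1], 1.0 / rate_hz)
    out = {"time_s": t}
    b, a = sps.butter(2, cutoff_hz, btype="low", fs=fs)
    pad = 3 * max(len(a), len(b))
    for col in env.columns:
        x = env[col].to_numpy()
        if len(x) > pad and x.max() > 0.0:
            x = np.clip(sps.filtfilt(b, a, x), 0.0, None)
            if x.max() > 0.0:
                x = x / x.max()
        out[col] = np.interp(t, t_src, x)
    return pd.DataFrame(out)


def generate_synthetic_emg(result: SimulationResult, rate_hz: float = 1400.0,
                           seed: int = 0, scale_v: float = 5e-4,
                           baseline_fraction: float = 0.01,
                           cutoff_hz: float = 2.0) -> pd.DataFrame:
    """Raw EMG surrogate: seeded broadband carrier amplitude-modulated by the
    band-limited muscle-force envelope, sampled at the EMG rate.

    Designed so that the standard envelope pipeline (demean, rectify, 6 Hz
    low-pass, trial-max normalize) recovers the modulating envelope of
    :func:`modulation_envelopes`.
    """
    env = modulation_envelopes(result, rate_hz=rate_hz, cutoff_hz=cutoff_hz)
    t = env["time_s"].to_numpy()
    rng = np.random.default_rng(seed)
    out = {"time_s": t}
    for col in env.columns:
        if col == "time_s":
            continue
        # Rademacher carrier: zero-mean and spectrally flat, with unit
        # magnitude so rectification returns the envelope itself
        carrier = rng.integers(0, 2, len(t)) * 2.0 - 1.0
        noise = baseline_fraction * rng.standard_normal(len(t))
        out[col] = scale_v * (carrier * env[col].to_numpy() + noise)
    return pd.DataFrame(out)
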