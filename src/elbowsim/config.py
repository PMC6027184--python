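"""YAML model/run configuration and (de)serialization.

A model configuration is a single YAML document describing bodies, ligament
bundles, contact pairs (cartilage mesh files plus analytic socket
definitions), muscles and anatomical frames.  Cartilage grids are rebuilt
from the referenced STL meshes at load time; discretization is deterministic,
so a round-tripped model is identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .contact import ContactParameters, CylindricalSocket, SphericalSocket
from .engine import ContactPair, ElbowModel, RigidBody
from .errors import ParameterError
from .geometry import AnatomicalFrame, discretize_cartilage, load_mesh
from .ligaments import LigamentBundle, LigamentComplex, WrapCylinder, WrapSphere
from .muscles import GainSchedule, MuscleActuator

log = logging.getLogger(__name__)


def _vec(x) -> list[float]:
    return [float(v) for v in np.asarray(x).reshape(-1)]


# ---------------------------------------------------------------------------
# Model -> dict
# ---------------------------------------------------------------------------

def model_to_dict(model: ElbowModel, frames: dict[str, AnatomicalFrame],
                  mesh_files: dict[str, str]) -> dict[str, Any]:
    """Serialize a model; ``mesh_files`` maps contact pair name -> STL path
    (relative to the config file) for each pair's cartilage surface."""
    d: dict[str, Any] = {
        "driven_body": model.driven_body,
        "gravity_mm_s2": _vec(model.gravity),
        "body_drag": {"linear_Ns_mm": model.body_drag_linear,
                      "angular_Nmms": model.body_drag_angular},
        "bodies": {}, "ligaments": [], "contact": {}, "muscles": [],
        "frames": {},
    }
    for name, b in model.bodies.items():
        d["bodies"][name] = {"mass_kg": b.mass,
                             "com_mm": _vec(b.com_local),
                             "inertia_kg_mm2": _vec(b.inertia)}
    for lb in model.ligaments.bundles:
        entry: dict[str, Any] = {
            "name": lb.name, "ligament": lb.ligament,
            "origin": [lb.origin_body, _vec(lb.origin_point)],
            "insertion": [lb.insertion_body, _vec(lb.insertion_point)],
            "k_N": lb.k, "eps_l": lb.eps_l,
            "l0_mm": None if lb.l0 is None else float(lb.l0),
        }
        if lb.via:
            entry["via"] = [[b, _vec(p)] for b, p in lb.via]
        if lb.wrap:
            obs = []
            for o in lb.wrap:
                if isinstance(o, WrapSphere):
                    obs.append({"type": "sphere", "body": o.body,
                                "center_mm": _vec(o.center_local),
                                "radius_mm": o.radius})
                else:
                    obs.append({"type": "cylinder", "body": o.body,
                                "point_mm": _vec(o.point_local),
                                "axis": _vec(o.axis_local),
                                "radius_mm": o.radius})
            entry["wrap"] = obs
        d["ligaments"].append(entry)

    if model.contacts:
        p = model.contacts[0].params
        d["contact"]["params"] = {"kc_N_mm_n": p.kc, "n": p.n,
                                  "c_max_Ns_mm": p.c_max, "d_max_mm": p.d_max}
        pairs = []
        for pair in model.contacts:
            g = pair.grid
            pd: dict[str, Any] = {
                "name": pair.name,
                "grid": {"mesh": mesh_files[pair.name], "body": g.parent_body,
                         "target_size_mm": g.target_size,
                         "thickness_mm": float(g.thickness[0]),
                         "compartment": g.compartment},
            }
            opp = pair.opposing
            if isinstance(opp, CylindricalSocket):
                pd["opposing"] = {
                    "type": "cylindrical_socket", "body": opp.body,
                    "center_mm": _vec(opp.center_local),
                    "axis": _vec(opp.axis_local),
                    "inner_radius_mm": opp.inner_radius,
                    "half_length_mm": opp.half_length,
                    "aperture_center": _vec(opp.aperture_center_local),
                    "aperture_half_angle_deg": float(
                        np.rad2deg(opp.aperture_half_angle))}
            elif isinstance(opp, SphericalSocket):
                pd["opposing"] = {
                    "type": "spherical_socket", "body": opp.body,
                    "center_mm": _vec(opp.center_local),
                    "inner_radius_mm": opp.inner_radius,
                    "aperture_axis": _vec(opp.aperture_axis_local),
                    "aperture_half_angle_deg": float(
                        np.rad2deg(opp.aperture_half_angle))}
            else:
                pd["opposing"] = {"type": "mesh", "body": opp.body_name,
                                  "mesh": mesh_files[f"{pair.name}-opposing"]}
            pairs.append(pd)
        d["contact"]["pairs"] = pairs

    sched = model.muscles[0].schedule if model.muscles else GainSchedule()
    d["gains"] = {"global_P": sched.global_p, "global_I": sched.global_i,
                  "global_D": sched.global_d,
                  "reference_PCSA_mm2": sched.reference_pcsa}
    for m in model.muscles:
        d["muscles"].append({"name": m.name,
                             "path": [[b, _vec(p)] for b, p in m.path],
                             "PCSA_mm2": m.pcsa, "Fmax_N": m.f_max})
    for name, f in frames.items():
        d["frames"][name] = {"origin_mm": _vec(f.origin),
                             "axes": _vec(f.axes)}
    return d


def save_model(path: str | Path, model: ElbowModel,
               frames: dict[str, AnatomicalFrame],
               mesh_files: dict[str, str]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model, frames, mesh_files), fh,
                       sort_keys=False)


# ---------------------------------------------------------------------------
# dict -> model
# ---------------------------------------------------------------------------

def _wrap_from_dict(d: dict) -> WrapSphere | WrapCylinder:
    if d["type"] == "sphere":
        return WrapSphere(body=d["body"], center_local=d["center_mm"],
                          radius=d["radius_mm"])
    if d["type"] == "cylinder":
        return WrapCylinder(body=d["body"], point_local=d["point_mm"],
                            axis_local=d["axis"], radius=d["radius_mm"])
    raise ParameterError(f"unknown wrap obstacle type {d['type']!r}")


def model_from_dict(d: dict[str, Any], base_dir: str | Path = ".",
                    ) -> tuple[ElbowModel, dict[str, AnatomicalFrame]]:
    base = Path(base_dir)
    bodies = {name: RigidBody(name=name, mass=bd["mass_kg"],
                              inertia=np.asarray(bd["inertia_kg_mm2"]).reshape(3, 3),
                              com_local=bd["com_mm"])
              for name, bd in d["bodies"].items()}

    bundles = []
    for e in d.get("ligaments", []):
        bundles.append(LigamentBundle(
            name=e["name"], ligament=e["ligament"],
            origin_body=e["origin"][0], origin_point=e["origin"][1],
            insertion_body=e["insertion"][0], insertion_point=e["insertion"][1],
            k=e["k_N"], eps_l=e.get("eps_l", 0.03), l0=e.get("l0_mm"),
            via=tuple((b, np.asarray(p)) for b, p in e.get("via", [])),
            wrap=tuple(_wrap_from_dict(w) for w in e.get("wrap", []))))

    contacts = []
    cd = d.get("contact", {})
    if cd:
        pp = cd.get("params", {})
        params = ContactParameters(kc=pp.get("kc_N_mm_n", 40.0),
                                   n=pp.get("n", 3.05),
                                   c_max=pp.get("c_max_Ns_mm", 5.0),
                                   d_max=pp.get("d_max_mm", 0.1))
        for pd in cd.get("pairs", []):
            gd = pd["grid"]
            surface = load_mesh(base / gd["mesh"], body_name=gd["body"])
            grid = discretize_cartilage(surface, gd.get("target_size_mm", 3.0),
                                        thickness=gd.get("thickness_mm", 2.0),
                                        compartment=gd.get("compartment", pd["name"]))
            od = pd["opposing"]
            if od["type"] == "cylindrical_socket":
                opposing: Any = CylindricalSocket(
                    body=od["body"], center_local=od["center_mm"],
                    axis_local=od["axis"],
                    inner_radius=od["inner_radius_mm"],
                    half_length=od["half_length_mm"],
                    aperture_center_local=od["aperture_center"],
                    aperture_half_angle=np.deg2rad(od["aperture_half_angle_deg"]))
            elif od["type"] == "spherical_socket":
                opposing = SphericalSocket(
                    body=od["body"], center_local=od["center_mm"],
                    inner_radius=od["inner_radius_mm"],
                    aperture_axis_local=od["aperture_axis"],
                    aperture_half_angle=np.deg2rad(od["aperture_half_angle_deg"]))
            elif od["type"] == "mesh":
                opposing = load_mesh(base / od["mesh"], body_name=od["body"])
            else:
                raise ParameterError(f"unknown opposing surface {od['type']!r}")
            contacts.append(ContactPair(pd["name"], grid, opposing, params))

    gd = d.get("gains", {})
    schedule = GainSchedule(global_p=gd.get("global_P", 50.0),
                            global_i=gd.get("global_I", 5.0),
                            global_d=gd.get("global_D", 0.0005),
                            reference_pcsa=gd.get("reference_PCSA_mm2", 487.0))
    muscles = [MuscleActuator(name=m["name"],
                              path=[(b, np.asarray(p)) for b, p in m["path"]],
                              pcsa=m["PCSA_mm2"], f_max=m["Fmax_N"],
                              schedule=schedule)
               for m in d.get("muscles", [])]

    drag = d.get("body_drag", {})
    model = ElbowModel(
        bodies=bodies, ligaments=LigamentComplex(bundles), contacts=contacts,
        muscles=muscles,
        gravity=np.asarray(d.get("gravity_mm_s2", [0, 0, -9810.0])),
        driven_body=d.get("driven_body", "humerus"),
        body_drag_linear=drag.get("linear_Ns_mm", 0.02),
        body_drag_angular=drag.get("angular_Nmms", 2.0))
    frames = {name: AnatomicalFrame(origin=fd["origin_mm"],
                                    axes=np.asarray(fd["axes"]).reshape(3, 3))
              for name, fd in d.get("frames", {}).items()}
    return model, frames


def load_model(path: str | Path) -> tuple[ElbowModel, dict[str, AnatomicalFrame]]:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return model_from_dict(d, base_dir=path.parent)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and settings tying the synth/calibrate/simulate/evaluate chain."""

    model: str = "model.yaml"
    model_calibrated: str = "model_calibrated.yaml"
    trials: dict[str, str] = field(default_factory=dict)
    simulate_trial: str = "60deg_s"
    dt_internal: float = 1e-4
    dt_output: float = 0.01
    duration: float | None = None
    calibration_factor: float = 0.8
    use_wrapped_lengths: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_output < self.dt_internal:
            raise ParameterError("dt_output must be >= dt_internal")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        d = {"model": self.model, "model_calibrated": self.model_calibrated,
             "trials": dict(self.trials), "simulate_trial": self.simulate_trial,
             "dt_internal": self.dt_internal, "dt_output": self.dt_output,
             "duration": self.duration,
             "calibration_factor": self.calibration_factor,
             "use_wrapped_lengths": self.use_wrapped_lengths,
             "seed": self.seed}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
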