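"""Five-stage design pipeline for the applicator family, plus config,
reporting and (de)serialization.

The pipeline reproduces the staged weight-reduction chain for square
applicators from 6x6 to 25x25 cm^2:

* **initial** — un-beveled tungsten frames at planes 70/80/95 cm, all inner
  edges at the 95% OAR of the upstream 6-MeV penumbra, outer edges at 2%.
* **bevel** — per-energy beveled outer edges (2% OAR anchor per energy).
* **plane optimization** — upper/middle trimmer planes moved to the
  mass-minimizing positions (defaults from the published grid-search optima;
  re-optimization available via the optimizer module).
* **inner edges** — planes fixed at 66/79 cm; per-applicator inner-edge OAR
  sets (the flatness-verified family values).
* **jaw schedule** — per-energy jaw positions interpolating the upper-edge
  OAR from its 6-MeV value down to 55% at 20 MeV.
* **thickness & bevel shape** — upper trimmer thickness scaled to 51%;
  middle/lower outer-edge OAR interpolated from 2% at 6 MeV to 48% at 20 MeV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beam_model import ElectronBeamModel, MachineGeometry
from .design_optimizer import interpolated_oar
from .fluence_flatness import evaluate_flatness, transport_fluence
from .materials import TrimmerMaterial
from .mass_engine import MassReport, TrimmerMass
from .trimmer_geometry import (ApplicatorDesign, CollimatorPlane,
                               CrossSectionProfile, build_applicator)

__all__ = [
    "FAMILY_INNER_OARS",
    "CollimationSystemDesign",
    "default_config",
    "load_config",
    "build_model",
    "applicator_stages",
    "run_design_pipeline",
    "write_design_report",
    "design_to_dict",
    "design_from_dict",
]

# Per-applicator inner-edge matching OARs at 6 MeV (lower/middle/upper) for
# the final family designs, and the common 20-MeV upper-edge OAR.
FAMILY_INNER_OARS: dict = {
    6.0:  {"lower": 0.950, "middle": 0.960, "upper": 0.965},
    10.0: {"lower": 0.950, "middle": 0.960, "upper": 0.965},
    14.0: {"lower": 0.925, "middle": 0.940, "upper": 0.950},
    20.0: {"lower": 0.890, "middle": 0.910, "upper": 0.930},
    25.0: {"lower": 0.890, "middle": 0.910, "upper": 0.930},
}
JAW_OAR_AT_20MEV = 0.55
FINAL_UPPER_THICKNESS_FRACTION = 0.51
FINAL_OUTER_OAR_AT_20MEV = 0.48

# Mass-minimizing upper/middle plane positions from the 0.5-cm grid search
# (10x10 and 20x20 templates; intermediate sizes interpolated).
PLANE_OPTIMA: dict = {6.0: (61.0, 77.0), 10.0: (61.0, 77.0),
                      14.0: (61.25, 77.25), 20.0: (61.5, 77.5),
                      25.0: (61.5, 77.5)}

STAGES = ("initial", "bevel", "plane_optimization", "inner_edges",
          "jaw_schedule", "thickness_bevel")


@dataclass(frozen=True)
class CollimationSystemDesign:
    """The five-applicator family: final designs, stage ledger, flatness."""

    applicators: dict        # field size -> ApplicatorDesign (final stage)
    ledger: pd.DataFrame     # one row per (applicator, stage)
    flatness: dict           # field size -> FlatnessReport at the lowest energy
    config: dict = field(default_factory=dict, compare=False)

    def total_mass(self, field_size: float) -> float:
        return self.applicators[field_size].total_trimmer_mass


def default_config() -> dict:
    return {
        "machine": {},   # MachineGeometry field overrides
        "beam": {},      # ElectronBeamModel field overrides
        "material": {},  # TrimmerMaterial field overrides
        "pipeline": {
            "applicators": [6.0, 10.0, 14.0, 20.0, 25.0],
            "initial_z": [70.0, 80.0, 95.0],
            "final_z": [66.0, 79.0, 95.0],
            "z_lower": 95.0,
            "plane_optima": {str(k): list(v) for k, v in PLANE_OPTIMA.items()},
            "inner_oars": {str(k): dict(v) for k, v in FAMILY_INNER_OARS.items()},
            "jaw_oar_20mev": JAW_OAR_AT_20MEV,
            "upper_thickness_fraction": FINAL_UPPER_THICKNESS_FRACTION,
            "outer_oar_20mev": FINAL_OUTER_OAR_AT_20MEV,
            "corner": "miter",
            "bevel_style": "taper",
            "stages": list(STAGES),
            "reoptimize_planes": False,
            "flatness_grid": 0.05,
        },
    }


def load_config(path: str | Path | None = None) -> dict:
    """Default config, deep-merged with a YAML file if given."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg


def build_model(config: dict) -> tuple[MachineGeometry, ElectronBeamModel, TrimmerMaterial]:
    machine = MachineGeometry(**config.get("machine", {}))
    beam_kwargs = dict(config.get("beam", {}))
    if "energies" in beam_kwargs:
        beam_kwargs["energies"] = tuple(float(e) for e in beam_kwargs["energies"])
    beam = ElectronBeamModel(**beam_kwargs)
    material = TrimmerMaterial(**config.get("material", {}))
    return machine, beam, material


def applicator_stages(field_size: float, machine: MachineGeometry,
                      beam: ElectronBeamModel, material: TrimmerMaterial,
                      pipeline_cfg: dict) -> dict:
    """Build every requested pipeline stage of one applicator; returns
    {stage: ApplicatorDesign}."""
    p = pipeline_cfg
    corner = p.get("corner", "miter")
    style = p.get("bevel_style", "taper")
    key = str(float(field_size))
    inner = {k: float(v) for k, v in p["inner_oars"][key].items()}
    zopt = tuple(float(v) for v in p["plane_optima"][key]) + (float(p["z_lower"]),)
    z_init = tuple(float(v) for v in p["initial_z"])
    z_final = tuple(float(v) for v in p["final_z"])
    common = dict(corner=corner, bevel_style=style)

    stages: dict = {}
    want = p.get("stages", STAGES)
    if "initial" in want:
        stages["initial"] = build_applicator(
            field_size, machine, beam, material, trimmer_z=z_init,
            bevel=False, tags=("initial",), **common)
    if "bevel" in want:
        stages["bevel"] = build_applicator(
            field_size, machine, beam, material, trimmer_z=z_init,
            bevel=True, tags=("initial", "bevel"), **common)
    if "plane_optimization" in want:
        if p.get("reoptimize_planes"):
            from .design_optimizer import optimize_trimmer_z
            res = optimize_trimmer_z(field_size, machine, beam, material,
                                     z_lower=float(p["z_lower"]), **common)
            zopt = (res.best_params["z_upper"], res.best_params["z_middle"],
                    float(p["z_lower"]))
        stages["plane_optimization"] = build_applicator(
            field_size, machine, beam, material, trimmer_z=zopt,
            bevel=True, tags=("bevel", "plane_optimization"), **common)
    if "inner_edges" in want:
        stages["inner_edges"] = build_applicator(
            field_size, machine, beam, material, trimmer_z=z_final,
            inner_oars=inner, bevel=True,
            tags=("bevel", "inner_edges"), **common)
    jaw = interpolated_oar(inner["upper"], float(p["jaw_oar_20mev"]),
                           beam.e_min, beam.e_max)
    if "jaw_schedule" in want:
        stages["jaw_schedule"] = build_applicator(
            field_size, machine, beam, material, trimmer_z=z_final,
            inner_oars=inner, jaw_oar=jaw, bevel=True,
            tags=("bevel", "inner_edges", "jaw_schedule"), **common)
    if "thickness_bevel" in want:
        outer = interpolated_oar(0.02, float(p["outer_oar_20mev"]),
                                 beam.e_min, beam.e_max)
        stages["thickness_bevel"] = build_applicator(
            field_size, machine, beam, material, trimmer_z=z_final,
            inner_oars=inner, jaw_oar=jaw,
            outer_oars={"middle": outer, "lower": outer},
            thickness_fractions={"upper": float(p["upper_thickness_fraction"])},
            bevel=True,
            tags=("bevel", "inner_edges", "jaw_schedule", "thickness_bevel"),
            **common)
    return stages


def run_design_pipeline(config: dict | None = None) -> CollimationSystemDesign:
    """Run the staged design chain for the whole applicator family."""
    cfg = config or default_config()
    machine, beam, material = build_model(cfg)
    p = cfg["pipeline"]
    rows = []
    finals: dict = {}
    flatness: dict = {}
    for size in p["applicators"]:
        size = float(size)
        stages = applicator_stages(size, machine, beam, material, p)
        prev = None
        initial = None
        for stage, design in stages.items():
            mass = design.total_trimmer_mass
            if initial is None:
                initial = mass
            step_red = np.nan if prev is None else 100.0 * (prev - mass) / prev
            cum_red = 100.0 * (initial - mass) / initial
            rows.append({"applicator": size, "stage": stage, "mass_kg": mass,
                         "step_reduction_pct": step_red,
                         "cumulative_reduction_pct": cum_red})
            prev = mass
        final = list(stages.values())[-1]
        finals[size] = final
        reports = []
        for axis in ("inplane", "crossplane"):
            prof = transport_fluence(machine, beam, final, beam.e_min, axis,
                                     grid_spacing=float(p.get("flatness_grid", 0.05)))
            reports.append(evaluate_flatness(prof, size))
        flatness[size] = min(reports, key=lambda r: r.margin)
    ledger = pd.DataFrame(rows)
    return CollimationSystemDesign(applicators=finals, ledger=ledger,
                                   flatness=flatness, config=cfg)


# ---------------------------------------------------------------------------
# serialization

_SCHEMA_VERSION = 1


def _profile_to_dict(p: CrossSectionProfile) -> dict:
    return {"axis": p.axis, "points": [list(pt) for pt in p.points],
            "inner_shear_slope": p.inner_shear_slope}


def _profile_from_dict(d: dict) -> CrossSectionProfile:
    return CrossSectionProfile(axis=d["axis"],
                               points=tuple(tuple(pt) for pt in d["points"]),
                               inner_shear_slope=d["inner_shear_slope"])


def design_to_dict(design: ApplicatorDesign) -> dict:
    return {
        "schema_version": _SCHEMA_VERSION,
        "field_size": design.field_size,
        "trimmer_z": list(design.trimmer_z),
        "planes": {k: asdict(v) for k, v in design.planes.items()},
        "profiles": {t: {ax: _profile_to_dict(pr) for ax, pr in axes.items()}
                     for t, axes in design.profiles.items()},
        "jaw_schedule": {str(E): v for E, v in design.jaw_schedule.items()},
        "mass_report": {
            "geometry_tag": design.mass_report.geometry_tag,
            "trimmers": {t: {"bars": tm.bars, "shear": tm.shear, "corner": tm.corner}
                         for t, tm in design.mass_report.trimmers.items()},
        },
        "tags": list(design.tags),
    }


def design_from_dict(d: dict) -> ApplicatorDesign:
    if d.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError("unsupported design schema version")
    planes = {k: CollimatorPlane(**v) for k, v in d["planes"].items()}
    profiles = {t: {ax: _profile_from_dict(pr) for ax, pr in axes.items()}
                for t, axes in d["profiles"].items()}
    report = MassReport(
        trimmers={t: TrimmerMass(bars=tm["bars"], shear=tm["shear"],
                                 corner=tm["corner"])
                  for t, tm in d["mass_report"]["trimmers"].items()},
        geometry_tag=d["mass_report"]["geometry_tag"])
    return ApplicatorDesign(
        field_size=d["field_size"], trimmer_z=tuple(d["trimmer_z"]),
        planes=planes, profiles=profiles,
        jaw_schedule={float(E): v for E, v in d["jaw_schedule"].items()},
        mass_report=report, tags=tuple(d["tags"]))


def write_design_report(system: CollimationSystemDesign, path: str | Path) -> list[Path]:
    """Emit the versioned design JSON plus fabrication-facing CSVs.

    Returns the list of files written.  Re-reading the JSON reconstructs
    identical designs (see :func:`design_from_dict`).
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    doc = {"schema_version": _SCHEMA_VERSION,
           "applicators": {str(size): design_to_dict(d)
                           for size, d in system.applicators.items()}}
    fp = out / "collimation_system.json"
    fp.write_text(json.dumps(doc, indent=1, sort_keys=True))
    written.append(fp)

    fp = out / "weight_ledger.csv"
    system.ledger.to_csv(fp, index=False)
    written.append(fp)

    jaw_rows = []
    for size, design in system.applicators.items():
        for E, axes in sorted(design.jaw_schedule.items()):
            jaw_rows.append({
                "applicator": size, "energy_mev": E,
                "inplane_aperture_cm": axes["inplane"]["aperture"],
                "inplane_at_isocenter_cm": axes["inplane"]["isocenter"],
                "crossplane_aperture_cm": axes["crossplane"]["aperture"],
                "crossplane_at_isocenter_cm": axes["crossplane"]["isocenter"],
            })
    fp = out / "jaw_schedule.csv"
    pd.DataFrame(jaw_rows).to_csv(fp, index=False)
    written.append(fp)

    for size, design in system.applicators.items():
        rows = []
        for trimmer, axes in design.profiles.items():
            for axis, prof in axes.items():
                for x, t in prof.points:
                    rows.append({"trimmer": trimmer, "axis": axis,
                                 "x_cm": x, "thickness_cm": t})
        fp = out / f"profiles_{size:g}x{size:g}.csv"
        pd.DataFrame(rows).to_csv(fp, index=False)
        written.append(fp)
    return written
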