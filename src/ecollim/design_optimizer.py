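"""Design-optimization machinery: exhaustive grid searches over trimmer
plane positions and inner-edge OARs, per-energy jaw schedules, and the
one-off calibration of the jaw plane heights.

Both optimizers are brute-force enumerations over their grids: results are
deterministic and bitwise reproducible, with documented tie-breaking (lowest
mass, then smallest upper-trimmer z, then smallest middle-trimmer z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .beam_model import (ElectronBeamModel, MachineGeometry, oar_offset,
                         project_to_plane, sigma_penumbra)
from .materials import TrimmerMaterial
from .trimmer_geometry import (ApplicatorDesign, InfeasibleGeometryError,
                               build_applicator)

__all__ = [
    "GridSpec",
    "OptimizationResult",
    "optimize_trimmer_z",
    "optimize_inner_oars",
    "incremental_designs",
    "interpolated_oar",
    "jaw_schedule",
    "calibrate_jaw_z",
    "calibrate_jaw_z_from_projection",
]


@dataclass(frozen=True)
class GridSpec:
    """Iterated grid-search specification.

    ``initial_bounds`` define the first-iteration grid; later iterations
    re-center on the incumbent with the (smaller) step of that iteration,
    spanning incumbent +/- 2*step, clipped to ``global_bounds``.
    """

    initial_bounds: dict  # param -> (lo, hi)
    steps: tuple  # one {param: step} dict per iteration
    global_bounds: dict | None = None

    def __post_init__(self) -> None:
        for param, (lo, hi) in self.initial_bounds.items():
            if hi < lo:
                raise ValueError(f"bounds reversed for {param}")
        for it in self.steps:
            if any(s <= 0 for s in it.values()):
                raise ValueError("steps must be positive")
        for prev, nxt in zip(self.steps[:-1], self.steps[1:]):
            if any(nxt[p] > prev[p] for p in nxt):
                raise ValueError("iteration steps must be nonincreasing")

    def grid_axes(self, iteration: int, incumbent: Mapping[str, float] | None) -> dict:
        axes = {}
        for param in self.initial_bounds:
            step = self.steps[iteration][param]
            if iteration == 0 or incumbent is None:
                lo, hi = self.initial_bounds[param]
            else:
                lo = incumbent[param] - 2.0 * step
                hi = incumbent[param] + 2.0 * step
                if self.global_bounds and param in self.global_bounds:
                    glo, ghi = self.global_bounds[param]
                    lo, hi = max(lo, glo), min(hi, ghi)
            n = int(round((hi - lo) / step)) + 1
            axes[param] = np.round(lo + step * np.arange(n), 10)
        return axes


@dataclass(frozen=True)
class OptimizationResult:
    best_params: dict
    best_mass: float
    evaluations: tuple  # records: {params..., "mass": kg, "feasible": bool|None}
    metadata: dict = field(default_factory=dict, compare=False)

    def isomass_grid(self):
        """(z_upper, z_middle, mass) records for isomass contour plotting."""
        return [(r.get("z_upper"), r.get("z_middle"), r["mass"])
                for r in self.evaluations if r["mass"] is not None]


def default_inner_edge_gridspec() -> GridSpec:
    """Three-iteration five-parameter schedule (OAR steps 1.5/1.0/0.5 %,
    z steps 1.5/1.0/0.5 cm) used for the inner-edge optimization."""
    return GridSpec(
        initial_bounds={
            "oar_upper": (0.875, 0.95), "oar_middle": (0.86, 0.95),
            "oar_lower": (0.86, 0.95), "z_upper": (58.5, 64.5),
            "z_middle": (74.5, 80.5),
        },
        steps=(
            {"oar_upper": 0.015, "oar_middle": 0.015, "oar_lower": 0.015,
             "z_upper": 1.5, "z_middle": 1.5},
            {"oar_upper": 0.01, "oar_middle": 0.01, "oar_lower": 0.01,
             "z_upper": 1.0, "z_middle": 1.0},
            {"oar_upper": 0.005, "oar_middle": 0.005, "oar_lower": 0.005,
             "z_upper": 0.5, "z_middle": 0.5},
        ),
        global_bounds={"oar_upper": (0.80, 0.95), "oar_middle": (0.80, 0.95),
                       "oar_lower": (0.80, 0.95), "z_upper": (55.0, 93.0),
                       "z_middle": (55.0, 93.0)},
    )


def optimize_trimmer_z(field_size: float,
                       machine: MachineGeometry,
                       beam: ElectronBeamModel,
                       material: TrimmerMaterial,
                       z_range: tuple[float, float] = (55.0, 93.0),
                       step: float = 0.5,
                       min_separation: float = 2.0,
                       z_lower: float = 95.0,
                       **build_kwargs) -> OptimizationResult:
    """Exhaustive search over upper/middle trimmer plane positions that
    minimizes total trimmer mass (beveled shapes regenerated per point).

    Ties break toward the smallest upper then middle plane position.
    """
    lo, hi = z_range
    zs = np.round(np.arange(lo, hi + step / 2.0, step), 10)
    z_jaw_floor = max(machine.z_jaw_inplane, machine.z_jaw_crossplane)
    records = []
    best = None
    for z_up in zs:
        if z_up <= z_jaw_floor:
            continue
        for z_mid in zs:
            if z_mid - z_up < min_separation or z_lower - z_mid < min_separation:
                continue
            try:
                design = build_applicator(field_size, machine, beam, material,
                                          trimmer_z=(float(z_up), float(z_mid), z_lower),
                                          **build_kwargs)
                mass = design.total_trimmer_mass
            except InfeasibleGeometryError:
                mass = None
            records.append({"z_upper": float(z_up), "z_middle": float(z_mid),
                            "mass": mass, "feasible": mass is not None})
            if mass is not None and (best is None or mass < best[0] - 1e-12):
                best = (mass, float(z_up), float(z_mid))
    if best is None:
        raise InfeasibleGeometryError("no feasible (z_upper, z_middle) point in the grid")
    mass, z_up, z_mid = best
    return OptimizationResult(
        best_params={"z_upper": z_up, "z_middle": z_mid},
        best_mass=mass, evaluations=tuple(records),
        metadata={"z_lower": z_lower, "step": step, "min_separation": min_separation})


def optimize_inner_oars(field_size: float,
                        machine: MachineGeometry,
                        beam: ElectronBeamModel,
                        material: TrimmerMaterial,
                        grid: GridSpec,
                        flatness_fn: Callable[[ApplicatorDesign], object],
                        z_lower: float = 95.0,
                        min_separation: float = 2.0,
                        **build_kwargs) -> OptimizationResult:
    """Iterated five-parameter grid search (three trimmer inner-edge OARs
    plus two trimmer plane positions) minimizing mass subject to the
    analytical flatness constraint at the lowest beam energy.

    ``flatness_fn(design)`` must return an object with boolean ``passed``
    and numeric ``margin`` attributes.  Within each iteration candidate
    points are checked in ascending-mass order, so the first feasible point
    is that iteration's optimum.
    """
    incumbent = None
    incumbent_mass = None
    all_records: list[dict] = []
    for it in range(len(grid.steps)):
        axes = grid.grid_axes(it, incumbent)
        candidates = []
        for ou in axes["oar_upper"]:
            for om in axes["oar_middle"]:
                for ol in axes["oar_lower"]:
                    for zu in axes["z_upper"]:
                        for zm in axes["z_middle"]:
                            if zm - zu < min_separation or z_lower - zm < min_separation:
                                continue
                            params = {"oar_upper": float(ou), "oar_middle": float(om),
                                      "oar_lower": float(ol), "z_upper": float(zu),
                                      "z_middle": float(zm)}
                            try:
                                design = build_applicator(
                                    field_size, machine, beam, material,
                                    trimmer_z=(float(zu), float(zm), z_lower),
                                    inner_oars={"upper": float(ou), "middle": float(om),
                                                "lower": float(ol)},
                                    **build_kwargs)
                            except InfeasibleGeometryError:
                                continue
                            candidates.append((design.total_trimmer_mass, params, design))
        candidates.sort(key=lambda c: (c[0], c[1]["z_upper"], c[1]["z_middle"]))
        found = None
        best_margin = (-np.inf, None)
        for mass, params, design in candidates:
            report = flatness_fn(design)
            rec = dict(params, mass=mass, feasible=bool(report.passed))
            all_records.append(rec)
            if report.margin > best_margin[0]:
                best_margin = (report.margin, params)
            if report.passed:
                found = (mass, params)
                break
        if found is None:
            raise InfeasibleGeometryError(
                f"iteration {it}: no flatness-feasible point; closest margin "
                f"{best_margin[0]:.4f} at {best_margin[1]}")
        incumbent_mass, incumbent = found
    return OptimizationResult(best_params=incumbent, best_mass=incumbent_mass,
                              evaluations=tuple(all_records),
                              metadata={"iterations": len(grid.steps)})


def incremental_designs(field_size: float,
                        machine: MachineGeometry,
                        beam: ElectronBeamModel,
                        material: TrimmerMaterial,
                        oar_sets: Sequence[Mapping[str, float]],
                        trimmer_z: tuple[float, float, float] = (66.0, 79.0, 95.0),
                        **build_kwargs) -> list[tuple[ApplicatorDesign, float | None]]:
    """Designs built at fixed trimmer planes for a ladder of inner-edge OAR
    sets, with the mass increment of each design over its predecessor."""
    for trimmer in ("upper", "middle", "lower"):
        vals = [s[trimmer] for s in oar_sets]
        if any(b < a for a, b in zip(vals[:-1], vals[1:])):
            warnings.warn(f"{trimmer} trimmer OAR sequence is not nondecreasing",
                          stacklevel=2)
    out: list[tuple[ApplicatorDesign, float | None]] = []
    prev_mass = None
    for oars in oar_sets:
        design = build_applicator(field_size, machine, beam, material,
                                  trimmer_z=trimmer_z, inner_oars=dict(oars),
                                  **build_kwargs)
        delta = None if prev_mass is None else design.total_trimmer_mass - prev_mass
        out.append((design, delta))
        prev_mass = design.total_trimmer_mass
    return out


def interpolated_oar(oar_lo: float, oar_hi: float,
                     e_lo: float = 6.0, e_hi: float = 20.0) -> Callable[[float], float]:
    """OAR(E) linear in energy between two endpoint values (exact at both)."""
    if not (0.0 < oar_lo < 1.0 and 0.0 < oar_hi < 1.0):
        raise ValueError("OARs must lie in (0, 1)")
    def fn(E: float) -> float:
        w = (E - e_lo) / (e_hi - e_lo)
        return oar_lo + w * (oar_hi - oar_lo)
    return fn


def jaw_schedule(oar_at_upper_6mev: float, oar_at_upper_20mev: float,
                 energies: Sequence[float], machine: MachineGeometry,
                 beam: ElectronBeamModel, upper_inner_edge: float,
                 z_upper: float) -> dict:
    """Per-energy jaw aperture half-widths (per axis) that place the upper
    trimmer inner edge at an OAR interpolated linearly in energy."""
    oar_fn = interpolated_oar(oar_at_upper_6mev, oar_at_upper_20mev)
    from .trimmer_geometry import aperture_for_downstream_match
    schedule: dict = {}
    for E in energies:
        per_axis = {}
        for axis in ("inplane", "crossplane"):
            zj = machine.z_jaw(axis)
            ap = aperture_for_downstream_match(upper_inner_edge, oar_fn(E), E,
                                               zj, z_upper, machine, beam)
            per_axis[axis] = {
                "aperture": ap,
                "isocenter": project_to_plane(ap, zj, machine.z_isocenter, machine),
            }
        schedule[E] = per_axis
    return schedule


def calibrate_jaw_z_from_projection(physical_half_width: float,
                                    isocenter_half_width: float,
                                    machine: MachineGeometry) -> float:
    """Jaw plane z from the ratio of a physical jaw half-aperture to its
    isocenter-projected value (projection through the virtual source)."""
    if not 0 < physical_half_width < isocenter_half_width:
        raise ValueError("physical aperture must be positive and smaller than "
                         "its isocenter projection")
    zeta = machine.zeta(machine.z_isocenter) * physical_half_width / isocenter_half_width
    return machine.z_virtual_source + zeta


def calibrate_jaw_z(printed_positions: Mapping[str, float], E: float,
                    target_oar: float, x_inner_upper: float, z_upper: float,
                    machine: MachineGeometry, beam: ElectronBeamModel,
                    ) -> tuple[float, float]:
    """Solve for the per-axis jaw plane z such that the modelled
    isocenter-projected jaw position (for a jaw matching ``target_oar`` at
    the upper trimmer inner edge at energy E) equals the printed value.

    ``printed_positions`` maps "inplane"/"crossplane" to the half-widths (cm
    at isocenter).  The projected position is independent of the jaw
    aperture itself; only the penumbra width depends on the jaw plane, so
    this reduces to a 1-D root find in sigma.
    """
    scale = machine.zeta(machine.z_isocenter) / machine.zeta(z_upper)
    k = oar_offset(target_oar)
    out = []
    for axis in ("inplane", "crossplane"):
        x_iso = printed_positions[axis]
        sigma_target = (x_iso / scale - x_inner_upper) / (-k)
        if sigma_target <= 0:
            raise ValueError(f"printed {axis} position inconsistent with the "
                             "upper inner edge (implied sigma <= 0)")
        def f(zj: float) -> float:
            return sigma_penumbra(E, zj, z_upper, machine, beam) - sigma_target
        lo = machine.z_virtual_source + 1e-3
        hi = z_upper - 1e-3
        if f(lo) < 0 or f(hi) > 0:
            raise ValueError(f"no jaw plane in ({lo:.1f}, {hi:.1f}) cm yields "
                             f"sigma={sigma_target:.3f} cm on the {axis} axis")
        out.append(float(brentq(f, lo, hi, xtol=1e-6)))
    return out[0], out[1]
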