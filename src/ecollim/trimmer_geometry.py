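"""Trimmer cross-section construction and the collimating-chain builder.

Each applicator trimmer is a square/rectangular frame whose bars have a
cross-section (thickness vs off-axis position) built from three rules:

* the **inner edge** sits where the penumbra cast by the upstream collimating
  component reaches a prescribed off-axis ratio (OAR) at the lowest beam
  energy (moving this OAR down shifts the edge toward the central axis);
* a **plateau** at full stopping thickness covers every position the highest
  beam energy can reach (out to its 2%-fluence position);
* a **beveled outer region** tapers the thickness down to the stopping
  thickness of the lowest energy, anchored per energy at the off-axis
  position of that energy's outer-OAR fluence level.

The chain is built bottom-up: the field size fixes the lower trimmer inner
edge at its plane, and each upstream component's aperture is solved so that
its penumbra takes the prescribed OAR value at the downstream inner edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .beam_model import (ElectronBeamModel, MachineGeometry, oar_offset,
                         project_to_plane, sigma_penumbra)
from .materials import TrimmerMaterial, stopping_thickness

__all__ = [
    "InfeasibleGeometryError",
    "CollimatorPlane",
    "CrossSectionProfile",
    "ApplicatorDesign",
    "aperture_for_downstream_match",
    "build_bevel_profile",
    "scale_profile_thickness",
    "build_applicator",
]

TRIMMERS = ("upper", "middle", "lower")


class InfeasibleGeometryError(ValueError):
    """Raised when an OAR-matching chain produces a non-positive aperture or
    a trimmer of non-positive width."""


@dataclass(frozen=True)
class CollimatorPlane:
    """One collimating level: role, plane position and aperture half-widths."""

    role: str  # jaw_inplane | jaw_crossplane | upper | middle | lower
    z_downstream: float
    aperture_half_width: dict  # {"inplane": cm, "crossplane": cm} at z_downstream
    inner_edge_divergent: bool = True

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.aperture_half_width.values()):
            raise ValueError("aperture half-widths must be positive")


@dataclass(frozen=True)
class CrossSectionProfile:
    """Piecewise-linear thickness profile t(x) of one bar pair.

    ``points`` runs from the inner edge outward; thickness is monotone
    nonincreasing.  Vertical steps (staircase bevels) are encoded as repeated
    x values.  Thickness is zero outside [x_inner, x_outer] (the bar simply
    ends; there is no zero-thickness skirt).
    """

    axis: str
    points: tuple  # ((x, t), ...)
    inner_shear_slope: float = 0.0  # dx/dz of a divergence-aligned inner face

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.points]
        ts = [p[1] for p in self.points]
        if len(self.points) < 2 or xs != sorted(xs):
            raise ValueError("profile points must be ordered in x")
        if self.x_outer <= self.x_inner:
            raise InfeasibleGeometryError("profile has non-positive width")
        if any(t < 0 for t in ts):
            raise ValueError("negative thickness")
        if any(t1 > t0 + 1e-12 for t0, t1 in zip(ts[:-1], ts[1:])):
            raise ValueError("thickness must be monotone nonincreasing outward")

    @property
    def x_inner(self) -> float:
        return self.points[0][0]

    @property
    def x_outer(self) -> float:
        return self.points[-1][0]

    @property
    def max_thickness(self) -> float:
        return self.points[0][1]

    def thickness(self, x):
        """Thickness at off-axis position(s) x (0 outside the bar)."""
        xs = np.asarray([p[0] for p in self.points])
        ts = np.asarray([p[1] for p in self.points])
        x = np.asarray(x, dtype=float)
        out = np.interp(x, xs, ts, left=0.0, right=0.0)
        return float(out) if out.ndim == 0 else out

    def area(self) -> float:
        """Cross-sectional area (cm^2) of the bar, trapezoid rule (exact for
        a piecewise-linear profile)."""
        xs = np.asarray([p[0] for p in self.points])
        ts = np.asarray([p[1] for p in self.points])
        return float(np.trapezoid(ts, xs))


@dataclass(frozen=True)
class ApplicatorDesign:
    """A complete applicator: collimating planes, per-axis trimmer profiles,
    per-energy jaw schedule and the mass report."""

    field_size: float
    trimmer_z: tuple  # (z_upper, z_middle, z_lower) downstream surfaces
    planes: dict  # role -> CollimatorPlane
    profiles: dict  # trimmer -> {"inplane": CrossSectionProfile, "crossplane": ...}
    jaw_schedule: dict  # E -> axis -> {"aperture": cm at jaw plane, "isocenter": cm}
    mass_report: object  # ecollim.mass_engine.MassReport
    tags: tuple = ()

    @property
    def total_trimmer_mass(self) -> float:
        return self.mass_report.total


def aperture_for_downstream_match(x_inner_downstream: float, target_oar: float,
                                  E_match: float, z_up: float, z_down: float,
                                  machine: MachineGeometry,
                                  beam: ElectronBeamModel) -> float:
    """Upstream aperture half-width whose penumbra has OAR ``target_oar`` at
    the downstream inner edge for energy ``E_match``."""
    sigma = sigma_penumbra(E_match, z_up, z_down, machine, beam)
    edge_at_down = x_inner_downstream - oar_offset(target_oar) * sigma
    aperture = project_to_plane(edge_at_down, z_down, z_up, machine)
    if aperture <= 0:
        raise InfeasibleGeometryError(
            f"matching OAR {target_oar} at x={x_inner_downstream} cm gives a "
            f"non-positive upstream aperture ({aperture:.3f} cm)")
    return aperture


def _pareto_anchors(anchors: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Upper envelope of (x_anchor, thickness) pairs sorted by thickness
    descending: keep an energy only if its anchor extends beyond every
    thicker (higher-energy) anchor."""
    kept: list[tuple[float, float]] = []
    x_max = -np.inf
    for x, t in sorted(anchors, key=lambda p: -p[1]):
        if x > x_max:
            kept.append((x, t))
            x_max = x
    return kept


def build_bevel_profile(x_inner: float,
                        energies: Sequence[float],
                        upstream_edge: Callable[[float], float],
                        sigma: Callable[[float], float],
                        outer_oar: Callable[[float], float],
                        material: TrimmerMaterial,
                        axis: str = "inplane",
                        style: str = "taper",
                        inner_shear_slope: float = 0.0) -> CrossSectionProfile:
    """Beveled bar profile from per-energy anchors.

    Anchor of energy E: x_a(E) = upstream_edge(E) + k(outer_oar(E)) * sigma(E),
    carrying the stopping thickness t(E).  The required profile is the upper
    envelope over energies, connected piecewise-linearly (``taper``) or as a
    step function (``staircase``).
    """
    if style not in ("taper", "staircase"):
        raise ValueError(f"unknown bevel style {style!r}")
    anchors = []
    for E in energies:
        x_a = upstream_edge(E) + oar_offset(outer_oar(E)) * sigma(E)
        anchors.append((x_a, float(stopping_thickness(E, material))))
    kept = _pareto_anchors(anchors)
    x_outer = kept[-1][0]
    if x_outer <= x_inner:
        raise InfeasibleGeometryError(
            f"outermost bevel anchor ({x_outer:.3f} cm) lies inside the inner "
            f"edge ({x_inner:.3f} cm)")

    # envelope polyline, plateau inward of the thickest kept anchor
    def envelope(x: float) -> float:
        if x <= kept[0][0]:
            return kept[0][1]
        xs = [p[0] for p in kept]
        ts = [p[1] for p in kept]
        if style == "taper":
            return float(np.interp(x, xs, ts))
        idx = int(np.searchsorted(xs, x, side="left"))
        return ts[min(idx, len(ts) - 1)]

    pts: list[tuple[float, float]] = [(x_inner, envelope(x_inner))]
    if style == "taper":
        pts += [(x, t) for x, t in kept if x > x_inner]
    else:
        outward = [(x, t) for x, t in kept if x > x_inner]
        for i, (x, t) in enumerate(outward[:-1]):
            pts.append((x, t))
            pts.append((x, outward[i + 1][1]))
        if outward:
            pts.append(outward[-1])
    return CrossSectionProfile(axis=axis, points=tuple(pts),
                               inner_shear_slope=inner_shear_slope)


def scale_profile_thickness(profile: CrossSectionProfile,
                            fraction: float) -> CrossSectionProfile:
    """Scale every thickness by ``fraction`` (mass scales exactly the same)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    pts = tuple((x, t * fraction) for x, t in profile.points)
    return CrossSectionProfile(axis=profile.axis, points=pts,
                               inner_shear_slope=profile.inner_shear_slope)


def _as_callable(spec, default: float) -> Callable[[float], float]:
    if spec is None:
        return lambda E: default
    if callable(spec):
        return spec
    if isinstance(spec, Mapping):
        return lambda E: spec[E]
    return lambda E: float(spec)


def build_applicator(field_size: float,
                     machine: MachineGeometry,
                     beam: ElectronBeamModel,
                     material: TrimmerMaterial,
                     *,
                     trimmer_z: tuple[float, float, float] = (70.0, 80.0, 95.0),
                     inner_oars: Mapping[str, float] | None = None,
                     jaw_oar=None,
                     outer_oars: Mapping[str, object] | None = None,
                     bevel: bool = True,
                     thickness_fractions: Mapping[str, float] | None = None,
                     corner: str = "miter",
                     bevel_style: str = "taper",
                     include_shear: bool = True,
                     tags: tuple = ()) -> ApplicatorDesign:
    """Build the full collimating chain for one applicator.

    Parameters
    ----------
    field_size : side of the square field at isocenter (cm).
    trimmer_z : downstream surfaces of (upper, middle, lower) trimmers (cm).
    inner_oars : OAR (of the upstream penumbra, at the lowest energy) at each
        trimmer's inner edge; default 95% everywhere (the shielding-design
        starting point).
    jaw_oar : OAR at the upper trimmer inner edge enforced by the jaws, per
        energy (float, mapping or callable); default: the upper trimmer's
        inner OAR at every energy.
    outer_oars : per-trimmer OAR schedule (per energy) at which the stopping
        thickness for that energy ends; default 2% at every energy.
    bevel : if False, bars keep full thickness out to the lowest-energy
        outer anchor (the un-beveled starting design).
    thickness_fractions : per-trimmer uniform thickness scaling (e.g. the
        51%-thickness upper trimmer).
    corner : frame corner convention, "miter" or "stacked".
    """
    from .mass_engine import MassReport, frame_mass  # deferred: avoid cycle

    if field_size <= 0:
        raise InfeasibleGeometryError("field size must be positive")
    zu, zm, zl = trimmer_z
    if not (machine.z_trimmer_min <= zu < zm < zl <= machine.z_trimmer_max):
        raise InfeasibleGeometryError(
            f"trimmer planes {trimmer_z} must be ordered within "
            f"[{machine.z_trimmer_min}, {machine.z_trimmer_max}] cm")
    if max(machine.z_jaw_inplane, machine.z_jaw_crossplane) >= zu:
        raise InfeasibleGeometryError("upper trimmer must lie below both jaw planes")

    inner = dict({t: 0.95 for t in TRIMMERS}, **(inner_oars or {}))
    outer = {t: _as_callable((outer_oars or {}).get(t), 0.02) for t in TRIMMERS}
    fractions = dict({t: 1.0 for t in TRIMMERS}, **(thickness_fractions or {}))
    jaw_oar_fn = _as_callable(jaw_oar, inner["upper"])
    e_min = beam.e_min
    energies = beam.energies if bevel else (e_min,)

    # --- bottom-up aperture chain at the lowest energy -----------------
    x_lower = field_size / 2.0 * machine.zeta(zl) / machine.zeta(machine.z_isocenter)
    ap_middle = aperture_for_downstream_match(x_lower, inner["lower"], e_min,
                                              zm, zl, machine, beam)
    ap_upper = aperture_for_downstream_match(ap_middle, inner["middle"], e_min,
                                             zu, zm, machine, beam)
    jaw_schedule: dict = {}
    for E in beam.energies:
        per_axis = {}
        for axis in ("inplane", "crossplane"):
            zj = machine.z_jaw(axis)
            ap = aperture_for_downstream_match(ap_upper, jaw_oar_fn(E), E,
                                               zj, zu, machine, beam)
            per_axis[axis] = {
                "aperture": ap,
                "isocenter": project_to_plane(ap, zj, machine.z_isocenter, machine),
            }
        jaw_schedule[E] = per_axis

    # --- per-trimmer bar profiles --------------------------------------
    def trimmer_profile(name: str, axis: str) -> CrossSectionProfile:
        if name == "upper":
            zj = machine.z_jaw(axis)
            def edge(E):  # jaw edge position projected onto the upper plane
                return project_to_plane(jaw_schedule[E][axis]["aperture"], zj, zu, machine)
            def sig(E):
                return sigma_penumbra(E, zj, zu, machine, beam)
            x_in, divergent, z_here = ap_upper, True, zu
        elif name == "middle":
            edge_val = project_to_plane(ap_upper, zu, zm, machine)
            edge = lambda E: edge_val
            sig = lambda E: sigma_penumbra(E, zu, zm, machine, beam)
            x_in, divergent, z_here = ap_middle, True, zm
        else:
            edge_val = project_to_plane(ap_middle, zm, zl, machine)
            edge = lambda E: edge_val
            sig = lambda E: sigma_penumbra(E, zm, zl, machine, beam)
            x_in, divergent, z_here = x_lower, False, zl
        slope = x_in / machine.zeta(z_here) if (divergent and include_shear) else 0.0
        if bevel:
            prof = build_bevel_profile(x_in, energies, edge, sig, outer[name],
                                       material, axis=axis, style=bevel_style,
                                       inner_shear_slope=slope)
        else:
            x_out = edge(e_min) + oar_offset(outer[name](e_min)) * sig(e_min)
            if x_out <= x_in:
                raise InfeasibleGeometryError(
                    f"{name} trimmer outer edge inside its inner edge")
            prof = CrossSectionProfile(
                axis=axis,
                points=((x_in, material.thickness_full), (x_out, material.thickness_full)),
                inner_shear_slope=slope)
        if fractions[name] != 1.0:
            prof = scale_profile_thickness(prof, fractions[name])
        return prof

    profiles = {name: {"inplane": trimmer_profile(name, "inplane"),
                       "crossplane": trimmer_profile(name, "crossplane")}
                for name in TRIMMERS}

    trimmer_masses = {
        name: frame_mass(profiles[name]["inplane"], profiles[name]["crossplane"],
                         material, corner=corner,
                         inner_shear_slopes=(profiles[name]["inplane"].inner_shear_slope,
                                             profiles[name]["crossplane"].inner_shear_slope))
        for name in TRIMMERS
    }
    report = MassReport(trimmers=trimmer_masses, geometry_tag=corner)

    planes = {
        "jaw_inplane": CollimatorPlane(
            "jaw_inplane", machine.z_jaw_inplane,
            {"inplane": jaw_schedule[e_min]["inplane"]["aperture"],
             "crossplane": jaw_schedule[e_min]["inplane"]["aperture"]}),
        "jaw_crossplane": CollimatorPlane(
            "jaw_crossplane", machine.z_jaw_crossplane,
            {"inplane": jaw_schedule[e_min]["crossplane"]["aperture"],
             "crossplane": jaw_schedule[e_min]["crossplane"]["aperture"]}),
        "upper": CollimatorPlane("upper", zu, {"inplane": ap_upper, "crossplane": ap_upper}),
        "middle": CollimatorPlane("middle", zm, {"inplane": ap_middle, "crossplane": ap_middle}),
        "lower": CollimatorPlane("lower", zl, {"inplane": x_lower, "crossplane": x_lower},
                                 inner_edge_divergent=False),
    }
    return ApplicatorDesign(field_size=field_size, trimmer_z=(zu, zm, zl),
                            planes=planes, profiles=profiles,
                            jaw_schedule=jaw_schedule, mass_report=report,
                            tags=tuple(tags))
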