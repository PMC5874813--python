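"""Analytical in-air Gaussian penumbra model for electron collimation design.

The collimating chain (X-ray jaws plus three applicator trimmer frames) is
modelled in a coordinate frame with z measured downstream from the target
plane: the effective (virtual) electron source sits at z = 6 cm, i.e. 94 cm
upstream of the isocenter at z = 100 cm.  A collimator edge at plane z'
(distance from the virtual source) casts a penumbra at a downstream plane z
whose off-axis fluence profile is an error function:

    OAR(E, x) = 0.5 * (1 - erf(x / (sqrt(2) * sigma_x(E))))

where x is the off-axis distance from the geometric (divergent) projection of
the upstream edge.  sigma_x combines multiple scattering in the air gap with
the projected Gaussian width of the virtual source:

    sigma_x^2 = A(E, z', z) + sigma_SW^2 * ((z - z') / z')^2

The air-scatter term A is injectable (see :data:`AIR_TERMS`) because the
moment combination appropriate for pencil beams leaving an upstream aperture
admits more than one defensible form.  The default, ``upstream_divergence``,
is the Fermi-Eyges result for a point source: pencil beams arriving at the
upstream aperture retain a conditional angular variance T*z'/4 (the
position-angle correlated remainder of the accumulated scattering moments),
which then fans out over the gap in addition to the fresh in-gap scattering
T*g^3/3.

Air scattering power follows the power law T_air(E) = 0.00554 * E^-1.78
(rad^2/cm, E in MeV), anchored to the ICRU 10-MeV value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import erf, erfinv

__all__ = [
    "MachineGeometry",
    "ElectronBeamModel",
    "PenumbraSpec",
    "AIR_TERMS",
    "scattering_power_air",
    "sigma_penumbra",
    "oar",
    "oar_offset",
    "project_to_plane",
]

# Default air-scattering power law coefficients (rad^2/cm, E in MeV).
T_AIR_COEFF = 0.00554
T_AIR_EXPONENT = -1.78


def _air_term_fermi_eyges(T: float, zp: float, z: float) -> float:
    """In-gap Fermi-Eyges term only: T * g^3 / 3 with g = z - z'."""
    g = z - zp
    return T * g**3 / 3.0


def _air_term_upstream_divergence(T: float, zp: float, z: float) -> float:
    """In-gap scattering plus the conditional angular spread carried by
    pencil beams leaving the upstream aperture (point source at z=0):

        sigma_air^2 = T * (z' * g^2 / 4  +  g^3 / 3)

    The z'*g^2/4 piece is the Fermi-Eyges conditional (position-resolved)
    angular variance T*z'/4 at the upstream plane, propagated over the gap.
    """
    g = z - zp
    return T * (zp * g**2 / 4.0 + g**3 / 3.0)


def _air_term_divergent_plane(T: float, zp: float, z: float) -> float:
    """Literal reading of the printed gap term: T * (z - z') * z^2 / 6."""
    return T * (z - zp) * z**2 / 6.0


AIR_TERMS: dict[str, Callable[[float, float, float], float]] = {
    "fermi_eyges": _air_term_fermi_eyges,
    "upstream_divergence": _air_term_upstream_divergence,
    "divergent_plane": _air_term_divergent_plane,
}


@dataclass(frozen=True)
class MachineGeometry:
    """z-positions (cm from the target plane) of the collimating chain.

    Defaults place the virtual source 94 cm upstream of the isocenter.  The
    jaw planes are not independently published; the defaults are derived from
    the ratio of physical to isocenter-projected jaw settings of the design
    study (see :func:`ecollim.design_optimizer.calibrate_jaw_z_projection`).
    """

    z_virtual_source: float = 6.0
    z_isocenter: float = 100.0
    z_jaw_inplane: float = 45.6
    z_jaw_crossplane: float = 54.5
    z_trimmer_min: float = 55.0
    z_trimmer_max: float = 95.0

    def __post_init__(self) -> None:
        if not (0.0 < self.z_virtual_source < min(self.z_jaw_inplane, self.z_jaw_crossplane)):
            raise ValueError("virtual source must lie above the jaw planes")
        if not (max(self.z_jaw_inplane, self.z_jaw_crossplane) < self.z_trimmer_min
                < self.z_trimmer_max <= self.z_isocenter):
            raise ValueError("planes must be ordered source < jaws < trimmers <= isocenter")

    def zeta(self, z: float) -> float:
        """Distance of plane z below the virtual source."""
        zeta = z - self.z_virtual_source
        if np.any(np.asarray(zeta) <= 0.0):
            raise ValueError(f"plane z={z} cm is at or above the virtual source")
        return zeta

    def z_jaw(self, axis: str) -> float:
        if axis == "inplane":
            return self.z_jaw_inplane
        if axis == "crossplane":
            return self.z_jaw_crossplane
        raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class ElectronBeamModel:
    """Energy grid and in-air scattering parameters of the electron beam.

    sigma_sw is the Gaussian virtual-source width (cm), a single value used
    at every energy.  The energy grid defaults to 6..20 MeV at 1-MeV spacing;
    the lowest energy controls trimmer widths (widest penumbra) and the
    highest controls full trimmer thickness.
    """

    energies: tuple[float, ...] = tuple(float(e) for e in range(6, 21))
    t_air_coeff: float = T_AIR_COEFF
    t_air_exponent: float = T_AIR_EXPONENT
    sigma_sw: float = 2.0
    air_term: str = "upstream_divergence"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.sigma_sw <= 0:
            raise ValueError("sigma_sw must be positive")
        if list(self.energies) != sorted(self.energies) or min(self.energies) <= 0:
            raise ValueError("energies must be positive and sorted ascending")
        if self.air_term not in AIR_TERMS:
            raise ValueError(f"unknown air_term {self.air_term!r}; choose from {sorted(AIR_TERMS)}")

    @property
    def e_min(self) -> float:
        return self.energies[0]

    @property
    def e_max(self) -> float:
        return self.energies[-1]


@dataclass(frozen=True)
class PenumbraSpec:
    """A single-edge penumbra: Gaussian width and projected edge position."""

    sigma_x: float
    edge_projection_x: float
    energy: float
    z_up: float
    z_down: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0:
            raise ValueError("sigma_x must be positive")
        if self.z_down <= self.z_up:
            raise ValueError("z_down must lie below z_up")


def scattering_power_air(E, beam: ElectronBeamModel | None = None):
    """Electron linear scattering power in air, rad^2/cm.

    Power law T_air(E) = c * E^p with c = 0.00554, p = -1.78 by default.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("energy must be positive")
    c = beam.t_air_coeff if beam is not None else T_AIR_COEFF
    p = beam.t_air_exponent if beam is not None else T_AIR_EXPONENT
    out = c * E**p
    return float(out) if out.ndim == 0 else out


def sigma_penumbra(E: float, z_up: float, z_down: float,
                   machine: MachineGeometry, beam: ElectronBeamModel) -> float:
    """Gaussian penumbra width (cm) at plane ``z_down`` for an edge at ``z_up``.

    Both planes are given in target-frame cm; distances entering the model
    are measured from the virtual source.
    """
    if z_down <= z_up:
        raise ValueError("downstream plane must lie below upstream plane")
    zp = machine.zeta(z_up)
    z = machine.zeta(z_down)
    T = scattering_power_air(E, beam)
    air = AIR_TERMS[beam.air_term](T, zp, z)
    src = (beam.sigma_sw * (z - zp) / zp) ** 2
    return float(np.sqrt(air + src))


def oar(x, sigma_x: float):
    """Off-axis ratio of a single-edge Gaussian penumbra.

    x is measured outward (away from the central axis) from the divergent
    projection of the upstream edge; OAR(0) = 0.5.
    """
    if sigma_x <= 0:
        raise ValueError("sigma_x must be positive")
    x = np.asarray(x, dtype=float)
    out = 0.5 * (1.0 - erf(x / (np.sqrt(2.0) * sigma_x)))
    return float(out) if out.ndim == 0 else out


def oar_offset(target_oar):
    """Offset from the projected edge, in multiples of sigma, where the
    penumbra OAR equals ``target_oar``.

    Positive outward: oar_offset(0.02) ~ +2.05, oar_offset(0.95) ~ -1.645.
    """
    p = np.asarray(target_oar, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("target OAR must lie strictly in (0, 1)")
    out = np.sqrt(2.0) * erfinv(1.0 - 2.0 * p)
    return float(out) if out.ndim == 0 else out


def project_to_plane(x, z_from: float, z_to: float, machine: MachineGeometry):
    """Project an off-axis position along the virtual-source fan line."""
    return x * machine.zeta(z_to) / machine.zeta(z_from)
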