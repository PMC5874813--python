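"""Trimmer material constants and the energy-dependent stopping thickness.

The trimmer frames are a tungsten alloy characterised by the two printed
design numbers: full thickness 0.53 cm and areal density 9.6 g/cm^2 (density
~18.11 g/cm^3, an alloy, not elemental tungsten).  The full thickness is the
1%-electron-transmission shielding thickness for a 20-MeV beam; the thickness
needed at lower energies is obtained by scaling with an electron range law
anchored at 20 MeV:

    t(E) = thickness_full * R(E) / R(20 MeV)

Two range laws are available:

``csda_table``
    An embedded CSDA-style range table for tungsten (g/cm^2), *computed* from
    standard stopping-power theory (Berger-Seltzer collision term with the
    Sternheimer density effect, plus a radiation-length-based radiative term
    with an incomplete-screening factor).  These are model-computed
    constants, not values transcribed from a published tabulation; only the
    ratio R(E)/R(20) enters any design quantity.  Log-log interpolation
    between the 1-MeV grid points.

``practical_linear``
    The classic linear practical-range law R_p ~ 0.521*E - 0.376 (the
    water practical-range fit); because only the ratio to the 20-MeV value is
    used, the absolute material scale drops out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrimmerMaterial", "TUNGSTEN_CSDA_RANGE", "stopping_thickness"]

# (E [MeV], CSDA range [g/cm^2]) for tungsten, computed from stopping-power
# theory as described in the module docstring.
TUNGSTEN_CSDA_RANGE: tuple[tuple[float, float], ...] = (
    (1.0, 0.7862), (2.0, 1.6533), (3.0, 2.4258), (4.0, 3.1167),
    (5.0, 3.7409), (6.0, 4.3101), (7.0, 4.8334), (8.0, 5.3176),
    (9.0, 5.7683), (10.0, 6.1899), (11.0, 6.5860), (12.0, 6.9594),
    (13.0, 7.3127), (14.0, 7.6480), (15.0, 7.9670), (16.0, 8.2713),
    (17.0, 8.5622), (18.0, 8.8408), (19.0, 9.1081), (20.0, 9.3650),
    (21.0, 9.6123), (22.0, 9.8507), (23.0, 10.0809), (24.0, 10.3033),
    (25.0, 10.5185), (26.0, 10.7270), (27.0, 10.9291), (28.0, 11.1253),
    (29.0, 11.3158), (30.0, 11.5011),
)

# Practical-range linear law coefficients (g/cm^2 per MeV, g/cm^2).
_PRACTICAL_SLOPE = 0.521
_PRACTICAL_INTERCEPT = -0.376

_ANCHOR_ENERGY = 20.0  # MeV at which thickness_full applies exactly


@dataclass(frozen=True)
class TrimmerMaterial:
    """Shielding material of the trimmer frames."""

    name: str = "tungsten alloy"
    areal_density_full: float = 9.6   # g/cm^2 at full thickness
    thickness_full: float = 0.53      # cm, stops a 20-MeV beam (1% transmission)
    range_table: tuple[tuple[float, float], ...] = TUNGSTEN_CSDA_RANGE
    range_law: str = "practical_linear"  # or "csda_table"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.thickness_full <= 0 or self.areal_density_full <= 0:
            raise ValueError("thickness and areal density must be positive")
        es = [e for e, _ in self.range_table]
        rs = [r for _, r in self.range_table]
        if es != sorted(es) or rs != sorted(rs) or len(es) != len(set(es)):
            raise ValueError("range table must be strictly increasing in both columns")
        if self.range_law not in ("csda_table", "practical_linear"):
            raise ValueError(f"unknown range law {self.range_law!r}")

    @property
    def density(self) -> float:
        """g/cm^3, derived from the two printed design numbers."""
        return self.areal_density_full / self.thickness_full

    def range_ratio(self, E) -> np.ndarray | float:
        """R(E) / R(20 MeV) under the configured range law."""
        E = np.asarray(E, dtype=float)
        if self.range_law == "practical_linear":
            r = _PRACTICAL_SLOPE * E + _PRACTICAL_INTERCEPT
            r20 = _PRACTICAL_SLOPE * _ANCHOR_ENERGY + _PRACTICAL_INTERCEPT
            if np.any(r <= 0):
                raise ValueError("energy below the validity of the practical-range law")
            out = r / r20
        else:
            es = np.array([e for e, _ in self.range_table])
            rs = np.array([r for _, r in self.range_table])
            if np.any(E < es[0]) or np.any(E > es[-1]):
                raise ValueError(
                    f"energy outside range-table coverage [{es[0]}, {es[-1]}] MeV")
            # log-log interpolation: ranges follow an approximate power law
            logr = np.interp(np.log(E), np.log(es), np.log(rs))
            r20 = np.interp(np.log(_ANCHOR_ENERGY), np.log(es), np.log(rs))
            out = np.exp(logr - r20)
        return float(out) if out.ndim == 0 else out


def stopping_thickness(E, material: TrimmerMaterial) -> float | np.ndarray:
    """Material thickness (cm) required to stop electrons of energy E.

    Anchored so that t(20 MeV) == material.thickness_full exactly; lower
    energies scale with the configured range law.
    """
    ratio = material.range_ratio(E)
    return material.thickness_full * ratio
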